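"""Probe-level beta values, probe QC and gene-level promoter methylation.

The per-probe methylation degree is
``beta = max(y_methy, 0) / (max(y_methy, 0) + max(y_umethy, 0) + alpha)`` with
alpha = 100 guarding against jointly low intensities.  QC drops non-CpG probes
first, then any probe with at least one NA cell.  Gene-level promoter
methylation is a two-stage mean — probe beta averaged over the samples of a
condition, then averaged over the probes inside [TSS-1500, TSS+1500] — and the
relative difference RD = (beta_t - beta_p) / (beta_p + delta) with delta = 1e-9
classifies genes as hyper (RD > 0.2) or hypo (RD < -0.2), strict inequalities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BetaMatrix, GeneAnnotation, ProbeManifest, SampleSheet

logger = logging.getLogger("methkey")

ALPHA_INTENSITY = 100.0
DELTA = 1e-9
RD_THRESHOLD = 0.2


@dataclass
class FilterLog:
    """Counts from probe QC, in the order the filters run."""

    n_input: int
    n_non_cpg_removed: int
    n_na_removed: int
    n_retained: int


@dataclass
class GeneMethylation:
    """Per-gene pooled promoter methylation, RD and hyper/hypo status."""

    table: pd.DataFrame  # columns: beta_t, beta_p, m_r, rd, status

    def genes_with_status(self, status: str) -> list[str]:
        t = self.table
        return list(t.index[t["status"] == status])


def beta_from_intensities(y_methy, y_umethy, alpha: float = ALPHA_INTENSITY):
    """Beta from (methylated, unmethylated) intensities; negatives clamp to 0."""
    m = np.maximum(np.asarray(y_methy, dtype=float), 0.0)
    u = np.maximum(np.asarray(y_umethy, dtype=float), 0.0)
    return m / (m + u + alpha)


def beta_matrix_from_intensities(
    intensities: pd.DataFrame, manifest: ProbeManifest, alpha: float = ALPHA_INTENSITY
) -> BetaMatrix:
    """Apply the beta transform to an intensity table (sample, channel) frame."""
    samples = intensities.columns.get_level_values("sample").unique()
    cols = {
        s: beta_from_intensities(intensities[(s, "methy")], intensities[(s, "umethy")], alpha)
        for s in samples
    }
    values = pd.DataFrame(cols, index=intensities.index)
    known = values.index.isin(manifest.table.index)
    if (~known).any():
        logger.info("dropping %d intensity probe(s) absent from manifest", int((~known).sum()))
        values = values.loc[known]
    return BetaMatrix(values, manifest)


def filter_probes(beta: BetaMatrix) -> tuple[BetaMatrix, FilterLog]:
    """QC in the stated order: non-CpG probes out, then any-NA probes out."""
    values = beta.values
    n_input = len(values)
    is_cpg = beta.manifest.table.loc[values.index, "is_cpg"].to_numpy()
    values = values.loc[is_cpg]
    n_non_cpg = n_input - len(values)
    has_na = values.isna().any(axis=1)
    retained = values.loc[~has_na]
    log = FilterLog(n_input, n_non_cpg, int(has_na.sum()), len(retained))
    logger.info(
        "probe QC: %d in, %d non-CpG removed, %d NA-containing removed, %d retained",
        log.n_input, log.n_non_cpg_removed, log.n_na_removed, log.n_retained,
    )
    if log.n_retained == 0:
        logger.warning("probe QC retained 0 probes")
    return BetaMatrix(retained, beta.manifest), log


def condition_means(beta: BetaMatrix, sheet: SampleSheet) -> pd.DataFrame:
    """Per-probe mean beta within each condition (columns beta_t, beta_p)."""
    v = beta.values
    return pd.DataFrame(
        {
            "beta_t": v[sheet.samples("cancer")].mean(axis=1),
            "beta_p": v[sheet.samples("paracancer")].mean(axis=1),
        }
    )


def rd(beta_t, beta_p, delta: float = DELTA):
    """Relative difference (beta_t - beta_p) / (beta_p + delta)."""
    bt = np.asarray(beta_t, dtype=float)
    bp = np.asarray(beta_p, dtype=float)
    return (bt - bp) / (bp + delta)


def classify_rd(rd_values, threshold: float = RD_THRESHOLD) -> pd.Series:
    """hyper iff RD > threshold, hypo iff RD < -threshold, else normal."""
    r = np.asarray(rd_values, dtype=float)
    out = np.where(r > threshold, "hyper", np.where(r < -threshold, "hypo", "normal"))
    idx = rd_values.index if isinstance(rd_values, pd.Series) else None
    return pd.Series(out, index=idx)


def promoter_probe_ids(
    manifest: ProbeManifest, annotation: GeneAnnotation, probe_subset=None
) -> dict[str, list[str]]:
    """Map gene_id -> probe ids inside [TSS-1500, TSS+1500], inclusive ends.

    Probe strand is ignored: the promoter window is symmetric around the TSS.
    """
    mt = manifest.table
    if probe_subset is not None:
        mt = mt.loc[mt.index.isin(probe_subset)]
    out: dict[str, list[str]] = {}
    by_chrom = {c: g.sort_values("pos") for c, g in mt.groupby("chrom")}
    for row in annotation.genes.itertuples(index=False):
        lo, hi = annotation.promoter_interval(row.gene_id)
        probes = by_chrom.get(row.chrom)
        if probes is None:
            out[row.gene_id] = []
            continue
        pos = probes["pos"].to_numpy()
        i, j = np.searchsorted(pos, lo, "left"), np.searchsorted(pos, hi, "right")
        out[row.gene_id] = list(probes.index[i:j])
    return out


def gene_promoter_beta(
    beta: BetaMatrix,
    annotation: GeneAnnotation,
    sheet: SampleSheet,
    threshold: float = RD_THRESHOLD,
    delta: float = DELTA,
) -> GeneMethylation:
    """Pooled gene-level promoter methylation and hyper/hypo classification.

    Uses all cancer vs all paracancer samples (unmatched pooling).  Genes with
    no promoter probes get status ``no_probes`` and NaN statistics.
    """
    means = condition_means(beta, sheet)
    probe_map = promoter_probe_ids(beta.manifest, annotation, probe_subset=beta.values.index)
    rows = []
    for gid in annotation.genes["gene_id"]:
        probes = probe_map[gid]
        m_r = len(probes)
        if m_r == 0:
            rows.append((gid, np.nan, np.nan, 0, np.nan, "no_probes"))
            continue
        bt = means.loc[probes, "beta_t"].mean()
        bp = means.loc[probes, "beta_p"].mean()
        r = rd(bt, bp, delta)
        status = "hyper" if r > threshold else ("hypo" if r < -threshold else "normal")
        rows.append((gid, bt, bp, m_r, r, status))
    table = pd.DataFrame(
        rows, columns=["gene_id", "beta_t", "beta_p", "m_r", "rd", "status"]
    ).set_index("gene_id")
    logger.info(
        "promoter methylation: %d hyper, %d hypo, %d normal, %d without probes",
        (table["status"] == "hyper").sum(), (table["status"] == "hypo").sum(),
        (table["status"] == "normal").sum(), (table["status"] == "no_probes").sum(),
    )
    return GeneMethylation(table)
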