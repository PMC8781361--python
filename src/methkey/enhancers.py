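"""Enhancer target assignment and differentially-methylated-enhancer (DME) calls.

Each enhancer is assigned the gene whose TSS is closest to the enhancer center
(same chromosome, within 1 Mb; ties broken by smaller TSS then lexicographic
gene id).  For every matched patient the enhancer methylation relative
difference RD_kj (cancer vs paracancer mean probe beta over the enhancer's
probes) and the target gene's expression ratio FC_kj (pseudocount 1 on
normalized counts) are computed, and their Spearman rank correlation r_k is
evaluated with the classic d-squared shortcut
``r = 1 - 6 sum d_j^2 / (n (n^2 - 1))`` (midranks + Pearson-of-ranks fallback
under ties).  A DME pair is called when the pooled enhancer |RD| > 0.2, r_k <
-0.4, and the target's pooled promoter |RD| <= 0.2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import BetaMatrix, EnhancerSet, GeneAnnotation, SampleSheet
from .methylation import DELTA, RD_THRESHOLD, GeneMethylation, condition_means, rd

logger = logging.getLogger("methkey")

MAX_TARGET_DISTANCE = 1_000_000
R_THRESHOLD = -0.4


@dataclass
class DMEResult:
    """Enhancer/target pair table with correlations and the final call flag."""

    pairs: pd.DataFrame  # enhancer_id, gene_id, r, enhancer_rd, promoter_rd, call
    vectors: dict[str, pd.DataFrame]  # enhancer_id -> per-patient RD/FC frame

    @property
    def called(self) -> pd.DataFrame:
        return self.pairs[self.pairs["call"]]

    @property
    def dme_genes(self) -> set[str]:
        return set(self.called["gene_id"])


def assign_targets(
    enhancers: EnhancerSet,
    annotation: GeneAnnotation,
    max_dist: float = MAX_TARGET_DISTANCE,
) -> pd.DataFrame:
    """Nearest-TSS target gene per enhancer within ``max_dist`` (inclusive).

    Returns a frame with columns enhancer_id, gene_id, distance; enhancers
    with no gene in range are omitted (count logged).  Ties go to the smaller
    TSS, then the lexicographically smaller gene id.
    """
    genes = annotation.genes.sort_values(["chrom", "tss", "gene_id"], kind="mergesort")
    rows = []
    n_unassigned = 0
    for chrom, enh in enhancers.table.groupby("chrom", sort=True):
        g = genes[genes["chrom"] == chrom]
        if g.empty:
            n_unassigned += len(enh)
            continue
        tss = g["tss"].to_numpy()
        gids = g["gene_id"].to_numpy()
        for row in enh.itertuples(index=False):
            d = np.abs(tss - row.center)
            best = d.min()
            if best > max_dist:
                n_unassigned += 1
                continue
            # candidates already sorted by (tss, gene_id): first minimal wins
            k = int(np.argmax(d == best))
            rows.append((row.enhancer_id, gids[k], int(d[k])))
    if n_unassigned:
        logger.info("%d enhancer(s) with no gene within %g bp", n_unassigned, max_dist)
    out = pd.DataFrame(rows, columns=["enhancer_id", "gene_id", "distance"])
    return out.sort_values("enhancer_id", kind="mergesort").reset_index(drop=True)


def enhancer_probe_ids(beta: BetaMatrix, enhancers: EnhancerSet) -> dict[str, list[str]]:
    """Probe ids inside each enhancer's [start, end] (internal, inclusive)."""
    mt = beta.manifest.table.loc[beta.values.index]
    by_chrom = {c: g.sort_values("pos") for c, g in mt.groupby("chrom")}
    out: dict[str, list[str]] = {}
    for row in enhancers.table.itertuples(index=False):
        probes = by_chrom.get(row.chrom)
        if probes is None:
            out[row.enhancer_id] = []
            continue
        pos = probes["pos"].to_numpy()
        i = np.searchsorted(pos, row.start, "left")
        j = np.searchsorted(pos, row.end, "right")
        out[row.enhancer_id] = list(probes.index[i:j])
    return out


def patient_vectors(
    beta: BetaMatrix,
    norm: pd.DataFrame,
    sheet: SampleSheet,
    probe_ids: list[str],
    gene_id: str,
    delta: float = DELTA,
) -> pd.DataFrame:
    """Per-matched-patient (RD_kj, FC_kj) for one enhancer/gene pair.

    RD_kj compares the patient's cancer vs paracancer mean beta over the
    enhancer's probes; FC_kj = (NC_cancer + 1) / (NC_paracancer + 1).
    """
    pairs = sheet.matched_pairs()
    if len(pairs) < 3:
        raise ValueError("per-patient correlation needs >= 3 matched pairs")
    if not probe_ids:
        raise ValueError("enhancer has no probes")
    b = beta.values.loc[probe_ids]
    rows = []
    for row in pairs.itertuples(index=False):
        bt = b[row.cancer].mean()
        bp = b[row.paracancer].mean()
        fc = (norm.at[gene_id, row.cancer] + 1.0) / (norm.at[gene_id, row.paracancer] + 1.0)
        rows.append((row.patient_id, rd(bt, bp, delta), fc))
    return pd.DataFrame(rows, columns=["patient_id", "rd", "fc"]).set_index("patient_id")


def spearman_shortcut(x, y) -> float:
    """Spearman correlation via the rank-difference shortcut.

    With distinct values this is exactly ``1 - 6 sum d^2 / (n(n^2-1))``; with
    ties midranks are used and the Pearson correlation of the midranks is
    returned instead (the shortcut assumes distinct ranks).  A constant input
    has no defined rank correlation and returns NaN with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or n != len(y):
        raise ValueError("spearman_shortcut needs two equal-length vectors, n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("constant vector: rank correlation undefined")
        return float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    has_ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    if has_ties:
        return float(np.corrcoef(rx, ry)[0, 1])
    d2 = np.sum((rx - ry) ** 2)
    return float(1.0 - 6.0 * d2 / (n * (n**2 - 1)))


def call_dme(
    beta: BetaMatrix,
    norm: pd.DataFrame,
    sheet: SampleSheet,
    enhancers: EnhancerSet,
    annotation: GeneAnnotation,
    promoter_meth: GeneMethylation,
    r_threshold: float = R_THRESHOLD,
    rd_threshold: float = RD_THRESHOLD,
    max_dist: float = MAX_TARGET_DISTANCE,
) -> DMEResult:
    """Full DME-pair pipeline in the stated order.

    (1) pooled enhancer RD screen (|RD| > rd_threshold); (2) per-patient rank
    correlation screen (r < r_threshold); (3) promoter exclusion (target's
    pooled promoter |RD| <= rd_threshold).  A gene may appear in several
    pairs.  Enhancers with no probes or no target in range are dropped
    (logged).
    """
    targets = assign_targets(enhancers, annotation, max_dist)
    probe_map = enhancer_probe_ids(beta, enhancers)
    means = condition_means(beta, sheet)
    rows = []
    vectors: dict[str, pd.DataFrame] = {}
    n_no_probes = 0
    for row in targets.itertuples(index=False):
        probes = probe_map[row.enhancer_id]
        if not probes:
            n_no_probes += 1
            continue
        bt = means.loc[probes, "beta_t"].mean()
        bp = means.loc[probes, "beta_p"].mean()
        enh_rd = float(rd(bt, bp))
        prom_rd = promoter_meth.table.at[row.gene_id, "rd"] if row.gene_id in promoter_meth.table.index else np.nan
        r = np.nan
        passed_rd = abs(enh_rd) > rd_threshold
        if passed_rd:
            vec = patient_vectors(beta, norm, sheet, probes, row.gene_id)
            if np.isfinite(vec["fc"]).all():
                r = spearman_shortcut(vec["rd"].to_numpy(), vec["fc"].to_numpy())
            vectors[row.enhancer_id] = vec
        call = bool(
            passed_rd
            and np.isfinite(r)
            and r < r_threshold
            and np.isfinite(prom_rd)
            and abs(prom_rd) <= rd_threshold
        )
        rows.append((row.enhancer_id, row.gene_id, row.distance, enh_rd, prom_rd, r, call))
    if n_no_probes:
        logger.info("%d enhancer(s) without probes dropped from DME calling", n_no_probes)
    pairs = pd.DataFrame(
        rows,
        columns=["enhancer_id", "gene_id", "distance", "enhancer_rd", "promoter_rd", "r", "call"],
    )
    logger.info(
        "DME: %d pairs called (%d distinct genes) of %d enhancer/target pairs",
        int(pairs["call"].sum()), pairs.loc[pairs["call"], "gene_id"].nunique(), len(pairs),
    )
    return DMEResult(pairs, vectors)
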