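"""Binned methylation profiles across gene regions.

The promoter (TSS +- 1500 bp) is partitioned into 30 bins of 100 bp, numbered
1..30 in transcription orientation; every other region (5'UTR, exon, intron,
3'UTR, intergenic, enhancer) is partitioned into 10 equal-length bins over its
concatenated intervals (last bin absorbs the remainder).  Promoter bin mu
covers transcription-frame offsets (-1500 + 100(mu-1), -1500 + 100 mu], so
bins 14-17 span exactly (-200, +200] around the TSS — the "key bins" where
abnormal methylation concentrates; the single boundary offset -1500 is folded
into bin 1 so the 30 bins cover the whole closed promoter window.

Per-bin methylation is the mean over probes of the per-probe condition mean
(the same two-stage average as the gene-level statistic), per-bin RD uses the
same relative-difference formula, and a bin is "abnormal" when |RD| > 0.2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BetaMatrix, EnhancerSet, GeneAnnotation, SampleSheet
from .methylation import DELTA, RD_THRESHOLD, condition_means

logger = logging.getLogger("methkey")

PROMOTER_BINS = 30
PROMOTER_BIN_BP = 100
REGION_BINS = 10
KEY_BINS = (14, 15, 16, 17)

REGION_KINDS = ("promoter", "utr5", "exon", "intron", "utr3", "intergenic")


def promoter_bin(pos: int, tss: int, strand: str) -> int | None:
    """Promoter bin (1..30) of a genomic position, or None if outside.

    Offsets are taken in transcription orientation; bin boundaries are half
    open upstream ((lo, hi]), so a probe exactly at the TSS (offset 0) falls
    in bin 15 and offset +1 starts bin 16.
    """
    offset = pos - tss if strand == "+" else tss - pos
    half = PROMOTER_BINS * PROMOTER_BIN_BP // 2
    if offset < -half or offset > half:
        return None
    if offset == -half:
        return 1
    return -((offset + half) // -PROMOTER_BIN_BP)  # ceil division


@dataclass
class RegionBins:
    """A region's concatenated-interval geometry for probe -> bin lookup."""

    intervals: list[tuple[int, int]]  # 1-based inclusive, transcription order
    strand: str
    n_bins: int = REGION_BINS

    def __post_init__(self) -> None:
        self.length = sum(e - s + 1 for s, e in self.intervals)
        if self.length < self.n_bins:
            logger.warning(
                "region of length %d shorter than its %d bins; empty bins allowed",
                self.length, self.n_bins,
            )
        self._bin_len = max(1, self.length // self.n_bins)

    def offset(self, pos: int) -> int | None:
        """Transcription-frame offset of pos in the concatenated region."""
        acc = 0
        for s, e in self.intervals:
            if s <= pos <= e:
                return acc + (pos - s if self.strand == "+" else e - pos)
            acc += e - s + 1
        return None

    def bin(self, pos: int) -> int | None:
        off = self.offset(pos)
        if off is None:
            return None
        return min(self.n_bins, off // self._bin_len + 1)


def build_bins(annotation: GeneAnnotation) -> dict[str, dict[str, RegionBins]]:
    """Per gene, per non-promoter region kind, the RegionBins geometry.

    Intervals are ordered in transcription orientation (ascending start on the
    plus strand, descending on the minus strand); the promoter is handled by
    ``promoter_bin`` directly.
    """
    out: dict[str, dict[str, RegionBins]] = {}
    for row in annotation.genes.itertuples(index=False):
        per_gene: dict[str, RegionBins] = {}
        for kind, ivs in annotation.regions.get(row.gene_id, {}).items():
            ordered = sorted(ivs, key=lambda iv: iv[0], reverse=(row.strand == "-"))
            per_gene[kind] = RegionBins(ordered, row.strand)
        out[row.gene_id] = per_gene
    return out


def _assign_promoter_probes(beta: BetaMatrix, annotation: GeneAnnotation):
    """Yield (gene_id, bin, probe_id) for probes in promoter windows."""
    mt = beta.manifest.table.loc[beta.values.index]
    by_chrom = {c: g.sort_values("pos") for c, g in mt.groupby("chrom")}
    half = PROMOTER_BINS * PROMOTER_BIN_BP // 2
    for row in annotation.genes.itertuples(index=False):
        probes = by_chrom.get(row.chrom)
        if probes is None:
            continue
        pos = probes["pos"].to_numpy()
        i = np.searchsorted(pos, row.tss - half, "left")
        j = np.searchsorted(pos, row.tss + half, "right")
        for pid, p in zip(probes.index[i:j], pos[i:j]):
            mu = promoter_bin(int(p), int(row.tss), row.strand)
            if mu is not None:
                yield row.gene_id, mu, pid


def bin_profile(
    beta: BetaMatrix,
    annotation: GeneAnnotation,
    sheet: SampleSheet,
    regions: tuple[str, ...] = REGION_KINDS,
) -> pd.DataFrame:
    """Per (gene, region, bin) methylation profile.

    Returns a frame indexed by (feature_id, region, bin) with columns beta_t,
    beta_p, m_r.  Bins with no probes are absent, never zero-filled.  A probe
    may contribute to several region tracks (promoter overlaps 5'UTR etc.).
    """
    means = condition_means(beta, sheet)
    geometry = build_bins(annotation)
    mt = beta.manifest.table.loc[beta.values.index]
    by_chrom = {c: g.sort_values("pos") for c, g in mt.groupby("chrom")}

    records: list[tuple[str, str, int, str]] = []
    if "promoter" in regions:
        for gid, mu, pid in _assign_promoter_probes(beta, annotation):
            records.append((gid, "promoter", mu, pid))
    for row in annotation.genes.itertuples(index=False):
        probes = by_chrom.get(row.chrom)
        if probes is None:
            continue
        pos = probes["pos"].to_numpy()
        for kind, rb in geometry[row.gene_id].items():
            if kind not in regions:
                continue
            for s, e in rb.intervals:
                i = np.searchsorted(pos, s, "left")
                j = np.searchsorted(pos, e, "right")
                for pid, p in zip(probes.index[i:j], pos[i:j]):
                    mu = rb.bin(int(p))
                    if mu is not None:
                        records.append((row.gene_id, kind, mu, pid))
    return _aggregate(records, means)


def enhancer_bin_profile(
    beta: BetaMatrix, enhancers: EnhancerSet, sheet: SampleSheet
) -> pd.DataFrame:
    """Per (enhancer, bin) profile using the same 10-bin machinery.

    Enhancers carry no strand; bins run in genomic orientation.  The region
    label is ``enhancer`` and the feature id is the enhancer id.
    """
    means = condition_means(beta, sheet)
    mt = beta.manifest.table.loc[beta.values.index]
    by_chrom = {c: g.sort_values("pos") for c, g in mt.groupby("chrom")}
    records = []
    for row in enhancers.table.itertuples(index=False):
        probes = by_chrom.get(row.chrom)
        if probes is None:
            continue
        rb = RegionBins([(row.start, row.end)], "+")
        pos = probes["pos"].to_numpy()
        i = np.searchsorted(pos, row.start, "left")
        j = np.searchsorted(pos, row.end, "right")
        for pid, p in zip(probes.index[i:j], pos[i:j]):
            mu = rb.bin(int(p))
            if mu is not None:
                records.append((row.enhancer_id, "enhancer", mu, pid))
    return _aggregate(records, means)


def _aggregate(records, means: pd.DataFrame) -> pd.DataFrame:
    cols = ["feature_id", "region", "bin"]
    if not records:
        idx = pd.MultiIndex.from_arrays([[], [], []], names=cols)
        return pd.DataFrame(columns=["beta_t", "beta_p", "m_r"], index=idx)
    rec = pd.DataFrame(records, columns=cols + ["probe_id"])
    rec = rec.join(means, on="probe_id")
    grp = rec.groupby(cols, sort=True)
    out = grp[["beta_t", "beta_p"]].mean()
    out["m_r"] = grp.size()
    return out


def bin_rd(
    profile: pd.DataFrame, delta: float = DELTA, threshold: float = RD_THRESHOLD
) -> pd.DataFrame:
    """Add per-bin RD and the abnormal flag (|RD| > threshold, strict)."""
    out = profile.copy()
    out["rd"] = (out["beta_t"] - out["beta_p"]) / (out["beta_p"] + delta)
    out["abnormal"] = out["rd"].abs() > threshold
    return out


def abnormal_density(
    profile: pd.DataFrame, gene_set, region: str = "promoter"
) -> pd.DataFrame:
    """Per-bin count and fraction of genes abnormal in that bin.

    ``profile`` must carry the ``abnormal`` column from :func:`bin_rd`.  Genes
    with a missing bin are excluded from that bin's denominator.
    """
    gene_set = set(gene_set)
    sub = profile.xs(region, level="region", drop_level=False)
    sub = sub[sub.index.get_level_values("feature_id").isin(gene_set)]
    n_bins = PROMOTER_BINS if region == "promoter" else REGION_BINS
    rows = []
    for mu in range(1, n_bins + 1):
        try:
            at_bin = sub.xs(mu, level="bin")
        except KeyError:
            rows.append((mu, 0, 0, np.nan))
            continue
        n = len(at_bin)
        k = int(at_bin["abnormal"].sum())
        rows.append((mu, k, n, k / n if n else np.nan))
    return pd.DataFrame(rows, columns=["bin", "n_abnormal", "n_genes", "fraction"]).set_index("bin")


def key_bin_filter(
    profile: pd.DataFrame, gene_set, bins: tuple[int, ...] = KEY_BINS
) -> set[str]:
    """Genes abnormal in at least one key promoter bin (TSS +- 200 bp)."""
    gene_set = set(gene_set)
    sub = profile.xs("promoter", level="region", drop_level=False)
    mask = (
        sub.index.get_level_values("feature_id").isin(gene_set)
        & sub.index.get_level_values("bin").isin(bins)
        & sub["abnormal"].to_numpy()
    )
    return set(sub.index.get_level_values("feature_id")[mask])
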