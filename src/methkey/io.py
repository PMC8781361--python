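"""Readers, writers and domain containers for every external table the pipeline touches.

All other modules operate on the in-memory types defined here.  Internal genomic
coordinates are 1-based inclusive (matching HM450K manifest positions); BED files
(0-based half-open) are converted at this boundary and nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("methkey")

#: tokens treated as missing in methylation tables
NA_TOKENS = {"NA", "", "NaN"}

CONDITIONS = ("cancer", "paracancer")


# ---------------------------------------------------------------------------
# coordinate conversion (the only place BED <-> internal happens)
# ---------------------------------------------------------------------------

def bed_to_internal(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open BED interval to 1-based inclusive."""
    return start + 1, end


def internal_to_bed(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open BED."""
    return start - 1, end


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SampleSheet:
    """Maps samples to patients and condition (cancer / paracancer).

    A matched pair is a patient with exactly one sample of each condition.
    """

    table: pd.DataFrame  # columns: sample_id, patient_id, condition

    def __post_init__(self) -> None:
        t = self.table
        required = {"sample_id", "patient_id", "condition"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id {dup!r} in sample sheet")
        bad = set(t["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition(s) {sorted(bad)}; expected {CONDITIONS}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples(self, condition: str) -> list[str]:
        t = self.table
        return list(t.loc[t["condition"] == condition, "sample_id"])

    @property
    def n_cancer(self) -> int:
        return len(self.samples("cancer"))

    @property
    def n_paracancer(self) -> int:
        return len(self.samples("paracancer"))

    def matched_pairs(self) -> pd.DataFrame:
        """Patients with exactly one cancer and one paracancer sample.

        Returns a frame with columns patient_id, cancer, paracancer, sorted by
        patient_id for determinism.
        """
        t = self.table
        rows = []
        for patient, grp in t.groupby("patient_id", sort=True):
            cans = grp.loc[grp["condition"] == "cancer", "sample_id"]
            paras = grp.loc[grp["condition"] == "paracancer", "sample_id"]
            if len(cans) == 1 and len(paras) == 1:
                rows.append((patient, cans.iloc[0], paras.iloc[0]))
        return pd.DataFrame(rows, columns=["patient_id", "cancer", "paracancer"])


@dataclass
class ProbeManifest:
    """HM450K-style probe manifest: probe id, genomic position, CpG flag."""

    table: pd.DataFrame  # columns: probe_id, chrom, pos, is_cpg

    def __post_init__(self) -> None:
        t = self.table
        required = {"probe_id", "chrom", "pos", "is_cpg"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"probe manifest missing columns: {sorted(missing)}")
        if t["probe_id"].duplicated().any():
            dup = t.loc[t["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValueError(f"duplicate probe_id {dup!r} in manifest")
        if len(t) and (t["pos"] < 1).any():
            raise ValueError("manifest positions must be >= 1 (1-based)")
        self.table = t.set_index("probe_id", drop=False)
        self.table.index.name = None

    @property
    def n_probes(self) -> int:
        return len(self.table)


@dataclass
class GeneAnnotation:
    """Strand-aware gene models: one TSS per gene plus region interval lists.

    ``genes`` columns: gene_id, symbol, chrom, strand, tss.
    ``regions`` maps gene_id -> {region_kind: [(start, end), ...]} in 1-based
    inclusive coordinates.  The promoter (TSS +- 1500 bp) is derived from the
    TSS, never stored.
    """

    genes: pd.DataFrame
    regions: dict[str, dict[str, list[tuple[int, int]]]] = field(default_factory=dict)

    PROMOTER_HALF_WIDTH = 1500

    def __post_init__(self) -> None:
        g = self.genes
        required = {"gene_id", "symbol", "chrom", "strand", "tss"}
        missing = required - set(g.columns)
        if missing:
            raise ValueError(f"gene annotation missing columns: {sorted(missing)}")
        if g["gene_id"].duplicated().any():
            dup = g.loc[g["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"gene {dup!r} annotated more than once (one TSS per gene)")
        bad = set(g["strand"]) - {"+", "-"}
        if bad:
            raise ValueError(f"unknown strand value(s): {sorted(bad)}")
        self.genes = g.set_index("gene_id", drop=False)
        self.genes.index.name = None

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def promoter_interval(self, gene_id: str) -> tuple[int, int]:
        """Closed interval [tss-1500, tss+1500] for a gene (strand symmetric)."""
        tss = int(self.genes.at[gene_id, "tss"])
        return tss - self.PROMOTER_HALF_WIDTH, tss + self.PROMOTER_HALF_WIDTH

    def symbol_to_id(self) -> dict[str, str]:
        """Symbol -> gene_id map (first wins on duplicate symbols, logged)."""
        out: dict[str, str] = {}
        dups = 0
        for gid, sym in zip(self.genes["gene_id"], self.genes["symbol"]):
            if sym in out:
                dups += 1
                continue
            out[sym] = gid
        if dups:
            logger.warning("%d duplicate symbols in annotation; first occurrence kept", dups)
        return out


@dataclass
class EnhancerSet:
    """Enhancer intervals with their center coordinate (floor midpoint)."""

    table: pd.DataFrame  # columns: enhancer_id, chrom, start, end, center (internal coords)

    def __post_init__(self) -> None:
        t = self.table
        if t["enhancer_id"].duplicated().any():
            dup = t.loc[t["enhancer_id"].duplicated(), "enhancer_id"].iloc[0]
            raise ValueError(f"duplicate enhancer_id {dup!r}")
        lengths = t["end"] - t["start"] + 1
        n_odd = int(((lengths < 50) | (lengths > 1500)).sum())
        if n_odd:
            logger.warning("%d enhancer(s) outside the typical 50-1500 bp length range", n_odd)
        self.table = t.set_index("enhancer_id", drop=False)
        self.table.index.name = None

    @property
    def n_enhancers(self) -> int:
        return len(self.table)


@dataclass
class CancerGeneSets:
    """Curated oncogene and tumor-suppressor symbol sets; overlap is reported."""

    oncogenes: set[str]
    tsgs: set[str]

    def __post_init__(self) -> None:
        both = self.oncogenes & self.tsgs
        if both:
            logger.info("%d gene(s) listed as both oncogene and TSG", len(both))

    @property
    def overlap(self) -> set[str]:
        return self.oncogenes & self.tsgs


@dataclass
class CountMatrix:
    """Integer gene x sample expression counts aligned to a sample sheet."""

    values: pd.DataFrame  # genes x samples, integer
    sheet: SampleSheet
    unknown_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = self.values
        if list(v.columns) != self.sheet.sample_ids:
            raise ValueError("count matrix columns are not aligned to the sample sheet")
        if len(v) and (v.to_numpy() < 0).any():
            raise ValueError("negative count encountered")

    @property
    def n_genes(self) -> int:
        return len(self.values)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class BetaMatrix:
    """Probe x sample methylation beta values in [0, 1] with an NA mask."""

    values: pd.DataFrame  # probes x samples, float with NaN for missing
    manifest: ProbeManifest

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError("beta value outside [0, 1]")

    @property
    def na_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_probes(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> SampleSheet:
    t = pd.read_csv(path, sep="\t", dtype=str)
    return SampleSheet(t)


def read_counts(path, sheet: SampleSheet) -> CountMatrix:
    """Read a gene x sample count TSV; cells must be nonnegative integers.

    Samples in the header that are absent from the sheet are a hard error;
    columns are re-ordered to sheet order.  Gene ids are retained verbatim.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    gene_col = raw.columns[0]
    genes = raw[gene_col]
    header = list(raw.columns[1:])
    unknown = [s for s in header if s not in set(sheet.sample_ids)]
    if unknown:
        raise ValueError(f"sample(s) {unknown} in count header absent from sample sheet")
    missing = [s for s in sheet.sample_ids if s not in header]
    if missing:
        raise ValueError(f"sheet sample(s) {missing} missing from count file")
    values = {}
    for col in header:
        cell = raw[col]
        as_num = pd.to_numeric(cell, errors="coerce")
        bad = as_num.isna() | (as_num != np.floor(as_num)) | (as_num < 0)
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"non-(nonnegative integer) count {cell.iloc[i]!r} at gene "
                f"{genes.iloc[i]!r}, sample {col!r}"
            )
        values[col] = as_num.astype(np.int64).to_numpy()
    mat = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"))
    mat = mat[sheet.sample_ids]
    return CountMatrix(mat, sheet)


def read_probe_manifest(path) -> ProbeManifest:
    t = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    if t["is_cpg"].dtype == object:
        t["is_cpg"] = t["is_cpg"].astype(str).str.lower().isin({"true", "1", "yes"})
    t["is_cpg"] = t["is_cpg"].astype(bool)
    t["pos"] = t["pos"].astype(np.int64)
    return ProbeManifest(t)


def read_beta_table(path, manifest: ProbeManifest) -> BetaMatrix:
    """Read a probe x sample beta TSV; NA tokens become NaN; probes not in the
    manifest are dropped (count logged)."""
    raw = pd.read_csv(
        path, sep="\t", index_col=0, na_values=list(NA_TOKENS), keep_default_na=False
    )
    raw.index = raw.index.astype(str)
    raw.index.name = "probe_id"
    known = raw.index.isin(manifest.table.index)
    n_dropped = int((~known).sum())
    if n_dropped:
        logger.info("dropping %d probe(s) absent from the manifest", n_dropped)
    raw = raw.loc[known].astype(float)
    return BetaMatrix(raw, manifest)


def read_intensity_table(path) -> pd.DataFrame:
    """Read per-probe (methylated, unmethylated) intensity pairs.

    Expects a probe_id index column then two columns per sample named
    ``<sample>.methy`` and ``<sample>.umethy``.  Negative (background
    corrected) intensities are kept as-is; the beta transform clamps later.
    Returns a frame with a two-level column index (sample, channel).
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    if raw.shape[1] % 2 != 0:
        raise ValueError(f"intensity table has odd column count ({raw.shape[1]})")
    samples, channels = [], []
    for col in raw.columns:
        base, _, chan = col.rpartition(".")
        if chan not in {"methy", "umethy"} or not base:
            raise ValueError(f"intensity column {col!r} not of the form <sample>.methy/.umethy")
        samples.append(base)
        channels.append(chan)
    raw.columns = pd.MultiIndex.from_arrays([samples, channels], names=["sample", "channel"])
    raw.index.name = "probe_id"
    return raw.astype(float)


def read_enhancers(path) -> EnhancerSet:
    """Read a BED3+ enhancer file (0-based half-open) into internal coordinates.

    Missing names get the id ``chrom:start-end`` (BED coordinates).  The center
    is the floor midpoint of the BED interval.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"BED line {ln}: fewer than 3 columns")
            chrom, bstart, bend = parts[0], int(parts[1]), int(parts[2])
            if bstart >= bend:
                raise ValueError(f"BED line {ln}: start {bstart} >= end {bend}")
            eid = parts[3] if len(parts) > 3 and parts[3] not in {"", "."} else f"{chrom}:{bstart}-{bend}"
            start, end = bed_to_internal(bstart, bend)
            center = (bstart + bend) // 2
            rows.append((eid, chrom, start, end, center))
    t = pd.DataFrame(rows, columns=["enhancer_id", "chrom", "start", "end", "center"])
    return EnhancerSet(t)


def read_gene_annotation(path) -> GeneAnnotation:
    """Read a 6-column gene-model TSV.

    Columns: gene_id, symbol, chrom, strand, tss, regions.  The regions cell
    encodes interval lists as ``kind:start-end,start-end|kind:...`` in 1-based
    inclusive coordinates; it may be empty.
    """
    t = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    t["tss"] = t["tss"].astype(np.int64)
    regions: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for gid, cell in zip(t["gene_id"], t.get("regions", pd.Series([""] * len(t)))):
        per_gene: dict[str, list[tuple[int, int]]] = {}
        if cell:
            for block in cell.split("|"):
                kind, _, ivs = block.partition(":")
                per_gene[kind] = [
                    (int(a), int(b)) for a, b in (iv.split("-") for iv in ivs.split(","))
                ]
        regions[gid] = per_gene
    genes = t[["gene_id", "symbol", "chrom", "strand", "tss"]]
    return GeneAnnotation(genes, regions)


def read_gene_list(path) -> set[str]:
    """One symbol per line; blank lines and # comments ignored."""
    out = set()
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s and not s.startswith("#"):
                out.add(s)
    return out


def read_cancer_gene_sets(oncogene_path, tsg_path) -> CancerGeneSets:
    return CancerGeneSets(read_gene_list(oncogene_path), read_gene_list(tsg_path))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


def write_counts(counts: CountMatrix, path) -> None:
    counts.values.to_csv(path, sep="\t", index_label="gene_id")


def write_beta_table(beta: BetaMatrix, path) -> None:
    beta.values.to_csv(path, sep="\t", index_label="probe_id", na_rep="NA", float_format="%.10g")


def write_probe_manifest(manifest: ProbeManifest, path) -> None:
    manifest.table.to_csv(path, sep="\t", index=False)


def write_enhancers(enhancers: EnhancerSet, path) -> None:
    """Write BED6-style (name in column 4) with coordinates converted back."""
    with open(path, "w") as fh:
        for row in enhancers.table.itertuples(index=False):
            bstart, bend = internal_to_bed(row.start, row.end)
            fh.write(f"{row.chrom}\t{bstart}\t{bend}\t{row.enhancer_id}\n")


def write_gene_annotation(ann: GeneAnnotation, path) -> None:
    rows = []
    for row in ann.genes.itertuples(index=False):
        per_gene = ann.regions.get(row.gene_id, {})
        cell = "|".join(
            f"{kind}:" + ",".join(f"{a}-{b}" for a, b in ivs)
            for kind, ivs in per_gene.items()
        )
        rows.append((row.gene_id, row.symbol, row.chrom, row.strand, row.tss, cell))
    pd.DataFrame(
        rows, columns=["gene_id", "symbol", "chrom", "strand", "tss", "regions"]
    ).to_csv(path, sep="\t", index=False)


def write_gene_list(symbols: set[str], path) -> None:
    with open(path, "w") as fh:
        for s in sorted(symbols):
            fh.write(s + "\n")
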