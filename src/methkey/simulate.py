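"""Seeded synthetic matched tumor/normal methylation + expression studies.

The generator emulates the statistical structure the pipeline assumes:

* matched cancer/paracancer pairs plus unmatched extra samples of both kinds;
* negative-binomial RNA-seq counts around log-normal gene baselines, with
  per-sample library-size factors;
* beta-distributed HM450K-style probe methylation (bounded, heteroskedastic),
  with probe density 6x higher in promoter bins 14-17, mirroring the dense
  probe coverage of CpG-island TSSs;
* planted gene classes — D-Hyper (down-regulated, promoter hypermethylated in
  the key bins), U-Hypo (the mirror image), DME (enhancer-only methylation
  shift whose per-patient magnitude is anti-monotone in that patient's
  expression ratio), and null;
* decoy enhancers near non-DME genes, a sprinkle of non-CpG probes and NA
  cells, and oncogene/TSG lists overlapping the planted classes.

Everything flows from one ``numpy`` generator seeded by ``SimConfig.seed``:
identical configs produce byte-identical studies.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as mio
from .io import (
    BetaMatrix,
    CancerGeneSets,
    CountMatrix,
    EnhancerSet,
    GeneAnnotation,
    ProbeManifest,
    SampleSheet,
)
from .regions import KEY_BINS, PROMOTER_BIN_BP, PROMOTER_BINS

CHROM = "chrS"
GENE_SPACING = 50_000
FIRST_TSS = 100_000
#: probe-density multiplier for the key bins (TSS +- 200 bp)
KEY_BIN_DENSITY = 6.0


@dataclass
class SimConfig:
    """Knobs of the synthetic study; defaults are the reference conditions."""

    seed: int = 0
    n_genes: int = 300
    n_matched_pairs: int = 9
    n_extra_cancer: int = 12
    n_extra_para: int = 3
    probes_per_promoter_bin: float = 1.0
    frac_dhyper: float = 0.1
    frac_uhypo: float = 0.1
    frac_dme: float = 0.1
    frac_null: float = 0.7
    lfc_mean: float = 1.5
    beta_shift: float = 0.25
    nb_dispersion: float = 0.1
    beta_concentration: float = 50.0
    key_bin_only: bool = True
    na_frac: float = 0.002
    non_cpg_frac: float = 0.02

    def __post_init__(self) -> None:
        total = self.frac_dhyper + self.frac_uhypo + self.frac_dme + self.frac_null
        if total > 1 + 1e-9:
            raise ValueError(f"gene fractions sum to {total} > 1")
        if self.n_matched_pairs < 3:
            raise ValueError("need >= 3 matched pairs (rank correlation needs >= 3 points)")


@dataclass
class GroundTruth:
    """Planted per-gene labels and effect sizes."""

    table: pd.DataFrame  # gene_id -> label, lfc, beta_shift, causal_enhancer

    def genes_with_label(self, label: str) -> list[str]:
        t = self.table
        return list(t.index[t["label"] == label])


@dataclass
class SyntheticStudy:
    sheet: SampleSheet
    counts: CountMatrix
    beta: BetaMatrix
    manifest: ProbeManifest
    annotation: GeneAnnotation
    enhancers: EnhancerSet
    cancer_sets: CancerGeneSets
    truth: GroundTruth


def _labels(cfg: SimConfig) -> list[str]:
    n = cfg.n_genes
    n_dh = round(cfg.frac_dhyper * n)
    n_uh = round(cfg.frac_uhypo * n)
    n_dme = round(cfg.frac_dme * n)
    labels = (["D-Hyper"] * n_dh + ["U-Hypo"] * n_uh + ["DME"] * n_dme)
    labels += ["null"] * (n - len(labels))
    return labels


def _sample_sheet(cfg: SimConfig) -> SampleSheet:
    rows = []
    for i in range(cfg.n_matched_pairs):
        rows.append((f"T{i:03d}", f"P{i:03d}", "cancer"))
        rows.append((f"N{i:03d}", f"P{i:03d}", "paracancer"))
    for i in range(cfg.n_extra_cancer):
        rows.append((f"TX{i:03d}", f"PX{i:03d}", "cancer"))
    for i in range(cfg.n_extra_para):
        rows.append((f"NX{i:03d}", f"PY{i:03d}", "paracancer"))
    return SampleSheet(pd.DataFrame(rows, columns=["sample_id", "patient_id", "condition"]))


def _gene_models(cfg: SimConfig, rng: np.random.Generator) -> GeneAnnotation:
    """Genes tiled every 50 kb on one toy chromosome, random strand.

    Each gene gets a small fixed-shape model downstream of its TSS in
    transcription orientation: 5'UTR (200 bp), two exons with an intron,
    a 3'UTR and a detached intergenic block.
    """
    rows, regions = [], {}
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    for g in range(cfg.n_genes):
        gid = f"g{g:04d}"
        sym = f"GENE{g:04d}"
        tss = FIRST_TSS + g * GENE_SPACING
        strand = strands[g]
        sgn = 1 if strand == "+" else -1

        def iv(a: int, b: int) -> tuple[int, int]:
            x, y = tss + sgn * a, tss + sgn * b
            return (x, y) if x <= y else (y, x)

        regions[gid] = {
            "utr5": [iv(0, 199)],
            "exon": [iv(0, 199), iv(1000, 1499)],
            "intron": [iv(200, 999)],
            "utr3": [iv(1500, 1799)],
            "intergenic": [iv(5000, 6999)],
        }
        rows.append((gid, sym, CHROM, strand, tss))
    genes = pd.DataFrame(rows, columns=["gene_id", "symbol", "chrom", "strand", "tss"])
    return GeneAnnotation(genes, regions)


def _place_probes(
    cfg: SimConfig, rng: np.random.Generator, ann: GeneAnnotation, labels: list[str]
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Probe manifest plus index arrays of planted-effect probe groups."""
    half = PROMOTER_BINS * PROMOTER_BIN_BP // 2
    probe_rows = []  # (chrom, pos, is_cpg, kind, gene_idx, bin)
    for g, row in enumerate(ann.genes.itertuples(index=False)):
        sgn = 1 if row.strand == "+" else -1
        for mu in range(1, PROMOTER_BINS + 1):
            lo = -half + PROMOTER_BIN_BP * (mu - 1)  # bin covers (lo, lo+100]
            mean = cfg.probes_per_promoter_bin * (KEY_BIN_DENSITY if mu in KEY_BINS else 1.0)
            for _ in range(rng.poisson(mean)):
                off = int(rng.integers(lo + 1, lo + PROMOTER_BIN_BP + 1))
                probe_rows.append((CHROM, row.tss + sgn * off, True, "promoter", g, mu))
        for kind, ivs in ann.regions[row.gene_id].items():
            for s, e in ivs:
                for _ in range(rng.poisson(1.0)):
                    pos = int(rng.integers(s, e + 1))
                    probe_rows.append((CHROM, pos, True, kind, g, 0))
    manifest = pd.DataFrame(
        probe_rows, columns=["chrom", "pos", "is_cpg", "kind", "gene_idx", "bin"]
    )
    # a sprinkle of non-CpG probes at random positions (removed by QC)
    n_noncpg = round(cfg.non_cpg_frac * len(manifest))
    span_hi = FIRST_TSS + cfg.n_genes * GENE_SPACING
    noncpg = pd.DataFrame(
        {
            "chrom": CHROM,
            "pos": rng.integers(1000, span_hi, size=n_noncpg),
            "is_cpg": False,
            "kind": "noncpg",
            "gene_idx": -1,
            "bin": 0,
        }
    )
    manifest = pd.concat([manifest, noncpg], ignore_index=True)
    manifest.insert(0, "probe_id", [f"cg{i:07d}" for i in range(len(manifest))])
    return manifest, {}


def _place_enhancers(
    cfg: SimConfig, rng: np.random.Generator, ann: GeneAnnotation, labels: list[str]
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Causal enhancers 5-20 kb from their DME gene's TSS, plus decoys.

    Gene tiles are 50 kb apart, so any enhancer within 25 kb of its gene's TSS
    has that gene as unambiguous nearest-TSS target.
    """
    rows = []
    causal: dict[str, str] = {}
    e = 0
    dme_idx = [i for i, lab in enumerate(labels) if lab == "DME"]
    null_idx = [i for i, lab in enumerate(labels) if lab == "null"]
    n_decoys = max(1, len(dme_idx) // 2)
    decoy_idx = list(rng.choice(null_idx, size=min(n_decoys, len(null_idx)), replace=False))
    for g in dme_idx + decoy_idx:
        tss = int(ann.genes["tss"].iloc[g])
        length = int(rng.integers(300, 801))
        dist = int(rng.integers(5_000, 20_001))
        side = 1 if rng.random() < 0.5 else -1
        center = tss + side * dist
        start = center - length // 2
        end = start + length - 1  # internal 1-based inclusive
        eid = f"e{e:04d}"
        rows.append((eid, CHROM, start, end, (start - 1 + end) // 2))
        if g in dme_idx:
            causal[ann.genes["gene_id"].iloc[g]] = eid
        e += 1
    table = pd.DataFrame(rows, columns=["enhancer_id", "chrom", "start", "end", "center"])
    return table, causal


def _enhancer_probes(
    rng: np.random.Generator, enh_table: pd.DataFrame, next_id: int
) -> pd.DataFrame:
    rows = []
    for row in enh_table.itertuples(index=False):
        for _ in range(int(rng.integers(2, 5))):
            pos = int(rng.integers(row.start, row.end + 1))
            rows.append((CHROM, pos, True, "enhancer", -1, 0, row.enhancer_id))
    out = pd.DataFrame(
        rows, columns=["chrom", "pos", "is_cpg", "kind", "gene_idx", "bin", "enhancer_id"]
    )
    out.insert(0, "probe_id", [f"cg{next_id + i:07d}" for i in range(len(out))])
    return out


def simulate_study(cfg: SimConfig) -> SyntheticStudy:
    """Generate the complete study with planted ground truth."""
    rng = np.random.default_rng(cfg.seed)
    labels = _labels(cfg)
    sheet = _sample_sheet(cfg)
    ann = _gene_models(cfg, rng)
    manifest_df, _ = _place_probes(cfg, rng, ann, labels)
    enh_table, causal = _place_enhancers(cfg, rng, ann, labels)
    enh_probes = _enhancer_probes(rng, enh_table, len(manifest_df))
    manifest_df = pd.concat([manifest_df, enh_probes], ignore_index=True)
    manifest_df["enhancer_id"] = manifest_df.get("enhancer_id").fillna("")

    samples = sheet.sample_ids
    cancer_mask = np.array([c == "cancer" for c in sheet.table["condition"]])
    pairs = sheet.matched_pairs()
    sample_pos = {s: i for i, s in enumerate(samples)}

    # ---- expression ------------------------------------------------------
    base_mu = np.exp(rng.normal(np.log(200.0), 1.0, size=cfg.n_genes))
    lib = np.exp(rng.normal(0.0, 0.15, size=len(samples)))
    lfc = np.zeros((cfg.n_genes, len(samples)))  # log2 effect per gene x sample
    # per-patient latent severity for DME genes: u in (0,1)
    u_dme: dict[tuple[int, str], float] = {}
    for g, lab in enumerate(labels):
        if lab == "D-Hyper":
            lfc[g, cancer_mask] = -cfg.lfc_mean
        elif lab == "U-Hypo":
            lfc[g, cancer_mask] = cfg.lfc_mean
        elif lab == "DME":
            lfc[g, cancer_mask] = 0.0  # unmatched cancer samples: no net shift
            for prow in pairs.itertuples(index=False):
                u = float(rng.random())
                u_dme[(g, prow.patient_id)] = u
                lfc[g, sample_pos[prow.cancer]] = cfg.lfc_mean * (2.0 * u - 1.0)
    mu = base_mu[:, None] * (2.0 ** lfc) * lib[None, :]
    r = 1.0 / cfg.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    count_df = pd.DataFrame(
        counts.astype(np.int64),
        index=pd.Index(ann.genes["gene_id"], name="gene_id"),
        columns=samples,
    )

    # ---- methylation -----------------------------------------------------
    kind = manifest_df["kind"].to_numpy()
    gene_idx = manifest_df["gene_idx"].to_numpy()
    bins = manifest_df["bin"].to_numpy()
    n_probes = len(manifest_df)
    base_beta = np.empty(n_probes)
    label_of_probe = np.array(
        [labels[g] if g >= 0 else "none" for g in gene_idx], dtype=object
    )
    is_prom = kind == "promoter"
    base_beta[:] = rng.uniform(0.4, 0.8, size=n_probes)  # gene body / intergenic default
    base_beta[is_prom] = rng.uniform(0.15, 0.5, size=int(is_prom.sum()))
    sel = is_prom & (label_of_probe == "D-Hyper")
    base_beta[sel] = rng.uniform(0.15, 0.35, size=int(sel.sum()))
    sel = is_prom & (label_of_probe == "U-Hypo")
    base_beta[sel] = rng.uniform(0.45, 0.6, size=int(sel.sum()))
    is_enh = kind == "enhancer"
    base_beta[is_enh] = rng.uniform(0.25, 0.45, size=int(is_enh.sum()))

    mean = np.tile(base_beta[:, None], (1, len(samples)))
    in_key = np.isin(bins, KEY_BINS)
    planted_prom = in_key if cfg.key_bin_only else is_prom

    shift = np.zeros(n_probes)
    shift[planted_prom & (label_of_probe == "D-Hyper")] = cfg.beta_shift
    shift[planted_prom & (label_of_probe == "U-Hypo")] = -cfg.beta_shift
    mean[:, cancer_mask] += shift[:, None]

    # Enhancer shifts: each matched patient's cancer sample gets a shift
    # magnitude that decreases with that patient's realized expression ratio
    # for the target gene (rank-assigned, plus jitter), so enhancer RD is
    # anti-monotone in patient FC by construction; unmatched cancer samples
    # get the mean effect so the pooled RD screen sees the shift.
    enh_ids = manifest_df["enhancer_id"].to_numpy()
    gid_list = list(ann.genes["gene_id"])
    causal_rev = {eid: gid for gid, eid in causal.items()}
    n_pairs = len(pairs)
    shift_of: dict[tuple[str, str], float] = {}  # (gene_id, cancer sample) -> shift
    for gid, eid in causal.items():
        ratios = np.array(
            [
                (count_df.at[gid, prow.cancer] + 1.0) / (count_df.at[gid, prow.paracancer] + 1.0)
                for prow in pairs.itertuples(index=False)
            ]
        )
        # highest-FC patient gets the smallest shift: rank descending
        order = np.argsort(np.argsort(-ratios))  # 0 = largest ratio
        for k, prow in enumerate(pairs.itertuples(index=False)):
            frac = order[k] / max(n_pairs - 1, 1)  # 0 for largest FC .. 1 for smallest
            d = cfg.beta_shift * (0.2 + 0.8 * frac) + rng.normal(0.0, 0.02)
            shift_of[(gid, prow.cancer)] = max(d, 0.02)
    patient_of = dict(zip(sheet.table["sample_id"], sheet.table["patient_id"]))
    matched_cancer = set(pairs["cancer"])
    for p in np.flatnonzero(is_enh):
        gid = causal_rev.get(enh_ids[p])
        if gid is None:
            continue  # decoy enhancer: no shift
        for s_i, (sname, is_c) in enumerate(zip(samples, cancer_mask)):
            if not is_c:
                continue
            if sname in matched_cancer:
                d = shift_of[(gid, sname)]
            else:
                d = cfg.beta_shift * 0.6
            mean[p, s_i] += d

    mean = np.clip(mean, 0.02, 0.98)
    c = cfg.beta_concentration
    beta_vals = rng.beta(c * mean, c * (1.0 - mean))
    na = rng.random(beta_vals.shape) < cfg.na_frac
    beta_vals[na] = np.nan
    beta_df = pd.DataFrame(
        beta_vals, index=pd.Index(manifest_df["probe_id"], name="probe_id"), columns=samples
    )

    manifest = ProbeManifest(
        manifest_df[["probe_id", "chrom", "pos", "is_cpg"]].copy()
    )
    beta = BetaMatrix(beta_df, manifest)
    counts_obj = CountMatrix(count_df, sheet)
    enhancers = EnhancerSet(enh_table)

    # ---- cancer gene sets ------------------------------------------------
    sym = list(ann.genes["symbol"])
    onco, tsg = set(), set()
    null_syms = [sym[i] for i, lab in enumerate(labels) if lab == "null"]
    for i, lab in enumerate(labels):
        if lab == "U-Hypo" and i % 2 == 0:
            onco.add(sym[i])
        if lab == "D-Hyper" and i % 2 == 0:
            tsg.add(sym[i])
        if lab == "DME" and i % 3 == 0:
            tsg.add(sym[i])
    # decoy members and one deliberate overlap
    onco.update(null_syms[:3])
    tsg.update(null_syms[3:6])
    if null_syms:
        onco.add(null_syms[0])
        tsg.add(null_syms[0])
    cancer_sets = CancerGeneSets(onco, tsg)

    truth = pd.DataFrame(
        {
            "gene_id": gid_list,
            "label": labels,
            "lfc": [
                -cfg.lfc_mean if l == "D-Hyper" else (cfg.lfc_mean if l == "U-Hypo" else 0.0)
                for l in labels
            ],
            "beta_shift": [
                cfg.beta_shift if l == "D-Hyper" else (-cfg.beta_shift if l == "U-Hypo" else 0.0)
                for l in labels
            ],
            "causal_enhancer": [causal.get(g, "") for g in gid_list],
        }
    ).set_index("gene_id")

    return SyntheticStudy(
        sheet, counts_obj, beta, manifest, ann, enhancers, cancer_sets, GroundTruth(truth)
    )


def summarize_truth(truth: GroundTruth) -> pd.DataFrame:
    """Planted gene counts per label; every label row is present, even at 0."""
    counts = truth.table["label"].value_counts()
    rows = [(lab, int(counts.get(lab, 0))) for lab in ("D-Hyper", "U-Hypo", "DME", "null")]
    return pd.DataFrame(rows, columns=["label", "n_genes"]).set_index("label")


def write_study(study: SyntheticStudy, out_dir) -> None:
    """Write every study table (TSV/BED/plain text) plus ground_truth.tsv."""
    os.makedirs(out_dir, exist_ok=True)
    j = lambda name: os.path.join(out_dir, name)
    mio.write_sample_sheet(study.sheet, j("samples.tsv"))
    mio.write_counts(study.counts, j("counts.tsv"))
    mio.write_beta_table(study.beta, j("beta.tsv"))
    mio.write_probe_manifest(study.manifest, j("manifest.tsv"))
    mio.write_gene_annotation(study.annotation, j("genes.tsv"))
    mio.write_enhancers(study.enhancers, j("enhancers.bed"))
    mio.write_gene_list(study.cancer_sets.oncogenes, j("oncogenes.txt"))
    mio.write_gene_list(study.cancer_sets.tsgs, j("tsgs.txt"))
    study.truth.table.to_csv(j("ground_truth.tsv"), sep="\t")


def read_study(in_dir) -> SyntheticStudy:
    """Load a study written by :func:`write_study` back into memory."""
    j = lambda name: os.path.join(in_dir, name)
    sheet = mio.read_sample_sheet(j("samples.tsv"))
    counts = mio.read_counts(j("counts.tsv"), sheet)
    manifest = mio.read_probe_manifest(j("manifest.tsv"))
    beta = mio.read_beta_table(j("beta.tsv"), manifest)
    ann = mio.read_gene_annotation(j("genes.tsv"))
    enhancers = mio.read_enhancers(j("enhancers.bed"))
    sets = mio.read_cancer_gene_sets(j("oncogenes.txt"), j("tsgs.txt"))
    truth = GroundTruth(pd.read_csv(j("ground_truth.tsv"), sep="\t", index_col=0, keep_default_na=False))
    return SyntheticStudy(sheet, counts, beta, manifest, ann, enhancers, sets, truth)
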