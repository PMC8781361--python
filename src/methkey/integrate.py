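"""Combine DE, promoter methylation, bin profiles and DME calls into gene
classes (U-Hypo, D-Hyper, DME), cancer-gene intersections and key-gene
candidates.

U-Hypo = up-regulated AND promoter hypomethylated; D-Hyper = down-regulated
AND promoter hypermethylated (promoter methylation represses expression, so
only the discordant combinations are kept).  Candidates are class members that
are also in a curated oncogene/TSG list and abnormally methylated in at least
one key promoter bin (TSS +- 200 bp).  Role/direction concordance (oncogenes
expected U-Hypo, TSGs D-Hyper) is reported as a column, never used as a
filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .enhancers import DMEResult, call_dme
from .expression import DEResult, de_test, normalize, size_factors
from .io import CancerGeneSets, GeneAnnotation
from .methylation import GeneMethylation, filter_probes, gene_promoter_beta
from .regions import bin_profile, bin_rd, key_bin_filter

logger = logging.getLogger("methkey")


@dataclass
class GeneClassTable:
    table: pd.DataFrame

    def genes_in_class(self, cls: str) -> set[str]:
        t = self.table
        return set(t.index[t[cls]])


def classify_genes(
    de: DEResult, meth: GeneMethylation, dme: DMEResult | None = None
) -> GeneClassTable:
    """Per-gene class table over the shared gene universe."""
    idx = de.table.index.intersection(meth.table.index)
    t = pd.DataFrame(index=idx)
    t["de_status"] = de.table.loc[idx, "status"]
    t["promoter_meth_status"] = meth.table.loc[idx, "status"]
    t["is_U_Hypo"] = (t["de_status"] == "up") & (t["promoter_meth_status"] == "hypo")
    t["is_D_Hyper"] = (t["de_status"] == "down") & (t["promoter_meth_status"] == "hyper")
    dme_genes = dme.dme_genes if dme is not None else set()
    t["is_DME_gene"] = t.index.isin(dme_genes)
    return GeneClassTable(t)


def candidate_key_genes(
    table: GeneClassTable,
    cancer_sets: CancerGeneSets,
    key_flags: set[str],
    annotation: GeneAnnotation,
) -> pd.DataFrame:
    """Candidate key genes: class member + cancer-gene listed + key-bin abnormal.

    Adds the cancer role (oncogene / TSG / both / none) by symbol lookup and a
    ``role_concordant`` report column (oncogene with U-Hypo, TSG with D-Hyper).
    Unmapped cancer-set symbols are logged, never fatal.
    """
    t = table.table.copy()
    sym_map = annotation.symbol_to_id()
    id_of = {gid: sym for sym, gid in sym_map.items()}
    unmapped = (cancer_sets.oncogenes | cancer_sets.tsgs) - set(sym_map)
    if unmapped:
        logger.info("%d cancer-set symbol(s) not in the annotation", len(unmapped))
    onco_ids = {sym_map[s] for s in cancer_sets.oncogenes if s in sym_map}
    tsg_ids = {sym_map[s] for s in cancer_sets.tsgs if s in sym_map}

    def role(gid: str) -> str:
        o, ts = gid in onco_ids, gid in tsg_ids
        if o and ts:
            return "both"
        return "oncogene" if o else ("TSG" if ts else "none")

    t["symbol"] = [id_of.get(g, "") for g in t.index]
    t["cancer_role"] = [role(g) for g in t.index]
    t["key_bin_abnormal"] = t.index.isin(key_flags)
    in_class = t["is_U_Hypo"] | t["is_D_Hyper"] | t["is_DME_gene"]
    t["candidate"] = in_class & (t["cancer_role"] != "none") & t["key_bin_abnormal"]
    t["role_concordant"] = (
        (t["cancer_role"].isin(["oncogene", "both"]) & t["is_U_Hypo"])
        | (t["cancer_role"].isin(["TSG", "both"]) & t["is_D_Hyper"])
    )
    return t


def report(table: pd.DataFrame, dme: DMEResult | None = None) -> dict[str, int]:
    """Summary counts mirroring the pipeline's intersection figures."""
    out = {
        "n_genes": len(table),
        "n_up": int((table["de_status"] == "up").sum()),
        "n_down": int((table["de_status"] == "down").sum()),
        "n_hyper": int((table["promoter_meth_status"] == "hyper").sum()),
        "n_hypo": int((table["promoter_meth_status"] == "hypo").sum()),
        "n_U_Hypo": int(table["is_U_Hypo"].sum()),
        "n_D_Hyper": int(table["is_D_Hyper"].sum()),
        "n_DME_genes": int(table["is_DME_gene"].sum()),
        "n_DME_pairs": int(dme.pairs["call"].sum()) if dme is not None else 0,
        "n_oncogene_candidates": int(
            (table["candidate"] & table["cancer_role"].isin(["oncogene", "both"])).sum()
        ),
        "n_TSG_candidates": int(
            (table["candidate"] & table["cancer_role"].isin(["TSG", "both"])).sum()
        ),
        "n_candidates": int(table["candidate"].sum()),
    }
    return out


@dataclass
class PipelineResult:
    de: DEResult
    meth: GeneMethylation
    profile: pd.DataFrame
    dme: DMEResult
    classes: GeneClassTable
    candidates: pd.DataFrame
    summary: dict[str, int]


def run_study(study) -> PipelineResult:
    """Run the full pipeline on an in-memory study (synthetic or loaded)."""
    factors = size_factors(study.counts)
    norm = normalize(study.counts, factors)
    de = de_test(norm, study.sheet)
    beta_qc, _ = filter_probes(study.beta)
    meth = gene_promoter_beta(beta_qc, study.annotation, study.sheet)
    prof = bin_rd(
        bin_profile(beta_qc, study.annotation, study.sheet, regions=("promoter",))
    )
    dme = call_dme(
        beta_qc, norm, study.sheet, study.enhancers, study.annotation, meth
    )
    classes = classify_genes(de, meth, dme)
    key_flags = key_bin_filter(prof, set(classes.table.index))
    candidates = candidate_key_genes(classes, study.cancer_sets, key_flags, study.annotation)
    summary = report(candidates, dme)
    return PipelineResult(de, meth, prof, dme, classes, candidates, summary)
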