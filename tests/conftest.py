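import logging

import numpy as np
import pandas as pd
import pytest

from methkey import SimConfig, run_study, simulate_study
from methkey.io import BetaMatrix, GeneAnnotation, ProbeManifest, SampleSheet

logging.getLogger("methkey").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def default_study():
    return simulate_study(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_result(default_study):
    return run_study(default_study)


def tiny_sheet(n_cancer=2, n_para=2) -> SampleSheet:
    rows = [(f"T{i}", f"P{i}", "cancer") for i in range(n_cancer)]
    rows += [(f"N{i}", f"P{i}", "paracancer") for i in range(n_para)]
    return SampleSheet(pd.DataFrame(rows, columns=["sample_id", "patient_id", "condition"]))


def random_beta_setup(rng, n_genes=5, n_probes=60, n_cancer=3, n_para=2):
    """A small random (BetaMatrix, GeneAnnotation, SampleSheet) triple."""
    sheet = tiny_sheet(n_cancer, n_para)
    tss = np.sort(rng.choice(np.arange(10_000, 200_000, 7_000), size=n_genes, replace=False))
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n_genes)],
            "symbol": [f"G{i}" for i in range(n_genes)],
            "chrom": "chrT",
            "strand": rng.choice(["+", "-"], size=n_genes),
            "tss": tss,
        }
    )
    ann = GeneAnnotation(genes, {g: {} for g in genes["gene_id"]})
    pos = rng.integers(5_000, 210_000, size=n_probes)
    manifest = ProbeManifest(
        pd.DataFrame(
            {
                "probe_id": [f"cg{i:05d}" for i in range(n_probes)],
                "chrom": "chrT",
                "pos": pos,
                "is_cpg": True,
            }
        )
    )
    values = pd.DataFrame(
        rng.uniform(0, 1, size=(n_probes, len(sheet.sample_ids))),
        index=pd.Index([f"cg{i:05d}" for i in range(n_probes)], name="probe_id"),
        columns=sheet.sample_ids,
    )
    return BetaMatrix(values, manifest), ann, sheet
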