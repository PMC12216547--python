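import numpy as np
import pandas as pd
import pytest

from devodyn.omics_io import ExpressionMatrix, SampleSheet, Scale
from devodyn.synthetic_data import SimConfig, simulate_paired


@pytest.fixture(scope="session")
def small_sim():
    """500-gene default-condition simulation shared across read-only tests."""
    return simulate_paired(SimConfig(n_genes=500, seed=1))


@pytest.fixture()
def tiny_sheet():
    rows = []
    for tp, stage in (("E1", "egg"), ("E2", "egg"), ("L1", "larva"),
                      ("P1", "pupa"), ("A1", "adult")):
        for rep in (1, 2):
            rows.append({"sample_id": f"{tp}_r{rep}", "timepoint": tp,
                         "stage": stage, "replicate": rep, "species": "A"})
    return SampleSheet(pd.DataFrame(rows))


@pytest.fixture()
def tiny_matrix(tiny_sheet):
    rng = np.random.default_rng(0)
    vals = pd.DataFrame(rng.normal(25, 2, size=(20, 10)),
                        index=[f"g{i}" for i in range(20)],
                        columns=tiny_sheet.sample_ids)
    return ExpressionMatrix(vals, Scale.lfq_log2)
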