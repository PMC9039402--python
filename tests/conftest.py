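import numpy as np
import pandas as pd
import pytest

from cernet.ingest import ClinicalTable, ExpressionMatrix
from cernet.synthdata import SynthConfig, generate_study


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic study shared by read-only tests."""
    cfg = SynthConfig(
        n_tumor=40,
        n_normal=10,
        n_mirna=40,
        n_lncrna=30,
        n_mrna=80,
        n_true_edges=40,
        n_triplets=4,
        n_prognostic=3,
        seed=11,
    )
    return generate_study(cfg)


@pytest.fixture
def toy_expression():
    """4 features × 5 samples log2 matrix with hand-picked values."""
    vals = pd.DataFrame(
        [
            [3.0, 1.0, 4.0, 1.0, 5.0],
            [2.0, 7.0, 1.0, 8.0, 2.0],
            [1.0, 2.0, 3.0, 4.0, 5.0],
            [5.0, 4.0, 3.0, 2.0, 1.0],
        ],
        index=["f1", "f2", "f3", "f4"],
        columns=[f"s{i}" for i in range(1, 6)],
    )
    return ExpressionMatrix(vals, "mRNA", "log2")


@pytest.fixture
def toy_clinical():
    return ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": [f"p{i}" for i in range(1, 5)],
                "time": [1.0, 2.0, 3.0, 4.0],
                "event": [1, 1, 1, 1],
            }
        )
    )
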