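import numpy as np
import pandas as pd
import pytest

from quiescreen.expression import ExpressionMatrix
from quiescreen.synthetic_data import CohortSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """Desk-scale cohort spec for fast unit tests."""
    return CohortSpec(n_genes=40, n_probes=30, module_size=5, seed=7)


@pytest.fixture
def two_group_matrix(rng):
    """Null two-group expression matrix: 30 genes x (6 + 8) samples."""
    genes = [f"G{i:03d}" for i in range(30)]
    samples = [f"A{i}" for i in range(6)] + [f"B{i}" for i in range(8)]
    values = pd.DataFrame(rng.normal(7.0, 1.0, (30, 14)), index=genes, columns=samples)
    labels = pd.Series(["a"] * 6 + ["b"] * 8, index=samples)
    return ExpressionMatrix(values, labels)
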