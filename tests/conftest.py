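import numpy as np
import pandas as pd
import pytest

from sfcomod.io import ExpressionMatrix
from sfcomod.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [6.0, 4.0, 2.0, 0.0], [1.0, 3.0, 2.0, 4.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(data)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured cohort shared across tests."""
    cfg = SyntheticConfig(
        n_samples=150,
        panel_size=80,
        n_suppressor=25,
        n_enhancer=15,
        n_background=200,
        n_null_background=50,
        n_matched_pairs=40,
        n_switch_genes=15,
        n_nonswitch_genes=15,
        seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
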