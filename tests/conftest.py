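import warnings

import numpy as np
import pytest

import synthcohort as sc

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def schema():
    return sc.default_schema()


@pytest.fixture(scope="session")
def true_model():
    return sc.default_true_model()


@pytest.fixture(scope="session")
def cohort_2k(schema, true_model):
    """Small simulated cohort with outcomes (shared across tests)."""
    cov = sc.simulate_covariates(schema, 2000, 11)
    return sc.simulate_outcomes(cov, true_model, 12)


@pytest.fixture(scope="session")
def covariates_10k(schema):
    return sc.simulate_covariates(schema, 10_000, 0)


@pytest.fixture(scope="session")
def toy_matrix():
    """Tiny handmade encoded table: one continuous column + one 2-level block."""
    from synthcohort.preprocess import ColumnInfo, EncodedMatrix

    rng = np.random.default_rng(0)
    n = 5000
    x = rng.beta(4, 6, n)
    cat = (rng.uniform(size=n) < 0.3).astype(float)
    vals = np.column_stack([x, cat, 1 - cat])
    layout = [ColumnInfo("x", "x", "continuous"),
              ColumnInfo("c=a", "c", "onehot", "a"),
              ColumnInfo("c=b", "c", "onehot", "b")]
    return EncodedMatrix(vals, ["x", "c=a", "c=b"], layout)
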