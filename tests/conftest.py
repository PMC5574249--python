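import numpy as np
import pandas as pd
import pytest

from brcaness import DiscoverySimConfig, ExpressionMatrix, LabeledCohort, simulate_discovery


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_matrix(rng):
    """20 genes x 6 samples, complete, two batches."""
    values = pd.DataFrame(
        rng.normal(8, 1, size=(20, 6)),
        index=[f"g{i}" for i in range(20)],
        columns=[f"s{j}" for j in range(6)],
    )
    batch = pd.Series(["A", "A", "A", "B", "B", "B"], index=values.columns)
    return ExpressionMatrix(values=values, batch=batch)


@pytest.fixture
def toy_cohort(rng):
    """12 samples, 30 genes, 5 informative with a strong two-sided shift."""
    n_genes, n = 30, 12
    y = np.array([1, 0] * (n // 2))
    x = rng.normal(0, 1, size=(n_genes, n))
    signs = np.array([1, -1, 1, -1, 1], dtype=float)
    x[:5] += 2.0 * signs[:, None] * y[None, :]
    values = pd.DataFrame(x, index=[f"g{i}" for i in range(n_genes)],
                          columns=[f"s{j}" for j in range(n)])
    label = pd.Series(y, index=values.columns)
    return LabeledCohort(expr=ExpressionMatrix(values=values), label=label)


@pytest.fixture(scope="session")
def default_cohort_with_truth():
    """One default-condition synthetic discovery cohort, shared across tests."""
    return simulate_discovery(DiscoverySimConfig(seed=7), return_truth=True)
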