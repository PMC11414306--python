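import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import rumennet as rn

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_design():
    return rn.CohortDesign(n_per_group=5, seed=7)


@pytest.fixture(scope="session")
def small_planted():
    return rn.default_planted_structure(n_genes=300, n_leaf_taxa=8, n_de_per_contrast=10)


@pytest.fixture(scope="session")
def small_cohort(small_design, small_planted):
    return rn.simulate_cohort(small_design, planted=small_planted, n_genes=300, n_leaf_taxa=8)


@pytest.fixture(scope="session")
def study_cohort():
    """The default-condition cohort: 80 observations, 2000 genes, 60 taxa rows."""
    return rn.simulate_cohort(rn.CohortDesign(n_per_group=10, seed=11))


def profiles_with_correlation(C: np.ndarray, n_samples: int, labels=None) -> pd.DataFrame:
    """Rows whose sample correlation matrix equals C exactly.

    Builds zero-mean orthonormal basis rows (Helmert contrasts) and mixes them
    with the Cholesky factor of C, so corrcoef(result) == C to rounding.
    """
    k = C.shape[0]
    if n_samples < k + 1:
        raise ValueError("need n_samples > k")
    H = np.zeros((k, n_samples))
    for i in range(k):
        H[i, : i + 1] = 1.0
        H[i, i + 1] = -(i + 1)
        H[i] /= np.linalg.norm(H[i])
    L = np.linalg.cholesky(C)
    X = L @ H
    idx = labels if labels is not None else [f"n{i}" for i in range(k)]
    return pd.DataFrame(X, index=idx, columns=[f"s{j}" for j in range(n_samples)])
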