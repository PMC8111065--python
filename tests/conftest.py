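import numpy as np
import pandas as pd
import pytest

from csfomics.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort (22 vs 32, 60 proteins) with planted effects."""
    cfg = CohortConfig(
        n_proteins=60,
        n_informative_proteins=5,
        protein_effect=1.5,
        metabolite_effects={"myo-inositol": 1.0, "glucose": 0.8},
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def planted_matrix():
    """Two balanced classes, 5 of 10 features shifted by 2 pooled SD."""
    rng = np.random.default_rng(0)
    n = 30
    X = pd.DataFrame(
        rng.normal(size=(2 * n, 10)), columns=[f"f{i:02d}" for i in range(10)]
    )
    y = np.array([1] * n + [0] * n)
    X.iloc[:n, :5] += 2.0
    return X, y


@pytest.fixture()
def separable_clouds():
    """Two point clouds separated along the first axis (margin >> noise)."""
    rng = np.random.default_rng(3)
    n = 20
    X = rng.normal(scale=0.1, size=(2 * n, 4))
    X[:n, 0] += 5.0
    y = np.array([1] * n + [0] * n)
    return pd.DataFrame(X, columns=list("abcd")), y
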