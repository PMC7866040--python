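import numpy as np
import pandas as pd
import pytest

from breathlasso import generate_cohort, reference_cohort_spec


@pytest.fixture(scope="session")
def adk_cohort() -> pd.DataFrame:
    """Reference controls + lung-adenocarcinoma cohort (81 subjects)."""
    return generate_cohort(reference_cohort_spec("lung_adk", seed=42))


@pytest.fixture(scope="session")
def full_cohort() -> pd.DataFrame:
    """All four reference groups (158 subjects)."""
    return generate_cohort(reference_cohort_spec(None, seed=42))


def make_logistic_data(
    n: int,
    p: int,
    beta: np.ndarray | None = None,
    seed: int = 0,
    standardized: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Small logistic-model dataset with standardized design columns."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    if standardized:
        X = (X - X.mean(0)) / X.std(0, ddof=1)
    eta = np.zeros(n) if beta is None else X @ np.asarray(beta, float)
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    if y.sum() < 2:
        y[:2] = 1.0
    if y.sum() > n - 2:
        y[:2] = 0.0
    return X, y
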