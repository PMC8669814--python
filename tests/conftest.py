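import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from wakecomp.cohort import default_config, generate_cohort
from wakecomp.preprocess import build_analysis_table, impute_chained

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210930)


@pytest.fixture(scope="session")
def cohort_table() -> pd.DataFrame:
    """Mid-size synthetic cohort with the default missingness pattern."""
    table, _ = generate_cohort(default_config(n=400, seed=7))
    return table


@pytest.fixture(scope="session")
def analysis_table(cohort_table) -> pd.DataFrame:
    """Imputed, closed analysis table built once for the whole suite."""
    completed, _ = impute_chained(cohort_table, seed=7)
    return build_analysis_table(completed)


def random_simplex_points(n: int, rng: np.random.Generator) -> np.ndarray:
    """Strictly-positive random compositions (rows sum to 1)."""
    x = rng.dirichlet((2.0, 2.0, 2.0), size=n)
    return np.clip(x, 1e-9, None) / np.clip(x, 1e-9, None).sum(1, keepdims=True)
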