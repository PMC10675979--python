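import numpy as np
import pandas as pd
import pytest

from metascreen.io import CohortMatrix


def vector_with_moments(mean: float, sd: float, n: int) -> np.ndarray:
    """A deterministic vector with exact sample mean and SD (ddof=1)."""
    base = np.linspace(-1.0, 1.0, n)
    base = (base - base.mean()) / base.std(ddof=1)
    return mean + sd * base


@pytest.fixture
def moments_vector():
    return vector_with_moments


def make_cohort(values: dict[str, list[float]], n_tumor: int, cohort_id: str = "C1") -> CohortMatrix:
    """Small cohort from per-gene value lists; first n_tumor samples are tumor."""
    df = pd.DataFrame(values).T
    n = df.shape[1]
    samples = [f"S{i}" for i in range(n)]
    df.columns = samples
    group = pd.Series(["tumor"] * n_tumor + ["normal"] * (n - n_tumor), index=samples)
    return CohortMatrix(cohort_id, cohort_id, df, group)


@pytest.fixture
def cohort_factory():
    return make_cohort
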