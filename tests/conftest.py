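import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from macsnet.datatypes import MetaboliteTable

settings.register_profile(
    "default",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_table(X: np.ndarray, n_control: int) -> MetaboliteTable:
    """Wrap a raw matrix as a two-group table (first n_control rows control)."""
    n, p = X.shape
    samples = [f"S{i:02d}" for i in range(n)]
    groups = ["control"] * n_control + ["treated"] * (n - n_control)
    return MetaboliteTable(
        intensities=pd.DataFrame(X, index=samples, columns=[f"M{j:03d}" for j in range(p)]),
        groups=pd.Series(groups, index=samples),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_table(rng):
    """12 x 30 two-group table, pure noise."""
    return make_table(np.exp(rng.normal(10, 0.3, size=(12, 30))), 6)


@pytest.fixture
def planted_table():
    """12 x 50 table with 8 metabolites shifted by 3 SD."""
    from macsnet.synthetic import generate_metabolite_table
    table, truth = generate_metabolite_table(6, 50, 8, 3.0, seed=42)
    return table, truth
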