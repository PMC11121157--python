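import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def standardized(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    a = a - a.mean(axis=0)
    return a / a.std(axis=0, ddof=1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_views():
    """Two standardized random views with p, q < n (classical-CCA regime)."""
    rng = np.random.default_rng(0)
    x = pd.DataFrame(
        standardized(rng.standard_normal((20, 5))),
        index=[f"S{i}" for i in range(20)],
        columns=[f"g{j}" for j in range(5)],
    )
    y = pd.DataFrame(
        standardized(rng.standard_normal((20, 4))),
        index=[f"S{i}" for i in range(20)],
        columns=[f"m{j}" for j in range(4)],
    )
    return x, y


@pytest.fixture(scope="session")
def recovery_data():
    """One realization of the recovery scenario, shared across tests."""
    from scclust.simulate import make_preset

    return make_preset("recovery", seed=0)
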