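import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hetvar import MetaDataset, fixture

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture
def f0() -> MetaDataset:
    """Homogeneous: identical effects, equal variances (Q = 0)."""
    return fixture("F0")


@pytest.fixture
def f1() -> MetaDataset:
    """Heterogeneous with equal variances (Q = 5, DL = 0.15)."""
    return fixture("F1")


@pytest.fixture
def f2() -> MetaDataset:
    """Heterogeneous, unequal variances, sample sizes attached."""
    return fixture("F2")


def random_dataset(rng: np.random.Generator, k: int = 5,
                   equal_v: bool = False, with_n: bool = False,
                   tau2: float = 0.2) -> MetaDataset:
    """A draw from the random-effects model for property tests."""
    if equal_v:
        v = np.full(k, float(rng.uniform(0.02, 0.5)))
    else:
        v = rng.uniform(0.02, 0.5, size=k)
    theta = rng.normal(0.3, np.sqrt(tau2), size=k)
    y = rng.normal(theta, np.sqrt(v))
    n = rng.integers(10, 200, size=k) if with_n else None
    return MetaDataset.from_arrays(y, v, n=n)
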