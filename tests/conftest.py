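import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from snoregrade.simulate import SyntheticNightSpec, simulate_cohort, simulate_night

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def short_night():
    """A 5-minute night at 4 kHz with a couple of apnea events."""
    spec = SyntheticNightSpec(duration_min=5.0, sample_rate=4000, target_ahi=24.0)
    return simulate_night(spec, seed=42)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Eight 20-minute nights, balanced over the four severity classes."""
    return simulate_cohort(8, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def separable_data():
    """Linearly separable 2-class minute features (200 rows, 5 columns)."""
    import pandas as pd

    gen = np.random.default_rng(7)
    n = 200
    y = np.repeat([0, 1], n // 2)
    X = gen.normal(size=(n, 5))
    X[:, 0] += 6.0 * y  # wide margin on the first column
    features = pd.DataFrame(X, columns=[f"f{i}" for i in range(5)])
    return features, y
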