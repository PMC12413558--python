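import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from planeqc import SimCohortConfig, WindowingConfig, build_dataset, simulate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """A desk-scale separable cohort: 8+8 videos, 32x32, 24 frames."""
    config = SimCohortConfig(
        n_correct=8, n_incorrect=8, n_frames=24, height=32, width=32, seed=11
    )
    videos, labels = simulate_cohort(config)
    return config, videos, labels


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    """One-window-per-video dataset over the small cohort (128 rows)."""
    _, videos, labels = small_cohort
    return build_dataset(videos, labels, WindowingConfig(n_frames_per_window=24))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
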