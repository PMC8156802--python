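import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    """Three easily separable subjects, two short recordings each."""
    from gaitfuse import SimulationConfig, simulate_dataset

    config = SimulationConfig(n_subjects=3, n_frames=40, noise_std=0.01, seed=7)
    return simulate_dataset(config, recordings_per_subject=2)


@pytest.fixture
def random_trajectory(rng):
    from gaitfuse import GaitTrajectory

    pos = rng.normal(size=(20, 10, 3))
    return GaitTrajectory.from_array(pos, subject_label="s01", tau=0.2)
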