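import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from adaptmtl.synth import generate_stimulus_set, generate_trial_sequence

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def stimulus_set():
    return generate_stimulus_set(10, 10, seed=1)


@pytest.fixture(scope="session")
def trial_table(stimulus_set):
    """One full session: 10 runs x 100 targets plus leading presentations."""
    return generate_trial_sequence(stimulus_set, 10, seed=0)


@pytest.fixture(scope="session")
def small_set():
    return generate_stimulus_set(4, 4, seed=2)


@pytest.fixture(scope="session")
def small_table(small_set):
    return generate_trial_sequence(small_set, 4, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
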