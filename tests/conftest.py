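import numpy as np
import pytest
from hypothesis import settings

from vo2pipe.synthetic import (NoiseConfig, make_cohort, make_protocol,
                               sample_power_trace, simulate_breaths)

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def profile():
    """One representative synthetic athlete."""
    return make_cohort(1, seed=11)[0]


@pytest.fixture(scope="session")
def quiet_noise():
    return NoiseConfig(vo2_sd=0.0, hr_sd=0.0, rf_sd=0.0, invalid_rate=0.0)


@pytest.fixture(scope="session")
def test2_session(profile):
    """A TEST2 interval session with default measurement noise."""
    protocol = make_protocol("TEST2", profile)
    trace = sample_power_trace(protocol, dt=1.0, noise_sd=2.0, seed=3)
    series = simulate_breaths(trace, profile, NoiseConfig(), seed=3)
    return trace, series


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
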