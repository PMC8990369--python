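import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import screenwatch as sw

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def short_config() -> sw.SessionConfig:
    """Two minutes of a default (noisy, bright) session."""
    return sw.SessionConfig(duration_s=120.0, seed=202)


@pytest.fixture(scope="session")
def short_session(short_config):
    return sw.simulate_session(short_config)


@pytest.fixture(scope="session")
def noiseless_config() -> sw.SessionConfig:
    return sw.SessionConfig(duration_s=120.0, seed=7).noiseless()


@pytest.fixture(scope="session")
def noiseless_session(noiseless_config):
    return sw.simulate_session(noiseless_config)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
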