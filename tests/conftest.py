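import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from newold.synthetic_session import GeneratorConfig, generate_session


@pytest.fixture(scope="session")
def default_session():
    """One default synthetic session shared by read-only tests."""
    return generate_session(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def recognition_trials(default_session):
    return default_session.recognition_trials()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
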