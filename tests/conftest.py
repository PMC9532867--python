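import pytest
from hypothesis import HealthCheck, settings

from sspmine.config import DEFAULT_CONFIG
from sspmine.families import load_family_registry

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    return DEFAULT_CONFIG


@pytest.fixture(scope="session")
def registry():
    return load_family_registry()
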