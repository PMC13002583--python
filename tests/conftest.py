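import pytest
from hypothesis import HealthCheck, settings

from varscreen import load_parameters

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def params():
    """Published base-case input set."""
    return load_parameters()
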