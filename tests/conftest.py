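import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gborn import GBConfig

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def cfg():
    """Default configuration: plain mode, eps_w 78.5, rmax 999 Å."""
    return GBConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
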