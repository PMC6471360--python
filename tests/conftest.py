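import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20191103)


@pytest.fixture
def sbo():
    from lipolyzer import OIL_COMPOSITIONS

    return OIL_COMPOSITIONS["SBO"]


@pytest.fixture
def pgo():
    from lipolyzer import OIL_COMPOSITIONS

    return OIL_COMPOSITIONS["PGO"]
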