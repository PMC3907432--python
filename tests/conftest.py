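import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spindlefield as sf
from spindlefield.fixtures import mini_spindle

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_free_model():
    """Full default spindle, free-end scenario (shared; expensive to build)."""
    return sf.build_spindle(sf.SpindleParams(scenario="free"), seed=1)


@pytest.fixture(scope="session")
def mini_free():
    return mini_spindle(seed=2, scenario="free")


@pytest.fixture(scope="session")
def mini_fixed():
    return mini_spindle(seed=2, scenario="fixed")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
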