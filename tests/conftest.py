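import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_object_scenario():
    """Plain two-object, one-attribute scenario with values 0.4 / 0.6."""
    from memdec import get_preset

    return get_preset("fig5a")
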