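import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def tabun_rsdl():
    """Strong-decontaminant scenario for a highly volatile agent."""
    from dermdecon import get_fixture

    return get_fixture("tabun-rsdl")


@pytest.fixture
def vx():
    from dermdecon import get_fixture

    return get_fixture("vx")


@pytest.fixture
def conservation():
    """Max deviation of the four-way mass balance from unity."""

    def check(curves):
        total = curves.M_abs + curves.M_surf + curves.M_reac + curves.M_remaining
        return float(np.abs(total - 1.0).max())

    return check
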