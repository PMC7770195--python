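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
    return np.random.default_rng(1234)


@pytest.fixture
def small_params():
    """A small, fast phantom used by unit tests (full geometry is exercised
    by the acceptance suite)."""
    from shgquant import PhantomParams

    return PhantomParams(seed=7, shape=(3, 200, 200))
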