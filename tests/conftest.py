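import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """A fast phantom spec shared across image tests."""
    from vitrehaze import PhantomSpec

    return PhantomSpec(n_bscans=4, n_ascans=32, n_depth=96, haze_level=0.01,
                       noise_sigma=0.05)
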