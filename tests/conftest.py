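import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume(rng):
    """A tiny 4D volume (6x6x6x40) of unit white noise, 2-mm grid, TR 2 s."""
    from boldsv.volume import Volume4D, mni_like_affine

    data = rng.standard_normal((6, 6, 6, 40))
    return Volume4D(data=data, affine=mni_like_affine((6, 6, 6), 2.0), tr=2.0)
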