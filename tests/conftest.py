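import numpy as np
import pytest

from nervemap import FiberMask, PhantomSpec, make_phantom_slide


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    return PhantomSpec(seed=11, canvas=(200, 200), radii=(30, 70), fiber_fraction=0.05)


@pytest.fixture
def phantom_slide(small_spec):
    return make_phantom_slide(small_spec)


def random_fiber_mask(rng, shape=(50, 60), p=0.1, mpp=8.0) -> FiberMask:
    return FiberMask(mask=rng.random(shape) < p, mpp_eff=mpp)
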