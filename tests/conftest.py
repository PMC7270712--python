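import numpy as np
import pytest
from hypothesis import settings

from rodentmri.phantom import PhantomSpec, make_head_phantom

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def head_phantom():
    """Default noise-free head phantom (64 x 64 x 32) with ground truth."""
    spec = PhantomSpec()
    image, truth = make_head_phantom(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def small_phantom():
    """Coarse phantom for fast registration tests."""
    spec = PhantomSpec(grid_shape=(32, 32, 16), voxel_sizes=(0.4, 0.4, 1.0))
    image, truth = make_head_phantom(spec)
    return spec, image, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
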