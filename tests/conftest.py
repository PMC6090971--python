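import numpy as np
import pytest

from pectoseg import PhantomSpec, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_phantom():
    """One noiseless 256x256 phantom, shared across read-only tests."""
    return make_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def noiseless_result(default_phantom):
    """Pipeline result on the default phantom (computed once)."""
    from pectoseg import segment

    return segment(default_phantom.image)


def random_mask(rng: np.random.Generator, shape=(12, 12), p=0.35) -> np.ndarray:
    return rng.random(shape) < p
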