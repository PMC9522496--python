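import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_image(rng):
    """A 16x16 random RGB image in [0, 1]."""
    return rng.uniform(0.0, 1.0, size=(16, 16, 3))


@pytest.fixture
def random_plane(rng):
    return rng.uniform(0.0, 1.0, size=(12, 12))
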