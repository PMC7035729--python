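import numpy as np
import pytest

from voxtex.volio import Volume3D


@pytest.fixture
def rng():
    return np.random.default_rng(123)


@pytest.fixture
def noise_volume(rng):
    """8x8x8 independent unit-normal noise."""
    return Volume3D(rng.standard_normal((8, 8, 8)))


@pytest.fixture
def constant_volume():
    return Volume3D(np.full((8, 8, 8), 5.0))
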