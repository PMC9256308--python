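import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def seeded_image(rng):
    """A generic 16x16 matrix on a 0-255-ish scale."""
    return rng.uniform(0.0, 255.0, size=(16, 16))
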