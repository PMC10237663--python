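import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_image(rng):
    """A 24×16×3 uint8 test image with distinguishable structure."""
    img = rng.integers(0, 256, size=(24, 16, 3), dtype=np.uint8)
    return img
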