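import numpy as np
import pytest

from tracescore.scoring import TraceMap
from tracescore.stimuli import LuminanceImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_scene(rng):
    """A non-degenerate 128x128 luminance image around 100 cd/m²."""
    return LuminanceImage(100.0 + 12.0 * rng.standard_normal((128, 128)), ppd=44.0)


def make_map(size, pixels):
    """Build a TraceMap from a list of (row, col) pixels."""
    m = np.zeros((size, size), dtype=int)
    for r, c in pixels:
        m[r, c] = 1
    return TraceMap(m)


@pytest.fixture
def map_factory():
    return make_map
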