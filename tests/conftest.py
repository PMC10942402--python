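import numpy as np
import pytest

from stoat import Slice


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_slice_pair(rng):
    """Two small random slices sharing a feature space."""
    def make(n, p=6, seed_shift=0):
        r = np.random.default_rng(100 + seed_shift)
        return Slice(expression=r.random((n, p)) + 0.1,
                     coords=r.random((n, 2)) * 5.0)
    return make(7), make(9, seed_shift=1)
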