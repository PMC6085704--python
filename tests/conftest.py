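import numpy as np
import pytest
from scipy import ndimage

from demonsreg import Image, VelocityField, make_checkerboard, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def checkerboard64():
    return make_checkerboard((64, 64), square_size=8)


@pytest.fixture
def phantom64():
    return make_phantom((64, 64))


@pytest.fixture
def random_image(rng):
    def _make(shape=(5, 5), lo=0, hi=20):
        return Image(rng.integers(lo, hi, size=shape).astype(float))
    return _make


@pytest.fixture
def smooth_velocity():
    """Smooth random velocity field, rescaled to a requested peak norm."""

    def _make(shape=(48, 48), seed=0, peak=2.0, smooth_sigma=6.0):
        gen = np.random.default_rng(seed)
        raw = gen.normal(size=(len(shape), *shape))
        v = np.stack([ndimage.gaussian_filter(raw[i], smooth_sigma) for i in range(len(shape))])
        norm = np.sqrt(np.sum(v**2, axis=0)).max()
        return VelocityField(v * (peak / norm))

    return _make
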