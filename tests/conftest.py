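import numpy as np
import pytest

from habitomics.imaging import RegionMask, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sphere_volume(rng):
    """32-cube volume with a radius-8 sphere mask and noisy interior."""
    shape = (32, 32, 32)
    zz, yy, xx = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    r = np.sqrt((zz - 16.0) ** 2 + (yy - 16.0) ** 2 + (xx - 16.0) ** 2)
    mask = r <= 8.0
    img = rng.normal(100.0, 10.0, shape)
    img[mask] += 50.0
    return Volume(img), RegionMask(mask)
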