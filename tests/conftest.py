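import numpy as np
import pytest

from synquant.core import ImagePlane


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


def make_plane(pixels, pixel_size_nm=100.0, **kw) -> ImagePlane:
    return ImagePlane(np.asarray(pixels, dtype=float), pixel_size_nm, **kw)


@pytest.fixture
def plane_factory():
    return make_plane
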