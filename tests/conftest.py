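import numpy as np
import pytest

from pydefine import PixelGeometry, PlaneImage


@pytest.fixture
def unit_geometry() -> PixelGeometry:
    return PixelGeometry(1.0, 1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_plane(pixels, geometry=None, bit_depth=8, name="") -> PlaneImage:
    geometry = geometry or PixelGeometry(1.0, 1.0)
    return PlaneImage(
        np.asarray(pixels, dtype=np.uint8 if bit_depth == 8 else np.uint16),
        bit_depth,
        geometry,
        name=name,
    )
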