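import numpy as np
import pytest

from landsdm.raster import RasterLayer, RasterStack, expand_categorical


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_layer(grid, name="layer", kind="quantitative", origin=None, pixel_size=1.0):
    grid = np.asarray(grid, dtype=float)
    if origin is None:
        origin = (0.0, grid.shape[0] * pixel_size)
    return RasterLayer(
        name=name, grid=grid, origin=origin, pixel_size=pixel_size, kind=kind
    )


@pytest.fixture
def small_stack(rng):
    """Two quantitative layers + one 3-class categorical on a 12x12 grid."""
    g1 = rng.standard_normal((12, 12))
    g2 = rng.standard_normal((12, 12))
    cat = rng.integers(1, 4, size=(12, 12)).astype(float)
    return RasterStack(
        [
            make_layer(g1, "alpha"),
            make_layer(g2, "beta"),
            make_layer(cat, "cover", kind="categorical"),
        ]
    )


@pytest.fixture
def expanded_stack(small_stack):
    return expand_categorical(small_stack).fill_all()
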