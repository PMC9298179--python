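import numpy as np
import pytest

from cellsharp.image_io import ImageGrid
from cellsharp.synthetic_cells import SceneSpec, synth_sharp_image


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_scene():
    """A 64x64 sharp synthetic cell scene."""
    return synth_sharp_image(SceneSpec(image_size=64, n_cells=6,
                                       cell_radius_range=(4.0, 8.0), seed=11))


@pytest.fixture
def textured_scene():
    """A 128x128 scene with enough texture for resolution estimation."""
    return synth_sharp_image(SceneSpec(image_size=128, seed=5))


@pytest.fixture
def fixture_batch(rng):
    """Seeded 2x1x16x16 batch pair for loss oracles."""
    x = rng.uniform(0.1, 0.9, size=(2, 1, 16, 16))
    xh = rng.uniform(0.1, 0.9, size=(2, 1, 16, 16))
    return x, xh


def make_grid(arr) -> ImageGrid:
    return ImageGrid(np.asarray(arr, dtype=np.float64))
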