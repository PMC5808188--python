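import numpy as np
import pytest

from seagrass import Grid, OpticalConstants, ReflectanceScene, SceneSpec
from seagrass.rasters import STAGE_SURFACE
from seagrass.synthetic import make_scene


@pytest.fixture(scope="session")
def optics() -> OpticalConstants:
    return OpticalConstants()


@pytest.fixture(scope="session")
def small_spec() -> SceneSpec:
    return SceneSpec(rows=120, cols=120, rng_seed=42)


@pytest.fixture(scope="session")
def scene(small_spec):
    return make_scene(small_spec)


def make_flat_scene(value, optics, rows=10, cols=10, stage=STAGE_SURFACE, mask=None):
    """Constant-reflectance scene helper."""
    grid = Grid(rows=rows, cols=cols, pixel_size=5.0)
    values = np.full((optics.n_bands, rows, cols), float(value))
    return ReflectanceScene(values=values, bands=optics.bands, grid=grid, mask=mask, stage=stage)


@pytest.fixture
def flat_scene_factory(optics):
    def _make(value, **kw):
        return make_flat_scene(value, optics, **kw)

    return _make
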