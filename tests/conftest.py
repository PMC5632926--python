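import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from popdasym.raster import RasterGrid
from popdasym.scene import SceneConfig, generate_scene

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=list(HealthCheck)
)
settings.load_profile("ci")


SMALL_CFG = SceneConfig(
    grid_rows=80,
    grid_cols=80,
    n_coarse_zones=4,
    n_fine_zones=20,
    n_finest_zones=60,
    seed=7,
)


@pytest.fixture(scope="session")
def small_scene():
    """One modest drift-free scene shared by read-only tests."""
    return generate_scene(SMALL_CFG)


@pytest.fixture()
def grid44():
    return RasterGrid(np.arange(16, dtype=float).reshape(4, 4), cell_size=100.0)


def builtup_pair(v1, v2, cell_size=100.0):
    """Co-registered single-value builtup grids for interpolation tests."""
    a = RasterGrid(np.full((2, 2), float(v1)), cell_size=cell_size)
    b = RasterGrid(np.full((2, 2), float(v2)), cell_size=cell_size)
    return a, b
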