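import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ifp

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_grid():
    """5x5x5 grid of unit voxels with origin at (0, 0, 0)."""
    return ifp.Grid3D((5, 5, 5), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))


@pytest.fixture
def centered_grid8():
    """8x8x8 grid, 10 mm voxels, centered on the origin."""
    return ifp.Grid3D((8, 8, 8), (10.0, 10.0, 10.0), (-35.0, -35.0, -35.0))


@pytest.fixture(scope="session")
def coarse_spec():
    """The default thorax spec (64^3, 4 mm voxels); session-scoped so the
    pipeline tests rasterize it once."""
    return ifp.default_spec()


@pytest.fixture(scope="session")
def coarse_phantom(coarse_spec):
    return ifp.build_phantom(coarse_spec)


def sphere_mask(grid, center, radius, name="sphere"):
    c = grid.voxel_centers()
    m = np.sum((c - np.asarray(center)) ** 2, axis=-1) <= radius**2
    return ifp.ROIMask(grid=grid, mask=m, name=name)


def dice(a, b):
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    return 2.0 * (a & b).sum() / max(a.sum() + b.sum(), 1)
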