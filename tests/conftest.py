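import numpy as np
import pytest

from adaptrt.grids import GridGeometry, StructureMask
from adaptrt.synthetic import PhantomConfig

#: grid used for quick phantom-based tests (desk-scale, 3 mm isotropic)
SMALL_GEOMETRY = GridGeometry(shape=(64, 64, 48), spacing=(3.0, 3.0, 3.0))


@pytest.fixture
def unit_geometry():
    """1 mm isotropic 24-cube used by the metric oracle tests."""
    return GridGeometry(shape=(24, 24, 24), spacing=(1.0, 1.0, 1.0))


@pytest.fixture
def small_phantom_config():
    return PhantomConfig(geometry=SMALL_GEOMETRY, cohort="uterine")


@pytest.fixture
def small_phantom(small_phantom_config):
    from adaptrt.synthetic import make_phantom
    return make_phantom(small_phantom_config)


def make_mask(geometry, voxels, name=""):
    return StructureMask(geometry, np.asarray(voxels, dtype=bool), name=name)


def box_mask(geometry, lo, hi, name="box"):
    """Axis-aligned solid box given inclusive index bounds."""
    voxels = np.zeros(geometry.shape, dtype=bool)
    voxels[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] = True
    return StructureMask(geometry, voxels, name=name)


def sphere_mask(geometry, center_mm, radius_mm, name="sphere"):
    coords = [geometry.axis_coords(a) for a in range(3)]
    x = coords[0][:, None, None]
    y = coords[1][None, :, None]
    z = coords[2][None, None, :]
    cx, cy, cz = center_mm
    voxels = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= radius_mm ** 2
    return StructureMask(geometry, voxels, name=name)
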