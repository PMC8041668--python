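import numpy as np
import pytest

from psmaburden.volume import SUVVolume, RegionMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_volume():
    """8x8x8 grid at 2 mm isotropic, SUV 7 everywhere."""
    return SUVVolume(values=np.full((8, 8, 8), 7.0), spacing=(2.0, 2.0, 2.0))


def make_sphere_volume(shape, spacing, center_mm, radius_mm, inside_suv, outside_suv=0.0):
    """Binary-contrast sphere phantom: voxel centers inside radius get inside_suv."""
    axes = [np.arange(s) * d for s, d in zip(shape, spacing)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    r2 = (gx - center_mm[0]) ** 2 + (gy - center_mm[1]) ** 2 + (gz - center_mm[2]) ** 2
    values = np.where(r2 <= radius_mm**2, inside_suv, outside_suv)
    return SUVVolume(values=values, spacing=spacing)


@pytest.fixture
def sphere_2ml():
    """2 ml uniform sphere (SUV 10) on zero background, 1 mm isotropic."""
    from psmaburden.synthetic import sphere_radius_mm

    r = sphere_radius_mm(2.0)
    return make_sphere_volume((40, 40, 40), (1.0, 1.0, 1.0), (20.0, 20.0, 20.0), r, 10.0)
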