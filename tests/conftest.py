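import numpy as np
import pytest

from potholes import CohortSpec, Geometry, ZVolume, generate_fa_cohort, zmap_cohort


@pytest.fixture(scope="session")
def small_geometry():
    return Geometry(shape=(8, 8, 8), voxel_size_mm=(2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def small_cohort():
    """20-subject plant-free cohort on a 24^3 grid (session-cached)."""
    spec = CohortSpec(n_subjects=20, grid_shape=(24, 24, 24), seed=11)
    cohort, _ = generate_fa_cohort(spec)
    return cohort


@pytest.fixture(scope="session")
def small_zmaps(small_cohort):
    reference, mask, zvols = zmap_cohort(small_cohort)
    return reference, mask, zvols


def make_zvolume(z_array, geometry=None, mask=None):
    z_array = np.asarray(z_array, dtype=float)
    geometry = geometry or Geometry(
        shape=z_array.shape, voxel_size_mm=(2.0, 2.0, 2.0)
    )
    mask = np.ones(z_array.shape, dtype=bool) if mask is None else mask
    return ZVolume(z=z_array, mask=mask, geometry=geometry)
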