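import numpy as np
import pytest

from mtbm.cohort import CohortSpec
from mtbm.shapes import box_grid, cylinder_grid, ellipsoid_grid, sphere_grid


@pytest.fixture
def cylinder():
    return cylinder_grid(radius=5.0, length=20.0, n_rings=30, n_around=40)


@pytest.fixture
def sphere():
    return sphere_grid(radius=10.0, n_rings=50, n_around=100)


@pytest.fixture
def box():
    return box_grid(10.0, 20.0, 30.0, n_rings=7, n_around=12)


@pytest.fixture
def small_ellipsoid():
    return ellipsoid_grid((20.0, 8.5, 7.0216), n_rings=30, n_around=45)


@pytest.fixture
def small_spec():
    """Reduced-grid cohort spec used throughout the statistical tests."""
    return CohortSpec(n_rings=30, n_around=45, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def rotation_matrix(angles=(0.3, 0.5, 0.7)):
    from scipy.spatial.transform import Rotation

    return Rotation.from_euler("xyz", angles).as_matrix()
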