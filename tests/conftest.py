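import numpy as np
import pytest

from qsmrim.core import GridGeometry
from qsmrim.phantom import LesionSpec, PhantomSpec


@pytest.fixture
def small_geometry():
    """Desk-scale grid: 64 mm^3 FOV is plenty for a single small lesion."""
    return GridGeometry((64, 64, 64), (0.5, 0.5, 0.5))


@pytest.fixture
def solid_sphere_spec(small_geometry):
    center = tuple(small_geometry.center_mm)
    lesion = LesionSpec("solid0", center, core_radius=4.0, core_chi=0.02)
    return PhantomSpec(small_geometry, (lesion,))


@pytest.fixture
def rim_sphere_spec(small_geometry):
    center = tuple(small_geometry.center_mm)
    lesion = LesionSpec(
        "rim0",
        center,
        core_radius=4.0,
        core_chi=0.02,
        rim_chi=0.10,
        rim_thickness=1.2,
        rim_coverage=1.0,
        class_label="rim",
    )
    return PhantomSpec(small_geometry, (lesion,))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
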