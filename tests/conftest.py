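import numpy as np
import pytest

from osteoquant import phantoms

#: small screw used throughout the suite (keeps EDT/face-count runtimes low)
SMALL_SCREW = dict(
    length_mm=0.4,
    radius_mm=0.15,
    thread_depth_mm=0.03,
    erosion_depth_um=40.0,
    layer_thickness_um=25.0,
    bone_fill_fraction=0.625,
    voxel_um=5.0,
)


@pytest.fixture(scope="session")
def small_screw_phantom():
    """Shared (volume, reference, truth) screw phantom at 5 um voxels."""
    return phantoms.make_screw_phantom(seed=1, t_years=0.5, **SMALL_SCREW)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
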