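import numpy as np
import pytest

from octsclera import PhantomSpec, generate_phantom, segment_volume


SMALL_SPEC = PhantomSpec(
    shape=(128, 96, 24),
    retina_top_px=20.0,
    cib_depth_px=50.0,
    choroid_thickness_px=30.0,
    thickness_wave_px=2.0,
    rpe_thickness_px=6.0,
    curvature_px=8.0,
    n_haller=5,
    haller_radius_px=(4.0, 6.0),
    n_sattler=4,
    sattler_radius_px=(2.0, 3.0),
    n_spca=6,
    seed=11,
)


@pytest.fixture(scope="session")
def small_phantom():
    """A compact layered phantom shared across tests (volume, truth)."""
    return generate_phantom(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_segmentation(small_phantom):
    """The small phantom's detected (CIB, COB) surfaces."""
    vol, _ = small_phantom
    return segment_volume(vol)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
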