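import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy import ndimage

from vertetrack.frames import FrameKind, ProjectionImage
from vertetrack.geometry import DetectorSpec, ROITemplate
from vertetrack.phantom import build_spine_phantom, target_roi_mask

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def tiny_spec():
    """64x48 detector over the full active area (coarse but true geometry)."""
    return DetectorSpec().scaled(0.0625)


@pytest.fixture(scope="session")
def small_spec():
    return DetectorSpec().scaled(0.125)


@pytest.fixture(scope="session")
def tiny_phantom():
    """Three-vertebra phantom on a coarse grid, cheap to render."""
    return build_spine_phantom(
        n_vertebrae=3,
        body_radius=50.0,
        vertebra_size=20.0,
        disc_gap=5.0,
        spacing=4.0,
    )


@pytest.fixture(scope="session")
def tiny_roi3d(tiny_phantom):
    return target_roi_mask(tiny_phantom, vertebra_size=20.0, margin=15.0)


def smooth_image(rng, shape=(48, 64), scale=1000.0, offset=100.0, sigma=1.0):
    """Smooth strictly positive random field (a stand-in projection)."""
    return ndimage.gaussian_filter(rng.random(shape), sigma) * scale + offset


@pytest.fixture
def smooth_pair(rng, tiny_spec):
    """A reference frame with a central ROI, on the tiny detector grid."""
    pixels = smooth_image(rng, shape=(tiny_spec.n_rows, tiny_spec.n_cols))
    ref = ProjectionImage(pixels=pixels, gantry_deg=180.0, kind=FrameKind.CBCT)
    mask = np.zeros_like(pixels, dtype=bool)
    mask[14:34, 22:42] = True
    roi = ROITemplate(mask=mask, angle_deg=180.0)
    return ref, roi
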