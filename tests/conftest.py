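import numpy as np
import pytest

from amineblot.calibration import CalibrationModel
from amineblot.core_image import GrayImage, RGBImage
from amineblot.synthetic_fixtures import DEFAULT_INTERCEPT, DEFAULT_SLOPE, DEFAULT_STANDARDS


@pytest.fixture
def rng():
    return np.random.default_rng(20260903)


@pytest.fixture
def noise_free_model():
    """The default generating line packaged as a fitted, noise-free model."""
    xs = np.repeat(DEFAULT_STANDARDS, 3).astype(float)
    return CalibrationModel(
        slope=DEFAULT_SLOPE,
        intercept=DEFAULT_INTERCEPT,
        r_squared=1.0,
        p_value=0.0,
        n=xs.size,
        residual_se=0.0,
        x_mean=float(xs.mean()),
        sxx=float(np.sum((xs - xs.mean()) ** 2)),
        clamp_max=max(DEFAULT_STANDARDS),
    )


@pytest.fixture
def random_rgb(rng):
    return RGBImage(rng.integers(0, 256, size=(16, 24, 3)))


@pytest.fixture
def disk_image():
    """Dark disk on a bright background, with the ground-truth mask."""
    h = w = 40
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    mask = (rr - 20) ** 2 + (cc - 18) ** 2 <= 8**2
    arr = np.full((h, w), 240.0)
    arr[mask] = 120.0
    return GrayImage(arr), mask
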