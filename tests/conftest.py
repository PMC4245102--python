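import numpy as np
import pytest

from courttrack.geometry import CourtCalibration, estimate_homography


@pytest.fixture
def perspective_h():
    """Homography from a realistic camera-behind-baseline trapezoid."""
    cal = CourtCalibration(
        image_corners=np.array([[100, 400], [540, 400], [480, 120], [160, 120]], dtype=float)
    )
    return estimate_homography(cal)


@pytest.fixture
def identity_h():
    from courttrack.geometry import Homography

    return Homography(np.eye(3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
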