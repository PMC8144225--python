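import numpy as np
import pytest

from cytoquant import ImageFrame


def stripe_image(angle_deg: float, shape=(128, 128), period: float = 8.0) -> ImageFrame:
    """Analytic stripe pattern with lines at ``angle_deg`` (axial, CCW from
    the x-axis, y up): intensity varies sinusoidally normal to the lines."""
    r, c = np.mgrid[0:shape[0], 0:shape[1]]
    a = np.radians(angle_deg)
    phase = c * np.sin(a) + r * np.cos(a)
    return ImageFrame(0.5 + 0.5 * np.cos(2 * np.pi * phase / period), 30.0)


def interior_mask(shape, margin: int = 16) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    mask[margin:shape[0] - margin, margin:shape[1] - margin] = True
    return mask


def axial_diff(a, b):
    """Smallest axial (period-180) angular difference in degrees."""
    return (np.asarray(a) - np.asarray(b) + 90.0) % 180.0 - 90.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
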