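import numpy as np
import pytest

from mamiq import (
    DetectorModel,
    ImageFrame,
    design_bar_layout,
    make_bar_pattern,
)
from mamiq.detector_response import ResponseFit

GAIN = 2471.0
OFFSET = 32.0
PITCH = 0.1
KERMA = 0.1  # µGy; noise-free fixtures only need the two DU levels


@pytest.fixture(scope="session")
def default_layout():
    layout, shape = design_bar_layout()
    return layout, shape


@pytest.fixture(scope="session")
def exact_response():
    """The true detector characteristic, for offset subtraction."""
    return ResponseFit(OFFSET, GAIN, 1.0, 0.0)


@pytest.fixture(scope="session")
def sharp_pattern(default_layout):
    """Noise-free, unblurred bar pattern: exactly two DU levels."""
    layout, shape = default_layout
    det = DetectorModel(gain_DU_per_uGy=GAIN, offset_DU=OFFSET, blur_sigma_mm=0.0, noise=None)
    return make_bar_pattern(layout, det, KERMA, shape, PITCH)


@pytest.fixture(scope="session")
def blurred_pattern(default_layout):
    """Noise-free pattern blurred by a Gaussian PSF of sigma = 0.08 mm."""
    layout, shape = default_layout
    det = DetectorModel(gain_DU_per_uGy=GAIN, offset_DU=OFFSET, blur_sigma_mm=0.08, noise=None)
    frame, truth = make_bar_pattern(layout, det, KERMA, shape, PITCH)
    return frame, truth, 0.08


def make_frame(pixels, pitch=PITCH, **kw):
    return ImageFrame(np.asarray(pixels, dtype=float), pitch, **kw)
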