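"""Linear detector characteristic: MPV = a + b·X.

The slope b is the gain G in digital units per µGy and feeds the signal
power spectrum and the NNPS normalisation; the intercept a is the pixel
value offset at zero air kerma and is subtracted before contrast is
measured.  The fit is ordinary (unweighted) least squares; a dark-frame
override is available to force the intercept instead of fitting it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .exceptions import DegenerateDesignError
from .image_model import ImageFrame, RegionOfInterest, extract_roi

__all__ = ["ResponseFit", "fit_response", "fit_response_from_frames", "mean_pixel_value"]


@dataclass(frozen=True)
class ResponseFit:
    offset_a_DU: float
    gain_G_DU_per_uGy: float
    r_squared: float
    stderr_gain: float
    n_points: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.gain_G_DU_per_uGy):
            raise ValueError("gain must be finite")
        if not (-1e-12 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared must be in [0,1], got {self.r_squared}")

    def predict(self, kerma_uGy):
        return self.offset_a_DU + self.gain_G_DU_per_uGy * np.asarray(kerma_uGy)


def fit_response(
    points: Iterable[tuple[float, float]],
    min_points: int = 3,
    force_offset: float | None = None,
) -> ResponseFit:
    """Least-squares line through (air kerma µGy, mean pixel value) pairs.

    ``force_offset`` fixes the intercept (e.g. from a dark frame) and
    fits only the slope.
    """
    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) < max(2, min_points):
        raise ValueError(f"need at least {max(2, min_points)} points, got {len(pts)}")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.unique(x).size < 2:
        raise DegenerateDesignError("all air-kerma values identical; slope is undefined")

    if force_offset is None:
        res = stats.linregress(x, y)
        offset = float(res.intercept)
        gain = float(res.slope)
        r2 = float(res.rvalue) ** 2
        stderr = float(res.stderr)
    else:
        offset = float(force_offset)
        yc = y - offset
        sxx = float(np.sum(x * x))
        gain = float(np.sum(x * yc) / sxx)
        resid = yc - gain * x
        dof = max(1, len(pts) - 1)
        s2 = float(np.sum(resid**2)) / dof
        stderr = float(np.sqrt(s2 / sxx))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - float(np.sum(resid**2)) / ss_tot)
    # guard fp rounding on exact data
    r2 = min(1.0, max(0.0, r2))
    return ResponseFit(offset, gain, r2, stderr, n_points=len(pts))


def mean_pixel_value(frame: ImageFrame, roi: RegionOfInterest | None = None) -> float:
    """Arithmetic mean of the ROI (whole frame when roi is None)."""
    pixels = extract_roi(frame, roi).pixels if roi is not None else frame.pixels
    return float(pixels.mean())


def fit_response_from_frames(
    frames: Sequence[ImageFrame],
    roi: RegionOfInterest | None = None,
    min_points: int = 3,
    force_offset: float | None = None,
) -> ResponseFit:
    """Fit the characteristic from an exposure series of flat fields,
    reading each frame's air kerma from its acquisition context."""
    points = []
    for f in frames:
        if f.acquisition.air_kerma_uGy is None:
            raise ValueError(f"frame {f.label!r} has no air kerma recorded")
        points.append((f.acquisition.air_kerma_uGy, mean_pixel_value(f, roi)))
    return fit_response(points, min_points=min_points, force_offset=force_offset)
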