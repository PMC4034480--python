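"""Noise estimation from flat fields: CV, 2-D NPS, radial 1-D NPS, NNPS.

The space-domain index is the coefficient of variation CV = sigma/MPV of
a uniform region (default 100x100 pixels).  In the frequency domain the
noise power spectrum of a linearised detector is estimated from an
ensemble of overlapping square ROIs (default 128x128 at 50% overlap):

    NPS(fx, fy) = < |DFT2(p)|^2 > * dx*dy / (Nx*Ny)        [mm^2]

with p the ROI's pixel values minus its mean (or a fitted plane).  No
spectral window is applied by default.  The 2-D spectrum is collapsed to
one dimension by radial averaging of the non-DC bins and linear
interpolation onto a constant frequency interval; the normalised NPS is
NNPS(f) = NPS(f) / (G*X)^2 with G the gain in DU/µGy and X the air kerma
in µGy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_model import ImageFrame, RegionOfInterest, extract_roi, tile_rois
from .resolution_metrics import FrequencySeries

__all__ = [
    "Spectrum2D",
    "coefficient_of_variation",
    "nps_2d",
    "radial_profile",
    "normalize_nps",
]


@dataclass
class Spectrum2D:
    """DC-centred 2-D noise power spectrum (mm^2)."""

    values: np.ndarray
    freq_step_per_mm: float
    n_rois: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"spectrum must be square 2-D, got shape {self.values.shape}")
        if np.any(self.values < -1e-12):
            raise ValueError("NPS values must be non-negative")
        if self.freq_step_per_mm <= 0:
            raise ValueError("freq_step_per_mm must be positive")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def axis_frequencies(self) -> np.ndarray:
        """Frequencies of each row/column, DC-centred."""
        n = self.n
        return (np.arange(n) - n // 2) * self.freq_step_per_mm

    @property
    def nyquist_per_mm(self) -> float:
        return (self.n // 2) * self.freq_step_per_mm


def coefficient_of_variation(frame: ImageFrame, roi: RegionOfInterest | None = None) -> float:
    """Sample standard deviation (n-1) over mean; a fraction, not %."""
    pixels = extract_roi(frame, roi).pixels if roi is not None else frame.pixels
    if pixels.size < 2:
        raise ValueError("CV needs at least 2 pixels")
    mean = float(pixels.mean())
    if mean <= 0:
        raise ValueError(f"CV undefined: ROI mean {mean} is not positive")
    return float(pixels.std(ddof=1)) / mean


def _detrended(pixels: np.ndarray, detrend: str) -> np.ndarray:
    if detrend == "mean":
        return pixels - pixels.mean()
    if detrend == "planar":
        n = pixels.shape[0]
        y, x = np.mgrid[0:n, 0:pixels.shape[1]]
        a = np.column_stack([np.ones(pixels.size), x.ravel(), y.ravel()])
        coef, *_ = np.linalg.lstsq(a, pixels.ravel(), rcond=None)
        return pixels - (a @ coef).reshape(pixels.shape)
    raise ValueError(f"detrend must be mean|planar, got {detrend!r}")


def nps_2d(
    flat: ImageFrame,
    roi_size: int = 128,
    overlap_fraction: float = 0.5,
    detrend: str = "mean",
    min_rois: int = 4,
) -> Spectrum2D:
    """Ensemble-averaged 2-D NPS from overlapping ROIs of a flat field."""
    rois = tile_rois(flat, roi_size, overlap_fraction)
    if len(rois) < min_rois:
        raise ValueError(
            f"only {len(rois)} ROIs of {roi_size}px fit the frame; at least {min_rois} required"
        )
    dx = flat.pixel_pitch_mm
    acc = np.zeros((roi_size, roi_size))
    for roi in rois:
        p = _detrended(flat.pixels[roi.slices], detrend)
        acc += np.abs(np.fft.fft2(p)) ** 2
    nps = acc / len(rois) * (dx * dx) / (roi_size * roi_size)
    return Spectrum2D(
        values=np.fft.fftshift(nps),
        freq_step_per_mm=1.0 / (roi_size * dx),
        n_rois=len(rois),
    )


def radial_profile(
    spec: Spectrum2D,
    n_bins: int | None = None,
    include_axes: bool = True,
) -> FrequencySeries:
    """Collapse the 2-D spectrum to 1-D by radial averaging.

    Non-DC bins are assigned the radius sqrt(fx^2+fy^2) and averaged in
    equal-width radial bins up to the axis Nyquist frequency (default
    bin width: one axis frequency step); empty bins are bridged by
    linear interpolation so the output grid has a constant interval.
    ``include_axes=False`` drops the fx=0 and fy=0 lines, which collect
    row/column-correlated artefact power.
    """
    if n_bins is None:
        n_bins = spec.n // 2
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    f_axis = spec.axis_frequencies()
    fx, fy = np.meshgrid(f_axis, f_axis)
    r = np.hypot(fx, fy)
    mask = r > 0  # exclude the DC bin
    if not include_axes:
        mask &= (fx != 0) & (fy != 0)
    f_nyq = spec.nyquist_per_mm
    mask &= r <= f_nyq + 1e-12

    edges = np.linspace(0.0, f_nyq, n_bins + 1)
    which = np.clip(np.digitize(r[mask], edges) - 1, 0, n_bins - 1)
    sums = np.bincount(which, weights=spec.values[mask], minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    filled = counts > 0
    if filled.sum() < 2:
        raise ValueError("too few occupied radial bins; increase the ROI size")
    values = np.interp(centers, centers[filled], sums[filled] / counts[filled])
    return FrequencySeries(centers, np.clip(values, 0.0, None), kind="NPS")


def normalize_nps(nps: FrequencySeries, gain_G: float, kerma_X_uGy: float) -> FrequencySeries:
    """NNPS(f) = NPS(f) / (G·X)²."""
    if gain_G <= 0:
        raise ValueError(f"gain must be positive, got {gain_G}")
    if kerma_X_uGy <= 0:
        raise ValueError(f"air kerma must be positive, got {kerma_X_uGy}")
    if nps.kind != "NPS":
        raise ValueError(f"expected an NPS series, got kind {nps.kind!r}")
    return FrequencySeries(
        nps.frequencies_per_mm.copy(),
        nps.values / (gain_G * kerma_X_uGy) ** 2,
        kind="NNPS",
    )
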