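"""The three sharpening operators characterised on the mammography unit.

Two belong to the same kernel family,

    [ 0   -1    0 ]
    [-1  1+4a  -1 ]      "sharpen":      a in [0.7, 1.0]
    [ 0   -1    0 ]      "sharpen more": a in [1.0, 1.3]

i.e. the original image plus an unscaled 4-neighbour difference operator.
Note the kernel DC gain is 4a-3, so the family preserves the mean only
at a = 1.

"sharpen edges" runs an 8-neighbour Laplacian [-1 -1 -1; -1 8 -1;
-1 -1 -1], rescales the response linearly so that its magnitude spans
the intensity range of the original image (sign preserved by default),
zeroes responses whose magnitude falls below a chosen quantile of the
nonzero edge-magnitude histogram, and adds the surviving signed edge map
back to the image weighted by k in [1.1, 1.3].  The quantile of the
threshold is not pinned down by the characterisation; 0.90 is the
documented default and it is always a parameter.

Outputs are unclamped floating point; clamping to a display range is
left to image export.  An adaptive contrast enhancement step (vendor
"fine view") is supported only as a user-registered filter hook.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage

from .exceptions import ConfigError
from .image_model import ImageFrame

__all__ = [
    "SHARPEN_ALPHA_RANGE",
    "SHARPEN_MORE_ALPHA_RANGE",
    "EDGE_K_RANGE",
    "sharpen_kernel",
    "laplacian_kernel",
    "apply_sharpen",
    "apply_sharpen_more",
    "apply_sharpen_edges",
    "FilterSpec",
    "register_filter",
]

SHARPEN_ALPHA_RANGE = (0.7, 1.0)
SHARPEN_MORE_ALPHA_RANGE = (1.0, 1.3)
EDGE_K_RANGE = (1.1, 1.3)

_BORDER_MODES = {"reflect": "reflect", "replicate": "nearest"}

#: User-registered filters (name -> callable ImageFrame -> ImageFrame),
#: e.g. a stand-in for a vendor post-processing step.
_USER_FILTERS: dict[str, Callable[[ImageFrame], ImageFrame]] = {}


def register_filter(name: str, fn: Callable[[ImageFrame], ImageFrame]) -> None:
    _USER_FILTERS[name] = fn


def sharpen_kernel(alpha: float) -> np.ndarray:
    return np.array([[0.0, -1.0, 0.0], [-1.0, 1.0 + 4.0 * alpha, -1.0], [0.0, -1.0, 0.0]])


def laplacian_kernel() -> np.ndarray:
    k = -np.ones((3, 3))
    k[1, 1] = 8.0
    return k


def _check_range(value: float, lo: float, hi: float, what: str, override: bool) -> None:
    if not override and not (lo <= value <= hi):
        raise ConfigError(
            f"{what} = {value} outside the characterised range [{lo}, {hi}]; "
            "pass allow_out_of_range=True to force"
        )


def _convolve(frame: ImageFrame, kernel: np.ndarray, border_mode: str) -> np.ndarray:
    if frame.shape[0] < 3 or frame.shape[1] < 3:
        raise ValueError(f"frame {frame.shape} smaller than the 3x3 kernel")
    try:
        mode = _BORDER_MODES[border_mode]
    except KeyError:
        raise ConfigError(f"border_mode must be one of {sorted(_BORDER_MODES)}") from None
    return ndimage.convolve(frame.pixels, kernel, mode=mode)


def apply_sharpen(
    frame: ImageFrame,
    alpha: float = 1.0,
    border_mode: str = "reflect",
    allow_out_of_range: bool = False,
) -> ImageFrame:
    """4-neighbour sharpening, a in [0.7, 1.0]."""
    _check_range(alpha, *SHARPEN_ALPHA_RANGE, "sharpen alpha", allow_out_of_range)
    return frame.with_pixels(_convolve(frame, sharpen_kernel(alpha), border_mode))


def apply_sharpen_more(
    frame: ImageFrame,
    alpha: float = 1.15,
    border_mode: str = "reflect",
    allow_out_of_range: bool = False,
) -> ImageFrame:
    """Same kernel family at stronger alpha in [1.0, 1.3]."""
    _check_range(alpha, *SHARPEN_MORE_ALPHA_RANGE, "sharpen-more alpha", allow_out_of_range)
    return frame.with_pixels(_convolve(frame, sharpen_kernel(alpha), border_mode))


def apply_sharpen_edges(
    frame: ImageFrame,
    k_weight: float = 1.2,
    edge_threshold_quantile: float = 0.90,
    border_mode: str = "reflect",
    rescale: str = "signed",
    allow_out_of_range: bool = False,
) -> ImageFrame:
    """Thresholded Laplacian edge enhancement.

    rescale="signed" (default) maps max |response| onto the image's
    intensity range, preserving sign; "unsigned" maps the signed
    response range affinely onto [min, max] of the image.
    """
    _check_range(k_weight, *EDGE_K_RANGE, "edge k_weight", allow_out_of_range)
    if not (0.0 <= edge_threshold_quantile < 1.0):
        raise ConfigError(
            f"edge_threshold_quantile must be in [0,1), got {edge_threshold_quantile}"
        )
    lap = _convolve(frame, laplacian_kernel(), border_mode)
    span = float(frame.pixels.max() - frame.pixels.min())
    peak = float(np.abs(lap).max())
    if peak == 0.0 or span == 0.0:
        # constant image: the edge map is identically zero
        return frame.with_pixels(frame.pixels.copy())
    if rescale == "signed":
        edge = lap * (span / peak)
    elif rescale == "unsigned":
        lo, hi = float(lap.min()), float(lap.max())
        edge = (lap - lo) * (span / (hi - lo)) + float(frame.pixels.min())
    else:
        raise ConfigError(f"rescale must be signed|unsigned, got {rescale!r}")
    mags = np.abs(edge)
    nonzero = mags[mags > 0]
    threshold = float(np.quantile(nonzero, edge_threshold_quantile)) if nonzero.size else 0.0
    edge = np.where(mags < threshold, 0.0, edge)
    return frame.with_pixels(frame.pixels + k_weight * edge)


@dataclass(frozen=True)
class FilterSpec:
    """Named, validated filter configuration usable from configs/CLI."""

    name: str
    alpha: float | None = None
    k_weight: float | None = None
    edge_threshold_quantile: float | None = None
    border_mode: str = "reflect"
    allow_out_of_range: bool = False

    def __post_init__(self) -> None:
        known = {"sharpen", "sharpen_more", "sharpen_edges"}
        if self.name not in known and self.name not in _USER_FILTERS:
            raise ConfigError(f"unknown filter {self.name!r}; builtins: {sorted(known)}")
        if self.border_mode not in _BORDER_MODES:
            raise ConfigError(f"border_mode must be one of {sorted(_BORDER_MODES)}")
        if not self.allow_out_of_range:
            if self.name == "sharpen" and self.alpha is not None:
                _check_range(self.alpha, *SHARPEN_ALPHA_RANGE, "sharpen alpha", False)
            if self.name == "sharpen_more" and self.alpha is not None:
                _check_range(self.alpha, *SHARPEN_MORE_ALPHA_RANGE, "sharpen-more alpha", False)
            if self.name == "sharpen_edges" and self.k_weight is not None:
                _check_range(self.k_weight, *EDGE_K_RANGE, "edge k_weight", False)

    def apply(self, frame: ImageFrame) -> ImageFrame:
        if self.name == "sharpen":
            out = apply_sharpen(
                frame, self.alpha if self.alpha is not None else 1.0,
                self.border_mode, self.allow_out_of_range,
            )
        elif self.name == "sharpen_more":
            out = apply_sharpen_more(
                frame, self.alpha if self.alpha is not None else 1.15,
                self.border_mode, self.allow_out_of_range,
            )
        elif self.name == "sharpen_edges":
            out = apply_sharpen_edges(
                frame,
                self.k_weight if self.k_weight is not None else 1.2,
                self.edge_threshold_quantile
                if self.edge_threshold_quantile is not None
                else 0.90,
                self.border_mode,
                allow_out_of_range=self.allow_out_of_range,
            )
        else:
            out = _USER_FILTERS[self.name](frame)
        out.label = self.name
        return out
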