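"""Synthetic bar-pattern and flat-field generator with known ground truth.

The generator emulates a linearised flat-panel mammography detector:
mean pixel value = offset + G·X, with G the gain in DU/µGy and X the
entrance air kerma in µGy (defaults G = 2471 DU/µGy, offset = 32 DU,
100 µm pixels).  The resolution phantom is a lead bar pattern whose
groups span 0.25–10 mm⁻¹; the default group set stops at the 5 mm⁻¹
Nyquist frequency of a 0.1 mm detector.

Image formation model
---------------------
1. A continuous transmission profile t(x) ∈ [0, 1] (0 under a lead bar,
   1 in a space) is built on a 16× supersampled grid.
2. t is convolved with a Gaussian PSF of width ``blur_sigma_mm`` and
   sampled pointwise at pixel centres.
3. The mean signal is offset + G·X·t.
4. Noise is added last: the quantum term draws a Poisson count per pixel
   with expectation quanta_per_mm2_uGy · pitch² · X · t, scaled back to
   DU, plus additive Gaussian read noise.  Per-pixel variance of a flat
   field is therefore G²·X/(quanta_per_mm2_uGy·pitch²) + read_sigma_DU².

The quantum noise parameter defaults to 7000 quanta/mm²/µGy so that the
default working exposure of 100 µGy yields a flat-field CV ≈ 1.2%,
typical of a mammography detector operated in its linear range.

Scatter, grids, heel effect and detector-element defects are not
modelled.  Group frequencies above Nyquist are generated (the sampling
step aliases them naturally) with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .exceptions import ConfigError
from .image_model import AcquisitionContext, ImageFrame, RegionOfInterest, write_image

__all__ = [
    "DEFAULT_FREQUENCIES_PER_MM",
    "PoissonGaussianNoise",
    "DetectorModel",
    "BarPatternLayout",
    "design_bar_layout",
    "make_bar_pattern",
    "make_flat_field",
    "make_exposure_series",
    "save_layout",
    "load_layout",
    "write_fixture_set",
]

#: Sub-Nyquist default group frequencies (mm^-1) for a 0.1 mm detector.
#: The physical pattern continues to 10 mm^-1; pass a longer list to mirror it.
DEFAULT_FREQUENCIES_PER_MM = (0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0)

_SUPERSAMPLE = 16


@dataclass(frozen=True)
class PoissonGaussianNoise:
    """Quantum (Poisson) plus electronic (Gaussian, in DU) noise."""

    read_sigma_DU: float = 300.0
    quanta_per_mm2_uGy: float = 7000.0

    def __post_init__(self) -> None:
        if self.read_sigma_DU < 0:
            raise ConfigError(f"read_sigma_DU must be >= 0, got {self.read_sigma_DU}")
        if self.quanta_per_mm2_uGy <= 0:
            raise ConfigError(f"quanta_per_mm2_uGy must be > 0, got {self.quanta_per_mm2_uGy}")


@dataclass(frozen=True)
class DetectorModel:
    """Linear detector characteristic plus PSF and noise model."""

    gain_DU_per_uGy: float = 2471.0
    offset_DU: float = 32.0
    blur_sigma_mm: float = 0.0
    noise: PoissonGaussianNoise | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain_DU_per_uGy <= 0:
            raise ConfigError(f"gain must be > 0, got {self.gain_DU_per_uGy}")
        if self.blur_sigma_mm < 0:
            raise ConfigError(f"blur_sigma_mm must be >= 0, got {self.blur_sigma_mm}")

    def flat_variance_DU2(self, kerma_uGy: float, pitch_mm: float) -> float:
        """Model per-pixel variance of a flat field at the given exposure."""
        if self.noise is None:
            return 0.0
        pixel_area = pitch_mm * pitch_mm
        quantum = (
            self.gain_DU_per_uGy**2 * kerma_uGy / (self.noise.quanta_per_mm2_uGy * pixel_area)
        )
        return quantum + self.noise.read_sigma_DU**2


@dataclass
class BarPatternLayout:
    """Ground-truth geometry of a bar phantom.

    One bounding box per group frequency; bars run perpendicular to the
    scan direction (``vertical`` bars vary along columns).  ``high_DU``
    and ``low_DU`` are the nominal space/bar levels and are filled in by
    :func:`make_bar_pattern` when left as None.
    """

    group_frequencies_per_mm: tuple[float, ...]
    group_boxes: tuple[RegionOfInterest, ...]
    bar_orientation: str = "vertical"
    high_DU: float | None = None
    low_DU: float | None = None
    #: Sub-pixel shift of every group's leading bar edge relative to its box
    #: origin.  A non-zero default breaks the accidental symmetry between the
    #: pixel grid and bar centres at grid-commensurate frequencies, which
    #: would otherwise make the profile extrema unrecoverable from samples.
    bar_phase_px: float = 0.25

    def __post_init__(self) -> None:
        freqs = tuple(float(f) for f in self.group_frequencies_per_mm)
        if len(freqs) == 0:
            raise ConfigError("layout needs at least one group frequency")
        if any(f <= 0 for f in freqs) or any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise ConfigError("group frequencies must be strictly increasing and positive")
        if len(self.group_boxes) != len(freqs):
            raise ConfigError("one bounding box required per group frequency")
        if self.bar_orientation not in ("vertical", "horizontal"):
            raise ConfigError(f"bar_orientation must be vertical|horizontal, got {self.bar_orientation}")
        if self.high_DU is not None and self.low_DU is not None and not (self.high_DU > self.low_DU):
            raise ConfigError("high_DU must exceed low_DU")
        self.group_frequencies_per_mm = freqs
        self.group_boxes = tuple(self.group_boxes)


def design_bar_layout(
    frequencies_per_mm=DEFAULT_FREQUENCIES_PER_MM,
    pitch_mm: float = 0.1,
    n_periods: int = 4,
    box_height_px: int = 64,
    margin_px: int = 8,
    gap_line_pairs: float = 2.0,
    orientation: str = "vertical",
) -> tuple[BarPatternLayout, tuple[int, int]]:
    """Lay bar groups left-to-right with guard gaps and return the layout
    plus the minimal frame shape that contains it.

    Each group spans ``n_periods`` full line pairs and starts with a bar
    edge exactly on a pixel boundary; gaps between groups are at least
    ``gap_line_pairs`` periods of the local group so that profile
    extraction never mixes groups.
    """
    if n_periods < 3:
        raise ConfigError("groups need at least 3 full line pairs")
    freqs = tuple(float(f) for f in frequencies_per_mm)
    boxes = []
    col = margin_px
    for f in freqs:
        period_px = 1.0 / (f * pitch_mm)
        # prefer a whole number of periods that is also a whole number of
        # pixels: the group profile is then exactly periodic over its box
        best_m, best_frac = n_periods, 1.0
        for m in range(n_periods, n_periods + 7):
            frac = abs(m * period_px - round(m * period_px))
            if frac < best_frac - 1e-9:
                best_m, best_frac = m, frac
            if frac < 1e-6:
                break
        width = int(math.ceil(best_m * period_px - 1e-9))
        boxes.append(RegionOfInterest(margin_px, col, box_height_px, width))
        col += width + max(8, int(math.ceil(gap_line_pairs * period_px)))
    n_rows = box_height_px + 2 * margin_px
    n_cols = boxes[-1].col0 + boxes[-1].n_cols + margin_px
    shape = (n_rows, n_cols)
    layout = BarPatternLayout(freqs, tuple(boxes), bar_orientation="vertical")
    if orientation == "horizontal":
        layout = _transpose_layout(layout)
        shape = (shape[1], shape[0])
    return layout, shape


def _transpose_layout(layout: BarPatternLayout) -> BarPatternLayout:
    boxes = tuple(
        RegionOfInterest(b.col0, b.row0, b.n_cols, b.n_rows) for b in layout.group_boxes
    )
    orientation = "horizontal" if layout.bar_orientation == "vertical" else "vertical"
    return replace(layout, group_boxes=boxes, bar_orientation=orientation)


def _transmission_profile(
    layout: BarPatternLayout, n_cols: int, pitch_mm: float, blur_sigma_mm: float
) -> np.ndarray:
    """Blurred transmission sampled at pixel centres (1-D, length n_cols)."""
    s = _SUPERSAMPLE
    x = np.arange(n_cols * s, dtype=np.float64) / s  # positions in pixel units
    t = np.ones_like(x)
    # Bars are extended a little past each measurement box (into half the
    # guard gap) so that, under blur, the profile INSIDE the box remains
    # exactly periodic instead of picking up bright-gap bleed at its edges.
    groups = sorted(
        zip(layout.group_frequencies_per_mm, layout.group_boxes), key=lambda g: g[1].col0
    )
    edges = [0.0] + [
        0.5 * (a.col0 + a.n_cols + b.col0) for (_, a), (_, b) in zip(groups, groups[1:])
    ] + [float(n_cols)]
    for (f, box), lo, hi in zip(groups, edges[:-1], edges[1:]):
        period_px = 1.0 / (f * pitch_mm)
        c0, c1 = box.col0, box.col0 + box.n_cols
        ext = 2.0 * period_px
        start = max(lo, c0 - ext)
        stop = min(hi, c1 + ext)
        u = (x - c0 - layout.bar_phase_px) / period_px
        inside = (x >= start) & (x < stop)
        bar = np.mod(u, 1.0) < 0.5  # bar first at the box origin (plus phase)
        t[inside & bar] = 0.0
    if blur_sigma_mm > 0:
        sigma_super = blur_sigma_mm / pitch_mm * s
        t = gaussian_filter1d(t, sigma_super, mode="nearest")
    centre = np.arange(n_cols) * s + s // 2  # supersample index of each pixel centre
    return t[centre]


def _realize(
    transmission: np.ndarray,
    detector: DetectorModel,
    kerma_uGy: float,
    pitch_mm: float,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Mean signal from transmission, with the detector's noise if any."""
    mean = detector.offset_DU + detector.gain_DU_per_uGy * kerma_uGy * transmission
    if detector.noise is None or rng is None:
        return mean
    noise = detector.noise
    pixel_area = pitch_mm * pitch_mm
    lam = noise.quanta_per_mm2_uGy * pixel_area * kerma_uGy * np.clip(transmission, 0.0, None)
    du_per_quantum = detector.gain_DU_per_uGy / (noise.quanta_per_mm2_uGy * pixel_area)
    quanta = rng.poisson(lam).astype(np.float64)
    pixels = detector.offset_DU + du_per_quantum * quanta
    if noise.read_sigma_DU > 0:
        pixels = pixels + rng.normal(0.0, noise.read_sigma_DU, size=pixels.shape)
    return pixels


def make_bar_pattern(
    layout: BarPatternLayout,
    detector: DetectorModel,
    kerma_uGy: float,
    frame_shape: tuple[int, int],
    pitch_mm: float,
) -> tuple[ImageFrame, BarPatternLayout]:
    """Render the bar phantom and return the frame plus the ground truth.

    Bars absorb fully (transmission 0), spaces and the open field
    transmit fully, so the nominal levels are low = offset and
    high = offset + G·X.
    """
    if kerma_uGy < 0:
        raise ConfigError(f"kerma must be >= 0, got {kerma_uGy}")
    work = layout if layout.bar_orientation == "vertical" else _transpose_layout(layout)
    work_shape = frame_shape if layout.bar_orientation == "vertical" else frame_shape[::-1]
    for f, box in zip(work.group_frequencies_per_mm, work.group_boxes):
        box.check_inside(work_shape)
        period_px = 1.0 / (f * pitch_mm)
        if box.n_cols < 3 * period_px:
            raise ConfigError(
                f"group at {f} mm^-1 spans {box.n_cols} px < 3 line pairs ({3 * period_px:.1f} px)"
            )
        if f > 1.0 / (2.0 * pitch_mm) and detector.blur_sigma_mm == 0:
            warnings.warn(
                f"group frequency {f} mm^-1 exceeds Nyquist {1.0 / (2 * pitch_mm)} mm^-1; "
                "it will alias",
                stacklevel=2,
            )

    profile_t = _transmission_profile(work, work_shape[1], pitch_mm, detector.blur_sigma_mm)
    t2d = np.broadcast_to(profile_t, work_shape).copy()
    rng = np.random.default_rng(detector.seed) if detector.noise is not None else None
    pixels = _realize(t2d, detector, kerma_uGy, pitch_mm, rng)
    if layout.bar_orientation == "horizontal":
        pixels = pixels.T.copy()

    truth = replace(
        layout,
        high_DU=detector.offset_DU + detector.gain_DU_per_uGy * kerma_uGy,
        low_DU=detector.offset_DU,
    )
    frame = ImageFrame(
        pixels=pixels,
        pixel_pitch_mm=pitch_mm,
        acquisition=AcquisitionContext(air_kerma_uGy=kerma_uGy),
        label="bar_pattern",
    )
    return frame, truth


def make_flat_field(
    detector: DetectorModel,
    kerma_uGy: float,
    frame_shape: tuple[int, int],
    pitch_mm: float,
    _rng: np.random.Generator | None = None,
) -> ImageFrame:
    """Uniformly exposed frame with mean offset + G·X."""
    if kerma_uGy < 0:
        raise ConfigError(f"kerma must be >= 0, got {kerma_uGy}")
    rng = _rng
    if rng is None and detector.noise is not None:
        rng = np.random.default_rng(detector.seed)
    t = np.ones(frame_shape, dtype=np.float64)
    pixels = _realize(t, detector, kerma_uGy, pitch_mm, rng)
    return ImageFrame(
        pixels=pixels,
        pixel_pitch_mm=pitch_mm,
        acquisition=AcquisitionContext(air_kerma_uGy=kerma_uGy),
        label="flat",
    )


def make_exposure_series(
    detector: DetectorModel,
    kermas_uGy,
    frame_shape: tuple[int, int],
    pitch_mm: float,
) -> list[ImageFrame]:
    """One flat field per kerma, drawn from a single seeded noise stream."""
    kermas = [float(k) for k in kermas_uGy]
    if not kermas:
        raise ConfigError("kermas_uGy must be non-empty")
    rng = np.random.default_rng(detector.seed) if detector.noise is not None else None
    return [make_flat_field(detector, k, frame_shape, pitch_mm, _rng=rng) for k in kermas]


# ---------------------------------------------------------------------------
# Fixture-set serialisation (plain text + npy, consumed by the CLI)


def save_layout(layout: BarPatternLayout, path: str | Path) -> None:
    import yaml

    doc = {
        "group_frequencies_per_mm": list(layout.group_frequencies_per_mm),
        "group_boxes": [
            {"row0": b.row0, "col0": b.col0, "n_rows": b.n_rows, "n_cols": b.n_cols}
            for b in layout.group_boxes
        ],
        "bar_orientation": layout.bar_orientation,
        "high_DU": layout.high_DU,
        "low_DU": layout.low_DU,
        "bar_phase_px": layout.bar_phase_px,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_layout(path: str | Path) -> BarPatternLayout:
    import yaml

    doc = yaml.safe_load(Path(path).read_text())
    boxes = tuple(RegionOfInterest(**b) for b in doc["group_boxes"])
    return BarPatternLayout(
        group_frequencies_per_mm=tuple(doc["group_frequencies_per_mm"]),
        group_boxes=boxes,
        bar_orientation=doc.get("bar_orientation", "vertical"),
        high_DU=doc.get("high_DU"),
        low_DU=doc.get("low_DU"),
        bar_phase_px=doc.get("bar_phase_px", 0.25),
    )


def write_fixture_set(
    directory: str | Path,
    detector: DetectorModel,
    kerma_uGy: float,
    pitch_mm: float = 0.1,
    frequencies_per_mm=DEFAULT_FREQUENCIES_PER_MM,
    flat_shape: tuple[int, int] = (512, 512),
) -> dict[str, Path]:
    """Write a pattern + flat + layout fixture set; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    layout, pattern_shape = design_bar_layout(frequencies_per_mm, pitch_mm)
    pattern, truth = make_bar_pattern(layout, detector, kerma_uGy, pattern_shape, pitch_mm)
    flat = make_flat_field(replace(detector, seed=detector.seed + 1), kerma_uGy, flat_shape, pitch_mm)
    paths = {
        "pattern": write_image(pattern, directory / "pattern.npy"),
        "flat": write_image(flat, directory / "flat.npy"),
        "layout": directory / "layout.yaml",
    }
    save_layout(truth, paths["layout"])
    return paths
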