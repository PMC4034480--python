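"""Combined quality indices: NEQ, figure of image quality, information
capacity.

NEQ(f) = SPS(f)/NPS(f) is the frequency-dependent effective SNR².  The
figure of image quality condenses resolution and noise into one scalar,

    FIQ_T = ( Σ_f MTF(f) ) / CV        (all measured frequencies)
    FIQ_R = ( Σ_{f1<=f<=f2} MTF(f) ) / CV   (one frequency band)

where the sum runs over the discrete measured MTF samples (the bar-group
frequencies) and CV is a fraction.  Shannon information capacity per
unit area for a rotationally symmetric system is

    IC = π ∫0^fmax log2(1 + SPS(f)/NPS(f)) · f df    [bits/mm²],

evaluated by trapezoidal quadrature with the upper limit defaulting to
the highest frequency both spectra cover (practically the Nyquist
frequency; the nominal infinite bound is always truncated).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .noise_metrics import normalize_nps
from .resolution_metrics import FrequencySeries, signal_power_spectrum

__all__ = [
    "DEFAULT_BANDS",
    "QualityReport",
    "neq",
    "fiq_total",
    "fiq_range",
    "information_capacity",
    "build_report",
]

DEFAULT_BANDS = ((0.0, 2.0), (2.0, 5.0), (5.0, 8.0))


def _common_grid(sps: FrequencySeries, nps: FrequencySeries):
    """Both series linearly interpolated onto the overlap of their ranges
    (sampled at the NPS frequencies, usually the finer regular grid)."""
    lo = max(sps.f_min, nps.f_min)
    hi = min(sps.f_max, nps.f_max)
    if hi <= lo:
        raise ValueError(
            f"series do not overlap: [{sps.f_min},{sps.f_max}] vs [{nps.f_min},{nps.f_max}]"
        )
    grid = nps.frequencies_per_mm
    grid = grid[(grid >= lo) & (grid <= hi)]
    if grid.size < 2:
        grid = np.linspace(lo, hi, 16)
    return grid, sps.interp(grid), nps.interp(grid)


def neq(sps: FrequencySeries, nps: FrequencySeries) -> FrequencySeries:
    """Pointwise SPS/NPS on a common grid."""
    grid, s, n = _common_grid(sps, nps)
    zero = n <= 0
    if np.any(zero):
        f_bad = grid[zero][0]
        raise ValueError(f"NPS is zero at {f_bad:.4g} mm^-1; NEQ undefined there")
    return FrequencySeries(grid, s / n, kind="NEQ")


def fiq_total(mtf: FrequencySeries, cv: float, f_max: float | None = None) -> float:
    """Sum of the measured MTF samples divided by CV (a fraction).

    ``f_max`` optionally restricts the sum, e.g. to the Nyquist
    frequency when the measured grid extends beyond it.
    """
    if cv <= 0:
        raise ValueError(f"CV must be positive, got {cv}")
    values = mtf.values
    if f_max is not None:
        values = values[mtf.frequencies_per_mm <= f_max]
        if values.size == 0:
            raise ValueError(f"no MTF samples at or below {f_max} mm^-1")
    return float(values.sum()) / cv


def fiq_range(mtf: FrequencySeries, cv: float, f1: float, f2: float) -> float:
    """Band-limited figure of image quality over the closed band [f1, f2]."""
    if cv <= 0:
        raise ValueError(f"CV must be positive, got {cv}")
    if not (f1 < f2):
        raise ValueError(f"need f1 < f2, got [{f1}, {f2}]")
    band = mtf.restrict(f1, f2)  # raises on an empty band, naming it
    return float(band.values.sum()) / cv


def information_capacity(
    sps: FrequencySeries, nps: FrequencySeries, f_max: float | None = None
) -> float:
    """π ∫ log2(1 + SPS/NPS) · f df over [grid start, f_max], bits/mm²."""
    grid, s, n = _common_grid(sps, nps)
    if f_max is None:
        f_max = float(grid[-1])
    # radial NPS grids end at a bin centre half a step below Nyquist; an
    # f_max within one grid step of the last sample just truncates there
    step = float(grid[-1] - grid[-2]) if grid.size > 1 else 0.0
    if f_max > grid[-1] + step + 1e-9:
        raise ValueError(f"f_max {f_max} exceeds the common grid maximum {grid[-1]:.4g}")
    keep = grid <= f_max + 1e-12
    grid, s, n = grid[keep], s[keep], n[keep]
    if np.any(n <= 0):
        raise ValueError("NPS must be positive below f_max")
    integrand = np.log2(1.0 + s / n) * grid
    return float(np.pi * np.trapezoid(integrand, grid))


@dataclass
class QualityReport:
    """Assembled scalar indices and the curves that produced them."""

    label: str
    cv: float
    mtf_sum_total: float
    fiq_total: float
    fiq_bands: list[tuple[float, float, float]]
    ic_bits_per_mm2: float
    curves: dict[str, FrequencySeries] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "cv": self.cv,
            "mtf_sum_total": self.mtf_sum_total,
            "fiq_total": self.fiq_total,
            "fiq_bands": [[f1, f2, v] for f1, f2, v in self.fiq_bands],
            "ic_bits_per_mm2": self.ic_bits_per_mm2,
            "parameters": self.parameters,
            "curves": {
                name: {
                    "kind": s.kind,
                    "frequencies_per_mm": s.frequencies_per_mm.tolist(),
                    "values": s.values.tolist(),
                }
                for name, s in self.curves.items()
            },
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "QualityReport":
        curves = {
            name: FrequencySeries(
                np.array(c["frequencies_per_mm"]), np.array(c["values"]), c["kind"]
            )
            for name, c in doc.get("curves", {}).items()
        }
        return cls(
            label=doc["label"],
            cv=doc["cv"],
            mtf_sum_total=doc["mtf_sum_total"],
            fiq_total=doc["fiq_total"],
            fiq_bands=[tuple(b) for b in doc["fiq_bands"]],
            ic_bits_per_mm2=doc["ic_bits_per_mm2"],
            curves=curves,
            parameters=doc.get("parameters", {}),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "QualityReport":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_report(
    label: str,
    mtf: FrequencySeries,
    nps: FrequencySeries,
    cv: float,
    gain: float,
    kerma_uGy: float,
    nnps: FrequencySeries | None = None,
    bands=DEFAULT_BANDS,
    k_const: float = 1.07,
    f_max: float | None = None,
) -> QualityReport:
    """Compute SPS, NEQ, FIQ_T, per-band FIQ_R and IC for one image."""
    sps = signal_power_spectrum(mtf, gain, k_const)
    if nnps is None:
        nnps = normalize_nps(nps, gain, kerma_uGy)
    neq_series = neq(sps, nps)
    mtf_sum = float(mtf.values.sum() if f_max is None
                    else mtf.values[mtf.frequencies_per_mm <= f_max].sum())
    fiq_t = mtf_sum / cv if cv > 0 else _raise_cv(cv)
    fiq_bands = [(f1, f2, fiq_range(mtf, cv, f1, f2)) for f1, f2 in bands]
    ic = information_capacity(sps, nps, f_max=f_max)
    return QualityReport(
        label=label,
        cv=cv,
        mtf_sum_total=mtf_sum,
        fiq_total=fiq_t,
        fiq_bands=fiq_bands,
        ic_bits_per_mm2=ic,
        curves={"mtf": mtf, "sps": sps, "nps": nps, "nnps": nnps, "neq": neq_series},
        parameters={
            "gain_DU_per_uGy": gain,
            "kerma_uGy": kerma_uGy,
            "k_const": k_const,
            "f_max_per_mm": f_max,
            "bands": [list(b) for b in bands],
            "fiq_grid": "measured MTF sample frequencies",
        },
    )


def _raise_cv(cv: float):
    raise ValueError(f"CV must be positive, got {cv}")
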