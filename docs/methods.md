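# Methods

This note records the measurement models implemented in `mamiq`, the
defaults and why they were chosen, what the synthetic phantoms do and do
not emulate, and the numerical decisions that were genuinely open.

## Detector model and linearisation

All frequency-domain metrics assume a linear (or linearised) detector:
mean pixel value MPV = a + G·X with entrance air kerma X in µGy.  The
characteristic is fitted by ordinary least squares
(`detector_response.fit_response`), reporting the intercept a (the DU
offset at zero kerma), the slope G (gain, DU/µGy), R², and the standard
error of the slope.  Weighted fits are deliberately out of scope; a
`force_offset` argument lets a dark-frame measurement fix the intercept.
Defaults throughout mirror a CsI/TFT full-field mammography panel:
G = 2471 DU/µGy, offset 32 DU, 0.1 mm pixels (Nyquist 5 mm⁻¹).

## Bar-pattern CTF and extremum read-off

`resolution_metrics.measure_ctf` averages `profile_lines` (default 8)
scan lines perpendicular to the bars into one profile per group, finds
alternating local extrema using the known bar period as a prior
(`scipy.signal.find_peaks` with a minimum spacing of 0.7 periods), and
forms CTF(f) = (Ī_max − Ī_min)/(Ī_max + Ī_min) after subtracting the
fitted detector offset when a response fit is supplied.  Groups in which
fewer than two maxima or minima can be found are omitted from the output
and logged — never reported as zero.

Reading extremum *values* straight off the sampled profile is biased:
at 4 mm⁻¹ on a 0.1 mm grid there are 2.5 samples per period and no
sample need fall on a bar centre, which loses up to ~25% of the
modulation.  The profile is therefore reconstructed band-limited
(FFT resampling, 16×) before read-off.  Two regimes are distinguished:

* If the profile spans a whole number of bar periods and pixels it is
  treated as exactly periodic and resampled without padding (no edge
  effects).  Otherwise it is reflect-padded by one period and extrema
  within half a period of the ends are discarded.
* If the profile is **binary** (exactly two DU levels — the signature of
  a noise-free, unblurred square wave) the raw sample values are used
  directly: they are exact there, while a band-limited reconstruction of
  ideal edges would ring (Gibbs) and overshoot.

Limits of validity: a sampled profile cannot distinguish a square wave
from a larger-amplitude sinusoid when the sampling phase is symmetric
about the bar centres, and at exactly Nyquist the quadrature component
of the modulation is invisible.  The synthetic layout therefore offsets
every group's bar phase by 0.25 px to break the symmetry, and accuracy
claims stop at 0.8× Nyquist (4 mm⁻¹ at 0.1 mm pitch): against an
analytic Gaussian MTF the full chain agrees within 5% there (typically
< 1% at PSF σ = 0.08 mm).  Sharper PSFs (σ ≲ 0.05 mm) push bar
harmonics past Nyquist and alias them into the pass band; the resulting
few-percent wiggles are a property of the sampled data, not of the
estimator.

## Coltman conversion

MTF(f) = (π/4)[C(f) + C(3f)/3 − C(5f)/5 + C(7f)/7], with C linearly
interpolated at harmonic frequencies and taken as zero beyond the
highest measured group (standard practice).  `harmonics` ∈ 1..4 controls
the truncation.  The `coltman1954` sign-convention flag is accepted for
completeness: the published 1954 coefficient rule and the series above
coincide through the 7f term and first diverge beyond it, so at this
truncation the flag changes nothing.  By default the curve is
renormalised to 1 at the lowest measured frequency, since published MTF
curves start at 1; the flag `renormalize=False` gives the raw series.

## Signal power spectrum

SPS(f) = k·(MTF(f)·G)².  The scale constant k defaults to 1.07.  Its
published units ("mGy", multiplying squared digital units) are
dimensionally puzzling; `k_const` is therefore treated as a plain
configurable scalar and all downstream quantities (NEQ, IC) scale
accordingly.

## Noise

* **CV** uses the sample standard deviation (n−1) over the mean of a
  uniform ROI.  The reference description is ambiguous between "100
  pixels" and "100 × 100 pixels"; the default ROI is 100×100 and the
  size is a parameter.
* **2-D NPS**: overlapping square ROIs (default 128 px, 50% overlap),
  per-ROI mean subtraction (a planar detrend is available for
  gradient-contaminated flats), no spectral window (none is applied in
  the reference procedure; windowing would be a documented non-default
  extension).  NPS = ⟨|FFT₂(p)|²⟩·ΔxΔy/(N_xN_y), in mm² for a
  linearised signal.  The estimator satisfies Parseval exactly up to the
  excluded DC bin: the white-noise acceptance check recovers σ²·ΔxΔy per
  bin within 3% and the integrated variance within 2% on a 512² frame.
* **Radial 1-D NPS**: every non-DC bin contributes at radius
  √(f_x²+f_y²); equal-width radial bins up to the axis Nyquist (default
  width = one axis frequency step) are averaged and interpolated onto a
  constant-interval grid.  The f_x = 0 and f_y = 0 axes are included by
  default (`include_axes=False` drops them when row/column artefacts
  dominate).
* **NNPS** = NPS/(G·X)².

## Indices

* **NEQ** = SPS/NPS on a common grid (both series linearly interpolated
  onto the overlap, sampled at the NPS frequencies — normally the finer
  regular grid).
* **FIQ** sums the MTF samples at the *measured bar-group frequencies*,
  not on a resampled fine grid: with ~12 groups this matches the
  magnitude of published "sum of MTF" rows (≈10–12), and the grid choice
  is recorded in every report.  FIQ_R bands are closed intervals;
  partition checks in the tests place band boundaries between sample
  frequencies so each sample counts exactly once.
* **IC** = π∫log₂(1+SPS/NPS)·f df by trapezoidal quadrature (no method
  is prescribed by the reference; the closed-form constant-SNR case is
  reproduced to 0.1% at 65 grid points).  The nominal infinite upper
  limit is truncated at the detector Nyquist frequency by default and is
  configurable — IC depends materially on this bandwidth, so reports
  record it.  A radial NPS grid ends half a bin below Nyquist; an
  `f_max` within one grid step of the last sample simply truncates
  there.

## Sharpening filters

The sharpen family kernel `[0 −1 0; −1 1+4α −1; 0 −1 0]` has DC gain
4α−3: it preserves constants only at α = 1 (the identity checks in the
tests).  Defaults: α = 1.0 ("sharpen"), α = 1.15 ("sharpen more",
midpoint of its range), k = 1.2 and edge-threshold quantile 0.90
("sharpen edges").  The characterisation gives ranges, not points, and
does not state the edge-histogram threshold level; 0.90 is a documented
guess, always exposed as a parameter.  Edge rescaling maps the maximum
absolute Laplacian response onto the image's intensity range with sign
preserved; an unsigned affine mapping is available.  Borders use
reflection by default (replication optional); outputs stay in floating
point, and clamping happens only on export.

Known limitation: with these kernels, white-noise CV ordering between
"sharpen more" and "sharpen" cannot match the published noise table.
CV is scale-invariant and the α > 1 kernel trades a larger DC gain
(4α−3 = 1.6 at α = 1.15) against a sub-proportional noise amplification
(√35.4 ≈ 5.9 vs √29 ≈ 5.4 at α = 1), so CV("sharpen more") <
CV("sharpen") on a white-noise flat.  The published ordering must stem
from processing internals (clamping, renormalisation) that the kernel
characterisation does not capture.  The tests assert what the kernels
do guarantee: both filters raise the CV of a noisy flat relative to the
raw image.

## Synthetic phantoms

The generator emulates: a linear detector with configurable gain/offset,
an isotropic Gaussian PSF, a bar pattern with groups 0.25–10 mm⁻¹ (the
default group set stops at the 5 mm⁻¹ Nyquist of 0.1 mm pixels; the
physical pattern's super-Nyquist groups can be enabled and alias, with a
warning), and Poisson quantum noise plus Gaussian read noise added after
blur.  Noise defaults — 7000 quanta/mm²/µGy and 300 DU read noise — are
set so the default working exposure of 100 µGy gives a flat-field
CV ≈ 1.2%, typical of a mammography detector in its linear range.
Geometry details that matter for measurement accuracy: groups span a
whole number of periods *and* pixels, bars extend two periods into the
guard gaps so the in-box profile stays periodic under blur, and every
group's bar phase is offset 0.25 px from the pixel grid.

Not emulated: scatter, anti-scatter grid artefacts, heel effect,
detector element defects, fixed-pattern noise, detector lag, and
anatomical backgrounds.  Passing tests therefore demonstrate the
correctness of the measurement chain on a linear shift-invariant,
white-plus-Poisson detector — not robustness to structured clinical
noise.

## Problem sizes and determinism

Default analysis sizes: 512×512 flats (49 NPS ROIs at 128 px / 50%
overlap), ~750×80 px bar patterns (12 groups, ≥4 periods each),
exposure series of 6 points at 64×64.  Every stochastic stage takes an
explicit integer seed (configs without a seed are rejected), and a fixed
seed makes pipeline outputs byte-identical across runs.
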