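# mamiq

Physical image-quality measurement chain for digital mammography:
detector response, bar-pattern MTF via Coltman's square-wave method,
noise power spectra, noise equivalent quanta, a combined **figure of
image quality (FIQ)**, and Shannon **information capacity (IC)** — plus
the three generic sharpening filters ("sharpen", "sharpen more",
"sharpen edges") whose reverse-engineered kernels the chain is designed
to score, and a synthetic phantom generator so every metric is testable
without clinical data.

It is written for medical physicists and image-processing researchers
who want to quantify what a post-processing filter does to resolution
and noise — in a single scalar as well as per frequency band.

## The measurements

With a linearised detector (mean pixel value MPV = a + G·X, gain *G* in
DU/µGy, entrance air kerma *X* in µGy):

* **CTF** from a lead bar pattern (groups 0.25–10 mm⁻¹):
  CTF(f) = (I_max − I_min) / (I_max + I_min), from the local extrema of
  scan-line profiles taken perpendicular to the bars.
* **MTF** by Coltman's square-to-sine conversion, truncated at the 7f
  harmonic: MTF(f) = (π/4)[C(f) + C(3f)/3 − C(5f)/5 + C(7f)/7].
* **SPS**(f) = k·(MTF(f)·G)², the signal power spectrum (k = 1.07 by
  default).
* **CV** = σ/MPV in a uniform 100×100-pixel region.
* **NPS**(f_x, f_y) = ⟨|DFT₂(p)|²⟩·ΔxΔy/(N_xN_y) over overlapping
  128×128 ROIs of a flat field, radially averaged to 1-D;
  **NNPS** = NPS/(G·X)².
* **NEQ**(f) = SPS(f)/NPS(f).
* **FIQ_T** = Σ_f MTF(f) / CV over the measured bar-group frequencies up
  to Nyquist, and **FIQ_R** the same sum restricted to a band [f₁, f₂].
* **IC** = π ∫ log₂(1 + SPS/NPS) · f df in bits/mm² (rotationally
  symmetric Shannon capacity, truncated at Nyquist by default).

The three filters are 3×3 convolutions: the sharpen family
`[0 −1 0; −1 1+4α −1; 0 −1 0]` (α ∈ [0.7, 1.0] for "sharpen",
[1.0, 1.3] for "sharpen more") and a thresholded 8-neighbour Laplacian
added back with weight k ∈ [1.1, 1.3] for "sharpen edges".

## Worked example

The default pipeline synthesises a typ-53-style bar pattern and a flat
field from a linear detector model (G = 2471 DU/µGy, offset 32 DU,
100 µm pixels, Gaussian PSF σ = 0.08 mm, Poisson + read noise at
100 µGy), measures the raw image and the three filtered versions, and
assembles one quality report each:

```python
from mamiq.cli_reporting import PipelineConfig, run_pipeline, compare_reports

config = PipelineConfig.from_dict({"seed": 7})
reports = run_pipeline(config)
for r in reports:
    print(f"{r.label:14s} CV = {100*r.cv:5.3f}%   sum MTF = {r.mtf_sum_total:6.3f}   "
          f"FIQ_T = {r.fiq_total:6.1f}   IC = {r.ic_bits_per_mm2:6.2f} bits/mm^2")
```

prints

```
raw            CV = 1.189%   sum MTF =  6.376   FIQ_T =  536.2   IC =  96.96 bits/mm^2
sharpen        CV = 6.402%   sum MTF =  9.035   FIQ_T =  141.1   IC =  69.42 bits/mm^2
sharpen_more   CV = 4.418%   sum MTF =  8.520   FIQ_T =  192.8   IC =  52.15 bits/mm^2
sharpen_edges  CV = 2.719%   sum MTF =  8.383   FIQ_T =  308.3   IC =  88.50 bits/mm^2
```

Reading the numbers: every filter raises the MTF sum (better resolution)
but also amplifies white noise, raising CV; FIQ_T trades the two off.
On these synthetic flats the raw image wins overall and "sharpen edges"
is the best filter — it buys most of the resolution for the least noise.
`compare_reports(reports)` prints the full ranking table (FIQ_T, each
FIQ_R band, IC) and flags when FIQ_T and IC disagree, which happens
because IC also weighs the *shape* of the noise spectrum:

```
               FIQ_T  IC_bits_per_mm2      CV  FIQ_R[0-2]  FIQ_R[2-5]  FIQ_R[5-8]  ...
raw            536.2            96.96 0.01189       433.2       153.7       2.725
sharpen_edges  308.3             88.5 0.02719       208.7       129.7       1.177
sharpen_more   192.8            52.15 0.04418       126.5       84.03       2.425
sharpen        141.1            69.42 0.06402       87.59        65.8       2.391
note: FIQ_T and IC rank the images differently: ...
```

The same chain is scriptable from the shell:

```sh
mamiq synthesize --out fixtures --seed 3 --blur 0.08
mamiq mtf --pattern fixtures/pattern.npy --layout fixtures/layout.yaml \
          --offset-du 32 --out mtf.tsv
mamiq nps --flat fixtures/flat.npy --out nps.tsv
mamiq report --mtf mtf.tsv --nps nps.tsv --cv 0.0119 --gain 2471 \
             --kerma 100 --out report.json
```

## Layout

| module | contents |
|---|---|
| `mamiq.image_model` | `ImageFrame`, ROIs, DICOM/PNG/npy I/O |
| `mamiq.synthetic_phantoms` | detector model, bar-pattern / flat-field generator |
| `mamiq.detector_response` | linear response fit (offset, gain, R², stderr) |
| `mamiq.sharpening_filters` | the three characterised 3×3 filters |
| `mamiq.resolution_metrics` | CTF measurement, Coltman MTF, SPS |
| `mamiq.noise_metrics` | CV, 2-D/radial NPS, NNPS |
| `mamiq.quality_indices` | NEQ, FIQ_T/FIQ_R, information capacity, reports |
| `mamiq.cli_reporting` | `mamiq` CLI, pipeline orchestration, comparisons |

See `docs/methods.md` for the measurement models, numerical choices and
known limitations.
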