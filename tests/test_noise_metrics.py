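import numpy as np
import pytest

from mamiq import (
    FrequencySeries,
    RegionOfInterest,
    Spectrum2D,
    coefficient_of_variation,
    normalize_nps,
    nps_2d,
    radial_profile,
)

from conftest import make_frame


def two_pixel_frame(sigma, mean):
    """Smallest frame whose sample std (n-1) and mean are exactly as asked."""
    d = sigma / np.sqrt(2.0)
    return make_frame(np.array([[mean - d, mean + d]]))


class TestCoefficientOfVariation:
    @pytest.mark.parametrize(
        "sigma, mean, printed_pct",
        [
            (0.913, 76.53, 1.193),
            (1.909, 160.91, 1.186),
            (2.887, 160.77, 1.796),
            (1.012, 160.58, 0.630),
        ],
    )
    def test_reproduces_printed_noise_table(self, sigma, mean, printed_pct):
        cv = coefficient_of_variation(two_pixel_frame(sigma, mean))
        assert cv == pytest.approx(sigma / mean, rel=1e-12)
        assert round(100.0 * cv, 3) == printed_pct

    def test_constant_region_has_zero_cv(self):
        assert coefficient_of_variation(make_frame(np.full((10, 10), 7.0))) == 0.0

    def test_hand_computed_two_values(self):
        cv = coefficient_of_variation(make_frame(np.array([[1.0, 3.0]])))
        assert cv == pytest.approx(np.sqrt(2.0) / 2.0)

    def test_non_positive_mean_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation(make_frame(np.array([[-1.0, 1.0]])))

    def test_roi_argument_restricts_the_region(self):
        px = np.zeros((10, 10))
        px[:5] = 4.0
        px[5:] = 2.0
        cv = coefficient_of_variation(make_frame(px), RegionOfInterest(0, 0, 5, 10))
        assert cv == 0.0


class TestNps2d:
    def test_constant_frame_gives_zero_spectrum(self):
        flat = make_frame(np.full((64, 64), 500.0))
        spec = nps_2d(flat, roi_size=16, overlap_fraction=0.5)
        np.testing.assert_allclose(spec.values, 0.0, atol=1e-18)

    def test_matches_hand_coded_double_loop_dft(self):
        rng = np.random.default_rng(0)
        px = rng.normal(100, 3, (4, 4))
        flat = make_frame(px)
        spec = nps_2d(flat, roi_size=4, overlap_fraction=0.0, min_rois=1)

        p = px - px.mean()
        n = 4
        dft = np.zeros((n, n), dtype=complex)
        for u in range(n):
            for v in range(n):
                acc = 0.0 + 0.0j
                for r in range(n):
                    for c in range(n):
                        acc += p[r, c] * np.exp(-2j * np.pi * (u * r + v * c) / n)
                dft[u, v] = acc
        expected = np.fft.fftshift(np.abs(dft) ** 2 * (0.1 * 0.1) / (n * n))
        np.testing.assert_allclose(spec.values, expected, atol=1e-12)

    def test_white_noise_level_and_parseval(self):
        rng = np.random.default_rng(42)
        sigma = 50.0
        flat = make_frame(100_000.0 + rng.normal(0.0, sigma, (512, 512)))
        spec = nps_2d(flat, roi_size=128, overlap_fraction=0.5)
        n = spec.n
        mask = np.ones((n, n), dtype=bool)
        mask[n // 2, n // 2] = False  # exclude DC
        level = spec.values[mask].mean()
        assert level == pytest.approx(sigma**2 * 0.1 * 0.1, rel=0.03)
        integral = spec.values[mask].sum() * spec.freq_step_per_mm**2
        assert integral == pytest.approx(sigma**2, rel=0.02)

    def test_invariant_under_constant_shift(self):
        rng = np.random.default_rng(1)
        px = rng.normal(1000, 5, (64, 64))
        a = nps_2d(make_frame(px), roi_size=32, overlap_fraction=0.5)
        b = nps_2d(make_frame(px + 123.0), roi_size=32, overlap_fraction=0.5)
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_too_few_rois_rejected_naming_minimum(self):
        flat = make_frame(np.ones((64, 64)))
        with pytest.raises(ValueError, match="4"):
            nps_2d(flat, roi_size=64, overlap_fraction=0.0)

    def test_planar_detrend_removes_a_gradient(self):
        y, x = np.mgrid[0:128, 0:128].astype(float)
        flat = make_frame(1000.0 + 3.0 * x + 2.0 * y)
        spec = nps_2d(flat, roi_size=32, overlap_fraction=0.0, detrend="planar")
        np.testing.assert_allclose(spec.values, 0.0, atol=1e-12)


class TestRadialProfile:
    def test_isotropic_constant_spectrum_stays_constant(self):
        spec = Spectrum2D(np.full((16, 16), 2.5), freq_step_per_mm=0.5, n_rois=1)
        prof = radial_profile(spec)
        np.testing.assert_allclose(prof.values, 2.5)
        assert prof.kind == "NPS"
        steps = np.diff(prof.frequencies_per_mm)
        np.testing.assert_allclose(steps, steps[0])  # constant interval

    def test_single_off_axis_bin_lands_in_the_predicted_bin(self):
        n, step = 16, 0.5
        vals = np.zeros((n, n))
        vals[n // 2 + 2, n // 2 + 1] = 1.0  # (fx, fy) = (0.5, 1.0)
        spec = Spectrum2D(vals, freq_step_per_mm=step, n_rois=1)
        n_bins = 8
        prof = radial_profile(spec, n_bins=n_bins)
        radius = np.hypot(1.0, 2.0) * step
        f_nyq = (n // 2) * step
        edges = np.linspace(0, f_nyq, n_bins + 1)
        target = np.digitize(radius, edges) - 1
        # predicted average: 1 / (number of non-DC bins sharing that annulus)
        fr = (np.arange(n) - n // 2) * step
        fx, fy = np.meshgrid(fr, fr)
        r = np.hypot(fx, fy)
        members = (r > 0) & (r <= f_nyq) & (np.digitize(r, edges) - 1 == target)
        assert prof.values[target] == pytest.approx(1.0 / members.sum())
        others = np.delete(prof.values, target)
        np.testing.assert_allclose(others, 0.0, atol=1e-15)

    def test_axis_exclusion_matches_masked_average_oracle(self):
        rng = np.random.default_rng(2)
        n, step = 16, 0.5
        vals = rng.uniform(1.0, 2.0, (n, n))
        vals[n // 2, :] += 50.0  # contaminate the fy = 0 axis
        spec = Spectrum2D(vals, freq_step_per_mm=step, n_rois=1)
        prof = radial_profile(spec, n_bins=8, include_axes=False)

        fr = (np.arange(n) - n // 2) * step
        fx, fy = np.meshgrid(fr, fr)
        r = np.hypot(fx, fy)
        edges = np.linspace(0, (n // 2) * step, 9)
        mask = (r > 0) & (fx != 0) & (fy != 0) & (r <= (n // 2) * step)
        for b in range(8):
            sel = mask & (np.clip(np.digitize(r, edges) - 1, 0, 7) == b)
            if sel.any():
                assert prof.values[b] == pytest.approx(vals[sel].mean())

    def test_too_few_bins_rejected(self):
        spec = Spectrum2D(np.ones((8, 8)), 0.5, 1)
        with pytest.raises(ValueError):
            radial_profile(spec, n_bins=1)


class TestNormalizeNps:
    def test_arithmetic_and_zero(self):
        nps = FrequencySeries(np.array([1.0]), np.array([4.0]), "NPS")
        assert normalize_nps(nps, gain_G=2.0, kerma_X_uGy=1.0).values[0] == pytest.approx(1.0)
        zero = FrequencySeries(np.array([1.0]), np.array([0.0]), "NPS")
        assert normalize_nps(zero, 2.0, 1.0).values[0] == 0.0

    def test_doubling_kerma_divides_by_four(self):
        nps = FrequencySeries(np.array([1.0, 2.0]), np.array([4.0, 8.0]), "NPS")
        a = normalize_nps(nps, 2.0, 1.0)
        b = normalize_nps(nps, 2.0, 2.0)
        np.testing.assert_allclose(a.values, 4.0 * b.values)

    def test_zero_kerma_rejected(self):
        nps = FrequencySeries(np.array([1.0]), np.array([4.0]), "NPS")
        with pytest.raises(ValueError):
            normalize_nps(nps, 2.0, 0.0)
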