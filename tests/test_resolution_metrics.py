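import math

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

from mamiq import (
    FrequencySeries,
    ctf_to_mtf,
    measure_bar_profiles,
    measure_ctf,
    signal_power_spectrum,
)

from conftest import GAIN, OFFSET, PITCH, make_frame


def series(freqs, values, kind="CTF"):
    return FrequencySeries(np.asarray(freqs, float), np.asarray(values, float), kind)


def oracle_ctf(frequency, sigma_mm, pitch_mm=PITCH, phase_px=0.25):
    """Brute-force 1-D oracle: dense square wave convolved with the same
    Gaussian; contrast read from continuous extrema at bar/space centres."""
    sub = 200  # samples per pixel
    period_px = 1.0 / (frequency * pitch_mm)
    n_px = int(math.ceil(12 * period_px)) + 40
    x = np.arange(n_px * sub) / sub
    u = np.mod((x - phase_px) / period_px, 1.0)
    profile = np.where(u < 0.5, 0.0, 1.0)  # bar (absorbing) first
    blurred = gaussian_filter1d(profile, sigma_mm / pitch_mm * sub, mode="nearest")
    centre = blurred[len(blurred) // 3 : 2 * len(blurred) // 3]
    i_max, i_min = centre.max(), centre.min()
    return (i_max - i_min) / (i_max + i_min)


class TestMeasureCtf:
    def test_unblurred_pattern_has_unit_contrast_everywhere(
        self, sharp_pattern, exact_response
    ):
        frame, truth = sharp_pattern
        ctf = measure_ctf(frame, truth, response=exact_response)
        assert len(ctf) == len(truth.group_frequencies_per_mm)
        np.testing.assert_allclose(ctf.values, 1.0, atol=1e-9)

    def test_blurred_contrast_matches_1d_oracle(self, blurred_pattern, exact_response):
        frame, truth, sigma = blurred_pattern
        ctf = measure_ctf(frame, truth, response=exact_response)
        for f, measured in zip(ctf.frequencies_per_mm, ctf.values):
            if f > 4.0:
                continue  # at/near Nyquist the sampled phase limits recovery
            assert measured == pytest.approx(oracle_ctf(f, sigma), rel=0.02), f

    def test_constant_frame_has_no_measurable_group(self, default_layout):
        layout, shape = default_layout
        flat = make_frame(np.full(shape, 100.0))
        assert measure_bar_profiles(flat, layout) == []
        with pytest.raises(ValueError):
            measure_ctf(flat, layout)

    def test_profile_measurement_fields(self, sharp_pattern):
        frame, truth = sharp_pattern
        for m in measure_bar_profiles(frame, truth):
            assert m.i_max > m.i_min
            assert m.n_peaks >= 4
            assert m.i_max == pytest.approx(truth.high_DU)
            assert m.i_min == pytest.approx(truth.low_DU)


class TestColtmanConversion:
    def test_zero_contrast_converts_to_zero(self):
        ctf = series([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        mtf = ctf_to_mtf(ctf, renormalize=False)
        np.testing.assert_allclose(mtf.values, 0.0)

    def test_full_series_value_for_unit_contrast(self):
        # C == 1 at f and at 3f, 5f, 7f
        ctf = series([1.0, 3.0, 5.0, 7.0], [1.0, 1.0, 1.0, 1.0])
        mtf = ctf_to_mtf(ctf, renormalize=False)
        expected = (math.pi / 4.0) * (1.0 + 1.0 / 3.0 - 1.0 / 5.0 + 1.0 / 7.0)
        assert mtf.values[0] == pytest.approx(expected)

    def test_single_term_when_harmonics_out_of_range(self):
        ctf = series([1.0], [1.0])
        mtf = ctf_to_mtf(ctf, renormalize=False)
        assert mtf.values[0] == pytest.approx(math.pi / 4.0)

    def test_one_harmonic_is_pi_over_4_times_ctf(self):
        rng = np.random.default_rng(0)
        vals = np.sort(rng.uniform(0.1, 1.0, 6))[::-1]
        ctf = series(np.arange(1, 7), vals)
        mtf = ctf_to_mtf(ctf, harmonics=1, renormalize=False)
        np.testing.assert_allclose(mtf.values, math.pi / 4.0 * vals)

    def test_sign_conventions_agree_at_this_truncation(self):
        ctf = series([0.5, 1.5, 2.5, 4.5], [0.9, 0.7, 0.4, 0.1])
        a = ctf_to_mtf(ctf, sign_convention="as_printed")
        b = ctf_to_mtf(ctf, sign_convention="coltman1954")
        np.testing.assert_array_equal(a.values, b.values)

    def test_renormalization_anchors_lowest_frequency_to_one(self, blurred_pattern, exact_response):
        frame, truth, _ = blurred_pattern
        mtf = ctf_to_mtf(measure_ctf(frame, truth, response=exact_response))
        assert mtf.values[0] == pytest.approx(1.0)

    def test_empty_ctf_rejected(self):
        with pytest.raises(ValueError):
            ctf_to_mtf(series([1.0], [0.5]), harmonics=0)


class TestEndToEndGaussian:
    def test_measured_mtf_tracks_analytic_gaussian(self, blurred_pattern, exact_response):
        """Bar pattern blurred by a Gaussian PSF: measured-then-converted
        MTF must match exp(-2 pi^2 sigma^2 f^2), renormalised at the first
        group, within 5% up to 0.8x Nyquist."""
        frame, truth, sigma = blurred_pattern
        mtf = ctf_to_mtf(measure_ctf(frame, truth, response=exact_response))
        f = mtf.frequencies_per_mm
        analytic = np.exp(-2.0 * np.pi**2 * sigma**2 * f**2)
        analytic /= analytic[0]
        keep = f <= 0.8 / (2.0 * PITCH)
        np.testing.assert_allclose(mtf.values[keep], analytic[keep], rtol=0.05)

    def test_mtf_non_increasing_under_low_pass_blur(self, blurred_pattern, exact_response):
        frame, truth, _ = blurred_pattern
        mtf = ctf_to_mtf(measure_ctf(frame, truth, response=exact_response))
        assert np.all(np.diff(mtf.values) <= 1e-9)


class TestSignalPowerSpectrum:
    def test_zero_mtf_gives_zero_sps(self):
        mtf = series([1.0, 2.0], [0.0, 0.0], kind="MTF")
        np.testing.assert_allclose(signal_power_spectrum(mtf, GAIN).values, 0.0)

    def test_arithmetic_example(self):
        mtf = series([1.0], [1.0], kind="MTF")
        sps = signal_power_spectrum(mtf, gain_G=2.0, k_const=1.07)
        assert sps.values[0] == pytest.approx(4.28)

    def test_doubling_gain_quadruples_sps(self):
        mtf = series([0.5, 1.0, 2.0], [1.0, 0.8, 0.3], kind="MTF")
        a = signal_power_spectrum(mtf, GAIN)
        b = signal_power_spectrum(mtf, 2 * GAIN)
        np.testing.assert_allclose(b.values, 4.0 * a.values)

    def test_negative_gain_rejected(self):
        with pytest.raises(ValueError):
            signal_power_spectrum(series([1.0], [1.0], kind="MTF"), -1.0)


class TestFrequencySeries:
    def test_table_round_trip(self, tmp_path):
        s = series([0.25, 0.5, 1.0], [1.0, 0.9, 0.7], kind="MTF")
        s.to_table(tmp_path / "mtf.tsv")
        back = FrequencySeries.from_table(tmp_path / "mtf.tsv")
        assert back.kind == "MTF"
        np.testing.assert_array_equal(back.frequencies_per_mm, s.frequencies_per_mm)
        np.testing.assert_array_equal(back.values, s.values)

    @pytest.mark.parametrize(
        "freqs, values, kind",
        [
            ([2.0, 1.0], [0.5, 0.5], "CTF"),  # not increasing
            ([1.0, 2.0], [0.5], "CTF"),  # length mismatch
            ([1.0], [1.2], "MTF"),  # above the Coltman overshoot allowance
            ([1.0], [-0.5], "NPS"),  # negative power
            ([1.0], [0.5], "XXX"),  # unknown kind
        ],
    )
    def test_validation_rejects_malformed_series(self, freqs, values, kind):
        with pytest.raises(ValueError):
            series(freqs, values, kind)

    def test_restrict_is_a_closed_interval(self):
        s = series([1.0, 2.0, 3.0, 4.0], [0.9, 0.8, 0.7, 0.6], kind="MTF")
        band = s.restrict(2.0, 4.0)
        np.testing.assert_array_equal(band.frequencies_per_mm, [2.0, 3.0, 4.0])
        with pytest.raises(ValueError):
            s.restrict(5.0, 6.0)
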