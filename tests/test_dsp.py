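"""Filters, resampling, windowed energy, smoothing, spectra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import wingbeat as wb
from wingbeat.dsp import SPECTRUM_EPS


def sos_gain_db(spec: wb.FilterSpec, freq_hz: float) -> float:
    from scipy.signal import sosfreqz

    _, h = sosfreqz(spec.sos, worN=[freq_hz], fs=spec.rate_hz)
    return 20 * np.log10(np.abs(h[0]))


class TestButterworthDesign:
    @pytest.mark.parametrize("kind,order,cutoff", [
        ("low_pass", 4, 1500.0), ("high_pass", 30, 180.0), ("high_pass", 4, 50.0),
    ])
    def test_minus_3db_at_cutoff(self, kind, order, cutoff):
        spec = wb.design_butterworth(kind, order, cutoff, 16000.0)
        assert sos_gain_db(spec, cutoff) == pytest.approx(-3.0103, abs=0.1)

    def test_detection_highpass_kills_mains_band(self):
        """The order-30 high-pass at 180 Hz leaves nothing at 50 Hz: the
        analog prototype magnitude 1/sqrt(1+(180/50)^60) is ~ -334 dB, so
        -100 dB is a conservative bound."""
        spec = wb.design_butterworth("high_pass", 30, 180.0, 16000.0)
        assert sos_gain_db(spec, 50.0) < -100.0

    def test_order30_cascade_is_stable(self):
        spec = wb.design_butterworth("high_pass", 30, 180.0, 16000.0)
        assert np.all(spec.pole_moduli() < 1.0)

    @pytest.mark.parametrize("kind,order,cutoff,rate", [
        ("low_pass", 4, 9000.0, 16000.0),   # cutoff >= Nyquist
        ("low_pass", 0, 100.0, 16000.0),    # non-positive order
        ("band_pass", 4, 100.0, 16000.0),   # unknown kind
    ])
    def test_invalid_designs_rejected(self, kind, order, cutoff, rate):
        with pytest.raises(ValueError):
            wb.design_butterworth(kind, order, cutoff, rate)


class TestApplyFilter:
    def test_zero_in_zero_out_and_linearity(self):
        spec = wb.design_butterworth("high_pass", 30, 180.0, 16000.0)
        assert np.all(wb.apply_filter(spec, np.zeros(5000)) == 0.0)
        rng = np.random.default_rng(3)
        x = rng.normal(size=5000)
        np.testing.assert_allclose(
            wb.apply_filter(spec, 3.5 * x), 3.5 * wb.apply_filter(spec, x),
            rtol=1e-7, atol=1e-9)

    def test_passband_sine_passes_at_unit_gain(self):
        spec = wb.design_butterworth("high_pass", 30, 180.0, 16000.0)
        t = np.arange(32000) / 16000.0
        y = wb.apply_filter(spec, np.sin(2 * np.pi * 1000.0 * t))
        steady = y[16000:]
        amplitude = np.sqrt(2 * np.mean(steady**2))
        assert amplitude == pytest.approx(1.0, rel=0.01)

    def test_time_invariance_in_the_interior(self):
        spec = wb.design_butterworth("low_pass", 4, 1500.0, 16000.0)
        rng = np.random.default_rng(11)
        x = np.zeros(8000)
        x[2000:4000] = rng.normal(size=2000)
        shift = 500
        y = wb.apply_filter(spec, x)
        y_shifted = wb.apply_filter(spec, np.roll(x, shift))
        np.testing.assert_allclose(y_shifted[2500 + shift : 6000],
                                   y[2500:6000 - shift], atol=1e-9)

    def test_rate_mismatch_rejected(self):
        spec = wb.design_butterworth("low_pass", 4, 1500.0, 16000.0)
        with pytest.raises(ValueError, match="designed for"):
            wb.apply_filter(spec, np.zeros(100), rate_hz=48000.0)

    def test_output_length_equals_input_length(self):
        spec = wb.design_butterworth("low_pass", 4, 1500.0, 16000.0)
        assert wb.apply_filter(spec, np.zeros(12345)).shape == (12345,)


class TestResample:
    def test_dc_preserved(self):
        y = wb.resample_to_16k(np.full(48000, 0.3), 48000)
        assert len(y) == 16000
        np.testing.assert_allclose(y[1000:-1000], 0.3, atol=1e-6)

    def test_low_frequency_sine_amplitude_preserved(self):
        t = np.arange(96000) / 48000.0
        y = wb.resample_to_16k(np.sin(2 * np.pi * 100.0 * t), 48000)
        # oracle: least-squares fit of a 100 Hz sinusoid to the interior
        ty = np.arange(len(y))[4000:-4000] / 16000.0
        basis = np.stack([np.sin(2 * np.pi * 100 * ty), np.cos(2 * np.pi * 100 * ty)], 1)
        coeffs, *_ = np.linalg.lstsq(basis, y[4000:-4000], rcond=None)
        assert np.hypot(*coeffs) == pytest.approx(1.0, rel=0.01)

    def test_antialiasing_brick_wall(self):
        """Content just below the new Nyquist survives; content just above
        is suppressed by at least 40 dB (it would alias to 7.9 kHz)."""
        t = np.arange(96000) / 48000.0
        for f, expect_pass in ((7900.0, True), (8100.0, False)):
            y = wb.resample_to_16k(np.sin(2 * np.pi * f * t), 48000)
            interior = y[4000:-4000]
            level_db = 20 * np.log10(np.sqrt(2 * np.mean(interior**2)) + 1e-15)
            if expect_pass:
                assert level_db > -3.0
            else:
                assert level_db < -40.0

    def test_band_limited_energy_preserved(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=480000)
        lp = wb.design_butterworth("low_pass", 8, 6500.0, 48000.0)
        x = wb.apply_filter(lp, x)
        y = wb.resample_to_16k(x, 48000)
        power_in = np.mean(x[48000:-48000] ** 2)
        power_out = np.mean(y[16000:-16000] ** 2)
        assert power_out == pytest.approx(power_in, rel=0.02)

    def test_multichannel_and_length_contract(self):
        x = np.zeros((4, 48001))
        y = wb.resample_to_16k(x, 48000)
        assert y.shape == (4, round(48001 * 16000 / 48000))

    def test_irrational_ratio_rejected(self):
        with pytest.raises(ValueError, match="not rational"):
            wb.resample(np.zeros(1000), 16000 * np.pi, 16000.0)


class TestWindowedEnergy:
    def test_constant_signal_closed_form(self):
        profile = wb.windowed_energy(np.full(3279, 0.25), 3279, 1024)
        assert profile.n_windows == 1
        assert profile.energies[0] == pytest.approx(3279 * 0.25**2)

    def test_window_counting(self):
        profile = wb.windowed_energy(np.zeros(3279 + 1024), 3279, 1024)
        assert profile.n_windows == 2
        # one sample short of a third window
        assert wb.windowed_energy(np.zeros(3279 + 2 * 1024 - 1), 3279, 1024).n_windows == 2

    def test_matches_brute_force_on_random_signal(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=50000)
        profile = wb.windowed_energy(x, 3279, 1024)
        brute = []
        k = 0
        while k * 1024 + 3279 <= len(x):
            total = 0.0
            for i in range(k * 1024, k * 1024 + 3279):
                total += x[i] ** 2
            brute.append(total)
            k += 1
        np.testing.assert_allclose(profile.energies, brute, rtol=1e-12)

    @given(hnp.arrays(np.float64, st.integers(30, 400),
                      elements=st.floats(-1, 1, allow_nan=False)),
           st.integers(5, 30), st.integers(1, 20))
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_property_equals_vectorized_oracle(self, x, window_len, hop):
        if len(x) < window_len:
            return
        profile = wb.windowed_energy(x, window_len, hop)
        expected = [np.sum(x[k * hop : k * hop + window_len] ** 2)
                    for k in range(profile.n_windows)]
        np.testing.assert_allclose(profile.energies, expected, rtol=1e-12, atol=1e-300)
        assert np.all(profile.energies >= 0)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            wb.windowed_energy(np.zeros(3278), 3279, 1024)


class TestMovingAverage:
    def test_constant_is_fixed_point_and_window1_is_identity(self):
        x = np.full(200, 4.2)
        np.testing.assert_allclose(wb.moving_average(x, 51), x)
        y = np.arange(30, dtype=float)
        np.testing.assert_array_equal(wb.moving_average(y, 1), y)

    def test_impulse_spreads_into_plateau(self):
        x = np.zeros(301)
        x[150] = 1.0
        y = wb.moving_average(x, 51)
        np.testing.assert_allclose(y[125:176], 1 / 51)
        assert np.all(y[:125] == 0) and np.all(y[176:] == 0)

    def test_matches_direct_convolution_in_interior(self):
        rng = np.random.default_rng(23)
        x = rng.normal(size=500)
        y = wb.moving_average(x, 51)
        full = np.convolve(x, np.ones(51) / 51, mode="same")
        np.testing.assert_allclose(y[25:-25], full[25:-25], rtol=1e-10, atol=1e-12)

    def test_mean_preserved_on_stationary_sequence(self):
        rng = np.random.default_rng(29)
        x = rng.normal(loc=1.5, size=20000)
        assert wb.moving_average(x, 51).mean() == pytest.approx(x.mean(), abs=1e-3)

    @pytest.mark.parametrize("window", [0, -3, 2, 50])
    def test_even_or_nonpositive_window_rejected(self, window):
        with pytest.raises(ValueError):
            wb.moving_average(np.zeros(10), window)


class TestMagnitudeSpectrum:
    def test_bin_centered_sine_peaks_at_its_bin(self):
        rate, n = 16000, 16000
        t = np.arange(n) / rate
        freqs, db = wb.magnitude_spectrum_db(np.sin(2 * np.pi * 440.0 * t), rate)
        assert freqs[np.argmax(db)] == pytest.approx(440.0)
        assert freqs[1] - freqs[0] == pytest.approx(rate / n)

    def test_parseval(self):
        rng = np.random.default_rng(31)
        x = rng.normal(size=4096)
        freqs, db = wb.magnitude_spectrum_db(x, 16000.0)
        mags = 10 ** (db / 20) - SPECTRUM_EPS
        # one-sided Parseval: interior bins count twice
        weights = np.full(len(mags), 2.0)
        weights[0] = 1.0
        weights[-1] = 1.0  # even length: last bin is Nyquist
        assert np.sum(weights * mags**2) / len(x) == pytest.approx(
            np.sum(x**2), rel=1e-6)

    def test_zero_signal_sits_at_floor(self):
        _, db = wb.magnitude_spectrum_db(np.zeros(1024), 16000.0)
        np.testing.assert_allclose(db, 20 * np.log10(SPECTRUM_EPS))

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            wb.magnitude_spectrum_db(np.array([]), 16000.0)
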