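"""ECG pipeline: Grubbs cleaning, filtering, R-peak detection, HRV spectra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

import drowsinet as dn
from drowsinet.containers import ECGRecord, RRSeries
from drowsinet.ecg import (HF_BAND, LF_BAND, grubbs_critical_value, hrv_psd,
                           lf_hf_ratio, remove_outliers_grubbs,
                           resample_tachogram, rr_outlier_filter,
                           rr_series_from_beats)
from drowsinet.synth import synthesize_ecg_with_snr


class TestGrubbs:
    def test_single_large_spike_flagged(self, rng):
        x = rng.normal(size=500)
        x[123] = 10.0 * x.std() + x.mean()
        # direct Grubbs statistic exceeds the critical value for this window
        g = np.abs(x - x.mean()).max() / x.std(ddof=1)
        assert g > grubbs_critical_value(x.size, 0.05)
        cleaned, removed = remove_outliers_grubbs(x, alpha=0.05, window=500)
        assert 123 in removed
        assert abs(cleaned[123]) < 3.0

    def test_constant_signal_untouched(self):
        x = np.full(100, 2.5)
        cleaned, removed = remove_outliers_grubbs(x)
        assert removed.size == 0
        np.testing.assert_array_equal(cleaned, x)

    def test_vanishing_alpha_removes_nothing(self, rng):
        x = rng.normal(size=300)
        x[10] = 8.0
        _, removed = remove_outliers_grubbs(x, alpha=1e-12, window=300)
        assert removed.size == 0

    def test_idempotent_on_clean_signal(self, rng):
        x = rng.normal(size=400)
        once, removed1 = remove_outliers_grubbs(x, window=400)
        twice, removed2 = remove_outliers_grubbs(once, window=400)
        np.testing.assert_array_equal(once, twice)
        assert removed2.size == 0


class TestBandpass:
    def test_zero_in_zero_out(self):
        rec = ECGRecord(np.zeros(5000), 1000.0)
        out = dn.bandpass_ecg(rec)
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    @pytest.mark.parametrize("freq, passband", [(10.0, True), (0.3, False)])
    def test_tone_response_matches_analytic_butterworth(self, freq, passband):
        fs = 1000.0
        t = np.arange(0, 30.0, 1 / fs)
        rec = ECGRecord(np.sin(2 * np.pi * freq * t), fs)
        out = dn.bandpass_ecg(rec)
        core = slice(int(5 * fs), int(25 * fs))  # avoid filter edge transients
        ratio = np.sqrt(np.mean(out.samples[core] ** 2) / 0.5)
        sos = sps.butter(2, [2.0, 40.0], btype="bandpass", fs=fs, output="sos")
        _, h = sps.sosfreqz(sos, worN=[freq], fs=fs)
        analytic = np.abs(h[0]) ** 2  # forward-backward squares the response
        assert ratio == pytest.approx(analytic, abs=0.01)
        if passband:
            assert ratio > 0.98
        else:
            assert ratio < 0.05

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="twice the upper band edge"):
            dn.bandpass_ecg(ECGRecord(np.zeros(100), 70.0))


class TestPanTompkins:
    def test_clean_60bpm_all_beats_within_10ms(self):
        prof = dn.SubjectProfile(
            "s", ((60.0, 1),),
            mean_rr_ms={l: 1000.0 for l in range(1, 6)},
            lf_amp_ms={l: 0.0 for l in range(1, 6)},
            hf_amp_ms={l: 0.0 for l in range(1, 6)},
            noise_sd_ms=0.0)
        rr, _ = dn.generate_rr_series(prof, 60.0)
        ecg, truth = dn.synthesize_ecg(rr)
        beats = dn.detect_r_peaks_pan_tompkins(dn.bandpass_ecg(ecg))
        assert beats.size == truth.r_peak_times_s.size
        err = np.abs(beats[:, None] - truth.r_peak_times_s[None, :]).min(axis=1)
        assert err.max() <= 0.010

    def test_flat_record_yields_no_beats(self):
        with pytest.warns(UserWarning):
            beats = dn.detect_r_peaks_pan_tompkins(ECGRecord(np.zeros(10_000), 1000.0))
        assert beats.size == 0

    def test_noisy_modulated_ecg_sensitivity_and_ppv(self, steady_profile):
        """LF+HF-modulated RR at 20 dB SNR: near-perfect detection at 50 ms."""
        prof = dn.SubjectProfile("s", ((120.0, 1),), seed=5)
        rr, _ = dn.generate_rr_series(prof, 120.0)
        ecg, truth = synthesize_ecg_with_snr(rr, snr_db=20.0, seed=6)
        cleaned, _ = remove_outliers_grubbs(ecg.samples)
        beats = dn.detect_r_peaks_pan_tompkins(
            dn.bandpass_ecg(ECGRecord(cleaned, ecg.fs_hz, ecg.start_time_s)))
        d = np.abs(beats[:, None] - truth.r_peak_times_s[None, :])
        sens = (d.min(axis=0) <= 0.05).mean()
        ppv = (d.min(axis=1) <= 0.05).mean()
        assert sens >= 0.995
        assert ppv >= 0.995


def brute_force_rr_filter(intervals, threshold=0.30):
    """Independent re-implementation of the 30%-of-last-4 ectopic rule."""
    flagged = [False] * len(intervals)
    clean = [0, 1, 2, 3]
    for i in range(4, len(intervals)):
        ref = [intervals[j] for j in clean[-4:]]
        m = sum(ref) / 4.0
        if abs(intervals[i] - m) / m > threshold:
            flagged[i] = True
        else:
            clean.append(i)
    return flagged


class TestRROutlierFilter:
    def make_series(self, intervals):
        times = np.cumsum(np.asarray(intervals)) / 1000.0
        return RRSeries(intervals_ms=intervals, beat_times_s=times)

    def test_candidate_above_threshold_flagged(self):
        rr = self.make_series([800.0, 810.0, 790.0, 800.0, 1100.0])
        out = rr_outlier_filter(rr)
        # |1100 - 800| / 800 = 0.375 > 0.30
        assert list(out.outlier_mask) == [False] * 4 + [True]

    def test_candidate_at_quarter_kept(self):
        rr = self.make_series([800.0, 810.0, 790.0, 800.0, 1000.0])
        out = rr_outlier_filter(rr)
        assert not out.outlier_mask.any()

    def test_constant_series_untouched(self):
        rr = self.make_series([900.0] * 50)
        assert not rr_outlier_filter(rr).outlier_mask.any()

    def test_short_series_is_identity_with_warning(self):
        rr = self.make_series([900.0] * 4)
        with pytest.warns(UserWarning):
            out = rr_outlier_filter(rr)
        np.testing.assert_array_equal(out.intervals_ms, rr.intervals_ms)

    def test_agrees_with_brute_force_on_random_series(self, rng):
        """Exhaustive check of the scanning rule against an independent oracle."""
        for _ in range(1000):
            n = int(rng.integers(5, 40))
            intervals = rng.uniform(400.0, 1400.0, size=n)
            rr = self.make_series(intervals)
            got = list(rr_outlier_filter(rr).outlier_mask)
            assert got == brute_force_rr_filter(list(intervals))


class TestResampleTachogram:
    def test_constant_series_resamples_constant(self):
        t = np.arange(1.0, 61.0)
        rr = RRSeries(np.full(60, 1000.0), t)
        grid, hrv = resample_tachogram(rr, 4.0)
        np.testing.assert_allclose(hrv, 1000.0, atol=1e-9)

    def test_sinusoidal_modulation_recovered_within_1ms(self):
        t = np.arange(0.9, 120.0, 0.9)
        vals = 900.0 + 40.0 * np.sin(2 * np.pi * 0.1 * t)
        rr = RRSeries(vals, t)
        grid, hrv = resample_tachogram(rr, 4.0)
        expected = 900.0 + 40.0 * np.sin(2 * np.pi * 0.1 * grid)
        assert np.abs(hrv - expected).max() < 1.0

    def test_sample_count_formula(self):
        t = np.arange(0.0, 120.5, 0.5)
        rr = RRSeries(np.full(t.size - 1, 500.0), t[1:])
        grid, hrv = resample_tachogram(rr, 4.0)
        assert grid.size == int(np.floor((t[-1] - t[1]) * 4.0)) + 1

    def test_masked_beats_excluded_from_support(self):
        t = np.arange(1.0, 61.0)
        vals = np.full(60, 1000.0)
        vals[30] = 2000.0
        mask = np.zeros(60, bool)
        mask[30] = True
        rr = RRSeries(vals, t, mask)
        _, hrv = resample_tachogram(rr, 4.0)
        assert np.abs(hrv - 1000.0).max() < 1e-6


class TestHrvPsd:
    def test_constant_input_zero_spectrum(self):
        psd = hrv_psd(np.full(480, 800.0), 4.0)
        assert psd.power.max() == 0.0
        assert psd.total_power_ms2 == 0.0

    def test_pure_0p10_tone_argmax_within_0p01(self):
        t = np.arange(480) / 4.0
        psd = hrv_psd(900 + 50 * np.sin(2 * np.pi * 0.10 * t), 4.0)
        assert abs(psd.freq_hz[np.argmax(psd.power)] - 0.10) <= 0.01

    def test_equal_tones_give_unit_lf_hf_ratio(self):
        t = np.arange(1920) / 4.0
        x = 900 + 30 * np.sin(2 * np.pi * 0.10 * t) + 30 * np.sin(2 * np.pi * 0.25 * t)
        ratio = lf_hf_ratio(hrv_psd(x, 4.0))
        assert 0.8 <= ratio <= 1.2

    def test_parseval_total_power_matches_time_domain(self):
        rng = np.random.default_rng(0)
        x = 900 + rng.normal(0, 30, size=960)
        psd = hrv_psd(x, 4.0)
        xd = x - x.mean()
        w = np.hanning(xd.size)
        var_windowed = np.sum((xd * w) ** 2) / np.sum(w**2)
        assert psd.total_power_ms2 == pytest.approx(var_windowed, rel=0.05)

    def test_fixed_grid_length(self):
        psd = hrv_psd(np.random.default_rng(1).normal(900, 20, 480), 4.0)
        assert psd.freq_hz.size == 128
        assert psd.freq_hz[0] == pytest.approx(0.04)
        assert psd.freq_hz[-1] == pytest.approx(0.40)


class TestLfHfRatio:
    def test_pure_lf_tone_ratio_large(self):
        t = np.arange(1920) / 4.0
        ratio = lf_hf_ratio(hrv_psd(900 + 50 * np.sin(2 * np.pi * 0.10 * t), 4.0))
        assert ratio >= 100.0

    def test_pure_hf_tone_ratio_tiny(self):
        t = np.arange(1920) / 4.0
        ratio = lf_hf_ratio(hrv_psd(900 + 50 * np.sin(2 * np.pi * 0.25 * t), 4.0))
        assert ratio <= 0.01

    def test_zero_hf_power_signalled(self):
        from drowsinet.containers import PSDSpectrum
        freq = np.linspace(0.04, 0.4, 128)
        power = np.where(freq < 0.12, 1.0, 0.0)
        with pytest.raises(ZeroDivisionError):
            lf_hf_ratio(PSDSpectrum(freq_hz=freq, power=power))


@settings(max_examples=30, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_pipeline_deterministic_for_fixed_input(seed):
    """The full ECG chain is a pure function of its input record."""
    rng = np.random.default_rng(seed)
    t = np.cumsum(rng.uniform(0.7, 1.1, size=40))
    rr = rr_series_from_beats(t)
    a = rr_outlier_filter(rr)
    b = rr_outlier_filter(rr)
    np.testing.assert_array_equal(a.outlier_mask, b.outlier_mask)
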