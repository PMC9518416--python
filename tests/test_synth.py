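"""Synthetic cohort generator: analytic ground truth and determinism."""

import numpy as np
import pytest
from scipy.signal import periodogram

import drowsinet as dn
from drowsinet.ecg import resample_tachogram
from drowsinet.synth import (ArtifactSpec, SubjectProfile, ThermalGeometry,
                             synthesize_ecg, template_span_s)


def make_profile(**kw):
    defaults = dict(subject_id="s", level_schedule=((300.0, 1),),
                    noise_sd_ms=0.0, seed=0)
    defaults.update(kw)
    return SubjectProfile(**defaults)


class TestGenerateRRSeries:
    def test_constant_case_yields_identical_intervals(self):
        prof = make_profile(
            lf_amp_ms={l: 0.0 for l in range(1, 6)},
            hf_amp_ms={l: 0.0 for l in range(1, 6)},
            mean_rr_ms={l: 1000.0 for l in range(1, 6)},
        )
        rr, truth = dn.generate_rr_series(prof, 60.0)
        assert len(rr) == 60
        np.testing.assert_allclose(rr.intervals_ms, 1000.0)
        np.testing.assert_allclose(truth.r_peak_times_s, np.arange(61.0))

    def test_lf_only_modulation_peaks_in_lf_band(self):
        prof = make_profile(
            lf_amp_ms={l: 50.0 for l in range(1, 6)},
            hf_amp_ms={l: 0.0 for l in range(1, 6)},
        )
        rr, _ = dn.generate_rr_series(prof, 300.0)
        grid, hrv = resample_tachogram(rr, 4.0)
        f, pxx = periodogram(hrv - hrv.mean(), fs=4.0)
        fmax = f[np.argmax(pxx)]
        assert 0.04 <= fmax <= 0.15

    def test_same_seed_bit_identical(self):
        prof = make_profile(noise_sd_ms=15.0, seed=42)
        rr1, _ = dn.generate_rr_series(prof, 200.0)
        rr2, _ = dn.generate_rr_series(prof, 200.0)
        np.testing.assert_array_equal(rr1.intervals_ms, rr2.intervals_ms)
        np.testing.assert_array_equal(rr1.beat_times_s, rr2.beat_times_s)

    def test_nonphysiological_mean_rr_rejected(self):
        with pytest.raises(ValueError, match="300-1500"):
            make_profile(mean_rr_ms={l: 200.0 for l in range(1, 6)})

    def test_lf_hf_ratio_must_decrease_with_level(self):
        with pytest.raises(ValueError, match="strictly decrease"):
            make_profile(lf_amp_ms={l: 10.0 for l in range(1, 6)},
                         hf_amp_ms={l: 10.0 for l in range(1, 6)})

    def test_generated_lf_hf_ratio_monotone_across_levels(self):
        """Independent periodogram estimate of LF/HF decreases from level 1 to 5."""
        ratios = []
        for level in range(1, 6):
            prof = make_profile(level_schedule=((300.0, level),),
                                noise_sd_ms=5.0, seed=7)
            rr, _ = dn.generate_rr_series(prof, 300.0)
            grid, hrv = resample_tachogram(rr, 4.0)
            f, pxx = periodogram(hrv - hrv.mean(), fs=4.0)
            lf = np.trapezoid(pxx[(f >= 0.04) & (f < 0.15)],
                              f[(f >= 0.04) & (f < 0.15)])
            hf = np.trapezoid(pxx[(f >= 0.15) & (f <= 0.4)],
                              f[(f >= 0.15) & (f <= 0.4)])
            ratios.append(lf / hf)
        assert all(a > b for a, b in zip(ratios, ratios[1:]))


class TestSynthesizeECG:
    def test_noise_free_60bpm_template_maxima_at_ground_truth(self):
        prof = make_profile(
            lf_amp_ms={l: 0.0 for l in range(1, 6)},
            hf_amp_ms={l: 0.0 for l in range(1, 6)},
            mean_rr_ms={l: 1000.0 for l in range(1, 6)},
        )
        rr, _ = dn.generate_rr_series(prof, 10.0)
        ecg, truth = dn.synthesize_ecg(rr)
        assert truth.r_peak_times_s.size == 11  # beats at 0..10 s
        # argmax search around each ground-truth time finds the R peak there
        for bt in truth.r_peak_times_s:
            i0 = int(round((bt - 0.3 - ecg.start_time_s) * ecg.fs_hz))
            i1 = int(round((bt + 0.3 - ecg.start_time_s) * ecg.fs_hz))
            local_max = i0 + np.argmax(ecg.samples[i0:i1])
            t_max = ecg.start_time_s + local_max / ecg.fs_hz
            assert abs(t_max - bt) <= 1.0 / ecg.fs_hz

    def test_zero_amplitude_template_gives_flat_record(self, steady_profile):
        rr, _ = dn.generate_rr_series(steady_profile, 10.0)
        ecg, _ = dn.synthesize_ecg(rr, amplitude_mv=0.0)
        np.testing.assert_array_equal(ecg.samples, 0.0)

    def test_injected_spike_count_matches_spec(self, steady_profile):
        rr, _ = dn.generate_rr_series(steady_profile, 10.0)
        spec = ArtifactSpec(n_outlier_spikes=7, spike_mv=30.0, seed=3)
        ecg, _ = dn.synthesize_ecg(rr, artifact_spec=spec)
        assert int(np.sum(np.abs(ecg.samples) > 15.0)) == 7

    def test_template_wider_than_min_rr_rejected(self):
        rr = dn.RRSeries(intervals_ms=[300.0, 300.0],
                         beat_times_s=[0.3, 0.6])
        wide = ((0.0, 1.0, 0.2),)  # 1.2 s span > 300 ms
        assert template_span_s(wide) > 0.3
        with pytest.raises(ValueError, match="wider than"):
            synthesize_ecg(rr, template=wide)

    def test_low_sampling_rate_rejected(self, steady_profile):
        rr, _ = dn.generate_rr_series(steady_profile, 10.0)
        with pytest.raises(ValueError, match="250"):
            dn.synthesize_ecg(rr, fs_hz=100.0)


class TestSynthesizeThermal:
    def test_patch_mean_is_exact_sinusoid_at_configured_rate(self):
        prof = make_profile(level_schedule=((120.0, 3),))
        geom = ThermalGeometry(pixel_noise_sd=0.0)
        seq, truth = dn.synthesize_thermal_sequence(prof, 120.0, geometry=geom)
        t = np.arange(seq.n_frames) / seq.frame_rate_hz
        rate = prof.resp_rate_hz[3]
        patch = seq.frames[:, 20:28, 26:38].mean(axis=(1, 2))
        # least-squares fit of sin/cos at the configured rate explains the
        # oscillation essentially perfectly
        design = np.column_stack([np.sin(2 * np.pi * rate * t),
                                  np.cos(2 * np.pi * rate * t),
                                  np.ones_like(t)])
        coef, *_ = np.linalg.lstsq(design, patch, rcond=None)
        resid = patch - design @ coef
        assert np.abs(resid).max() < 1e-3
        assert np.hypot(coef[0], coef[1]) == pytest.approx(
            geom.oscillation_amp, rel=1e-3)

    def test_zero_oscillation_amplitude_gives_constant_stack(self):
        prof = make_profile()
        geom = ThermalGeometry(oscillation_amp=0.0, pixel_noise_sd=0.0)
        seq, _ = dn.synthesize_thermal_sequence(prof, 30.0, geometry=geom)
        assert np.ptp(seq.frames, axis=0).max() == 0.0

    def test_linear_drift_displaces_ground_truth_center(self):
        prof = make_profile()
        geom = ThermalGeometry(frame_shape=(48, 128), start_center=(24.0, 12.0),
                               drift="linear", drift_px_per_frame=(0.0, 1.0))
        seq, truth = dn.synthesize_thermal_sequence(
            prof, 51 / 7.5, geometry=geom)
        c = truth.region_center_px_t
        np.testing.assert_allclose(c[50] - c[0], [0.0, 50.0])

    def test_patch_leaving_frame_rejected(self):
        prof = make_profile()
        geom = ThermalGeometry(drift="linear", drift_px_per_frame=(0.0, 2.0))
        with pytest.raises(ValueError, match="leaves the frame"):
            dn.synthesize_thermal_sequence(prof, 60.0, geometry=geom)


class TestGenerateCohort:
    def test_on_disk_layout_counts(self, tmp_path):
        manifest = dn.generate_cohort(2, 600.0, seed=1, out_dir=tmp_path,
                                      levels=(1, 3))
        assert len(manifest["subjects"]) == 2
        for entry in manifest["subjects"]:
            labels = np.loadtxt(entry["labels"], delimiter=",", skiprows=1)
            assert labels.shape == (10, 2)  # one row per minute
            assert (tmp_path / entry["subject_id"] / "ecg.csv").exists()
            assert (tmp_path / entry["subject_id"] / "thermal.tif").exists()

    def test_fixed_seed_identical_cohort(self):
        a = dn.generate_cohort(2, 150.0, seed=9, levels=(2,))
        b = dn.generate_cohort(2, 150.0, seed=9, levels=(2,))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.ecg.samples, y.ecg.samples)
            np.testing.assert_array_equal(x.thermal.frames, y.thermal.frames)
            np.testing.assert_array_equal(x.labels, y.labels)

    def test_full_level_schedule_covers_all_scores(self):
        subjects = dn.generate_cohort(1, 300.0, seed=0, levels=(1, 2, 3, 4, 5))
        scores = set(subjects[0].labels[:, 1])
        assert scores == {1.0, 2.0, 3.0, 4.0, 5.0}

    def test_too_short_session_rejected(self):
        with pytest.raises(ValueError, match="2-minute epoch"):
            dn.generate_cohort(1, 60.0, seed=0)
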