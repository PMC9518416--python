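"""Synthetic cohort generator: ECG, thermal breathing video and drowsiness labels.

The study data this package targets (simulator driving with ECG + thermal
imaging, observer-rated drowsiness) are private, so this module generates
subjects with the physiological structure the classifiers assume:

* beat-to-beat (RR) intervals modulated in the LF (centred 0.10 Hz) and HF
  (centred 0.25 Hz) heart-rate-variability bands, with an LF/HF power ratio
  that decreases monotonically with the drowsiness level;
* a "nostril" patch in a thermal frame sequence whose mean intensity
  oscillates at a respiration rate that decreases with the drowsiness level;
* one observer drowsiness score (ORD, 1 wakeful ... 5 extremely drowsy) per
  1-minute driving segment.

Every generated quantity has an analytically known ground truth
(:class:`GroundTruth`), which the pipeline tests use as their oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .containers import ECGRecord, RRSeries, ThermalSequence

__all__ = [
    "SubjectProfile",
    "GroundTruth",
    "ArtifactSpec",
    "ThermalGeometry",
    "generate_rr_series",
    "synthesize_ecg",
    "synthesize_thermal_sequence",
    "simulate_subject",
    "cohort_profiles",
    "generate_cohort",
    "LEVEL_MEAN_RR_MS",
    "LEVEL_LF_AMP_MS",
    "LEVEL_HF_AMP_MS",
    "LEVEL_RESP_RATE_HZ",
]

# Modulation band centres: mid-band of the canonical LF (0.04-0.15 Hz) and
# HF (0.15-0.4 Hz) HRV definitions, so band assignment is unambiguous.
LF_CENTER_HZ = 0.10
HF_CENTER_HZ = 0.25

# Per-ORD-level defaults. The direction of the effects (LF/HF ratio down,
# respiration rate down, mean RR up as drowsiness deepens) is physiological;
# the magnitudes are free generator parameters chosen to give clearly
# separable classes (see docs/methods.md).
LEVEL_MEAN_RR_MS = {1: 850.0, 2: 900.0, 3: 950.0, 4: 1000.0, 5: 1050.0}
LEVEL_LF_AMP_MS = {1: 40.0, 2: 30.0, 3: 20.0, 4: 12.0, 5: 6.0}
LEVEL_HF_AMP_MS = {1: 10.0, 2: 15.0, 3: 22.0, 4: 30.0, 5: 40.0}
LEVEL_RESP_RATE_HZ = {1: 0.30, 2: 0.26, 3: 0.22, 4: 0.18, 5: 0.14}


@dataclass
class SubjectProfile:
    """Physiological parameters of one synthetic subject.

    ``level_schedule`` is a sequence of ``(duration_s, ord_level)`` pairs
    covering the session in order.  Per-level parameter maps default to the
    module-level tables.
    """

    subject_id: str
    level_schedule: tuple  # ((duration_s, level), ...)
    mean_rr_ms: dict = field(default_factory=lambda: dict(LEVEL_MEAN_RR_MS))
    lf_amp_ms: dict = field(default_factory=lambda: dict(LEVEL_LF_AMP_MS))
    hf_amp_ms: dict = field(default_factory=lambda: dict(LEVEL_HF_AMP_MS))
    resp_rate_hz: dict = field(default_factory=lambda: dict(LEVEL_RESP_RATE_HZ))
    noise_sd_ms: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.level_schedule = tuple((float(d), int(l)) for d, l in self.level_schedule)
        if not self.level_schedule:
            raise ValueError("level schedule must not be empty")
        for dur, lvl in self.level_schedule:
            if dur <= 0:
                raise ValueError("schedule durations must be positive")
            if lvl not in {1, 2, 3, 4, 5}:
                raise ValueError(f"ORD level must be in 1..5, got {lvl}")
        if self.noise_sd_ms < 0:
            raise ValueError("noise SD must be nonnegative")
        for lvl, rr in self.mean_rr_ms.items():
            if not 300.0 <= rr <= 1500.0:
                raise ValueError(
                    f"mean RR for level {lvl} must be in 300-1500 ms, got {rr}"
                )
        # LF/HF must strictly decrease with level, except in the degenerate
        # single-band configurations used for controlled fixtures
        lf_all = [self.lf_amp_ms[l] for l in sorted(self.lf_amp_ms)]
        hf_all = [self.hf_amp_ms[l] for l in sorted(self.hf_amp_ms)]
        if any(a < 0 for a in lf_all + hf_all):
            raise ValueError("band amplitudes must be nonnegative")
        if any(v > 0 for v in lf_all) and any(v > 0 for v in hf_all):
            ratios = [lf / hf if hf > 0 else np.inf
                      for lf, hf in zip(lf_all, hf_all)]
            if not all(a > b for a, b in zip(ratios, ratios[1:])):
                raise ValueError(
                    "LF/HF amplitude ratio must strictly decrease with level")
        rates = [self.resp_rate_hz[lvl] for lvl in sorted(self.resp_rate_hz)]
        if not all(a >= b for a, b in zip(rates, rates[1:])):
            raise ValueError("respiration rate must be non-increasing with level")
        if any(r <= 0 for r in rates):
            raise ValueError("respiration rates must be positive")

    @property
    def session_length_s(self) -> float:
        return sum(d for d, _ in self.level_schedule)

    def level_at(self, t_s) -> np.ndarray:
        """ORD level in effect at time(s) ``t_s`` (last level extends past the end)."""
        t = np.atleast_1d(np.asarray(t_s, dtype=float))
        edges = np.cumsum([d for d, _ in self.level_schedule])
        idx = np.searchsorted(edges, t, side="right")
        idx = np.clip(idx, 0, len(self.level_schedule) - 1)
        levels = np.array([l for _, l in self.level_schedule])
        out = levels[idx]
        return out if np.ndim(t_s) else int(out[0])

    def minute_labels(self, session_length_s: float | None = None) -> np.ndarray:
        """(segment_start_s, ord_score) rows, one per 1-minute segment."""
        total = session_length_s or self.session_length_s
        starts = np.arange(0.0, np.floor(total / 60.0) * 60.0, 60.0)
        scores = np.array([float(self.level_at(s + 30.0)) for s in starts])
        return np.column_stack([starts, scores])


@dataclass
class GroundTruth:
    """Analytic ground truth accompanying a synthetic record."""

    r_peak_times_s: np.ndarray = None  # type: ignore[assignment]
    resp_rate_hz_t: object = None  # callable t -> Hz
    region_center_px_t: np.ndarray = None  # type: ignore[assignment]  # (n_frames, 2) row,col

    def __post_init__(self) -> None:
        if self.r_peak_times_s is not None:
            t = np.asarray(self.r_peak_times_s, dtype=float)
            if t.size > 1:
                drr = np.diff(t)
                if np.any(drr <= 0):
                    raise ValueError("R-peak times must be strictly increasing")
                if np.any(drr < 0.250):
                    raise ValueError("minimum RR interval is 250 ms")
            self.r_peak_times_s = t


def generate_rr_series(
    profile: SubjectProfile, duration_s: float
) -> tuple[RRSeries, GroundTruth]:
    """Generate an RR-interval train with LF+HF sinusoidal modulation.

    The n-th interval is ``mean_rr(level) + lf_amp(level) sin(2 pi 0.1 t_n)
    + hf_amp(level) sin(2 pi 0.25 t_n) + eps_n`` with ``eps ~ N(0, noise_sd^2)``
    and ``t_n`` the time of the beat opening the interval; beat times are the
    cumulative interval sums.  Reproducible for a fixed profile seed.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(profile.seed)
    beats = [0.0]
    intervals = []
    t = 0.0
    while t < duration_s:
        lvl = profile.level_at(t)
        rr_ms = (
            profile.mean_rr_ms[lvl]
            + profile.lf_amp_ms[lvl] * np.sin(2 * np.pi * LF_CENTER_HZ * t)
            + profile.hf_amp_ms[lvl] * np.sin(2 * np.pi * HF_CENTER_HZ * t)
            + (rng.normal(0.0, profile.noise_sd_ms) if profile.noise_sd_ms else 0.0)
        )
        rr_ms = max(rr_ms, 300.0)  # physiological floor
        t += rr_ms / 1000.0
        if t > duration_s + 1e-9:
            break
        beats.append(t)
        intervals.append(rr_ms)
    beat_times = np.asarray(beats)
    rr = RRSeries(intervals_ms=np.asarray(intervals), beat_times_s=beat_times[1:])
    truth = GroundTruth(r_peak_times_s=beat_times)
    return rr, truth


@dataclass
class ArtifactSpec:
    """Optional corruption applied to the synthetic ECG."""

    baseline_wander_mv: float = 0.0
    baseline_wander_hz: float = 0.25
    powerline_mv: float = 0.0
    powerline_hz: float = 50.0
    noise_sd_mv: float = 0.0
    n_outlier_spikes: int = 0
    spike_mv: float = 5.0
    seed: int = 0

    @classmethod
    def broadband_snr_db(cls, clean_rms_mv: float, snr_db: float, **kw) -> "ArtifactSpec":
        """Broadband noise level giving the requested SNR against ``clean_rms_mv``."""
        return cls(noise_sd_mv=clean_rms_mv / (10.0 ** (snr_db / 20.0)), **kw)


# P-QRS-T template: (offset_s, amplitude_mv, sigma_s) per Gaussian.
# Analytically, the R Gaussian dominates so the template maximum is at offset 0.
DEFAULT_TEMPLATE = (
    (-0.180, 0.12, 0.025),  # P
    (-0.030, -0.15, 0.010),  # Q
    (0.000, 1.00, 0.012),  # R
    (0.030, -0.20, 0.010),  # S
    (0.220, 0.25, 0.045),  # T
)


def template_span_s(template=DEFAULT_TEMPLATE) -> float:
    lo = min(off - 3 * sig for off, _, sig in template)
    hi = max(off + 3 * sig for off, _, sig in template)
    return hi - lo


def synthesize_ecg(
    rr: RRSeries,
    fs_hz: float = 1000.0,
    artifact_spec: ArtifactSpec | None = None,
    template=DEFAULT_TEMPLATE,
    amplitude_mv: float = 1.0,
) -> tuple[ECGRecord, GroundTruth]:
    """Render an ECG by placing a fixed P-QRS-T Gaussian template at each beat.

    The template's R-wave Gaussian peaks exactly at each ground-truth beat
    time, which gives the R-peak detector an analytically known oracle.
    """
    if fs_hz < 250.0:
        raise ValueError("ECG sampling rate must be at least 250 Hz")
    beat_times = np.concatenate([[rr.beat_times_s[0] - rr.intervals_ms[0] / 1000.0],
                                 rr.beat_times_s]) if len(rr) else np.array([0.0])
    min_rr_s = np.min(rr.intervals_ms) / 1000.0 if len(rr) else np.inf
    if template_span_s(template) > min_rr_s:
        raise ValueError("ECG template is wider than the minimum RR interval")
    pad = 0.5  # lead-in/out so edge beats carry a full template
    t0 = beat_times[0] - pad
    n = int(np.round((beat_times[-1] + pad - t0) * fs_hz))
    t = t0 + np.arange(n) / fs_hz
    sig = np.zeros(n)
    for off, amp, s in template:
        centers = beat_times + off
        # accumulate each Gaussian only over its +-4 sigma support
        half = int(np.ceil(4 * s * fs_hz))
        idx0 = np.round((centers - t0) * fs_hz).astype(int)
        for c, i0 in zip(centers, idx0):
            lo, hi = max(i0 - half, 0), min(i0 + half + 1, n)
            if lo >= hi:
                continue
            sig[lo:hi] += amp * amplitude_mv * np.exp(
                -0.5 * ((t[lo:hi] - c) / s) ** 2
            )
    spec = artifact_spec or ArtifactSpec()
    rng = np.random.default_rng(spec.seed)
    if spec.baseline_wander_mv:
        if spec.baseline_wander_hz >= 0.5:
            raise ValueError("baseline wander must stay below 0.5 Hz")
        sig = sig + spec.baseline_wander_mv * np.sin(
            2 * np.pi * spec.baseline_wander_hz * t
        )
    if spec.powerline_mv:
        sig = sig + spec.powerline_mv * np.sin(2 * np.pi * spec.powerline_hz * t)
    if spec.noise_sd_mv:
        sig = sig + rng.normal(0.0, spec.noise_sd_mv, size=n)
    if spec.n_outlier_spikes:
        pos = rng.choice(n, size=spec.n_outlier_spikes, replace=False)
        sig[pos] += spec.spike_mv * rng.choice([-1.0, 1.0], size=spec.n_outlier_spikes)
    record = ECGRecord(samples=sig, fs_hz=fs_hz, start_time_s=t0)
    return record, GroundTruth(r_peak_times_s=beat_times)


@dataclass
class ThermalGeometry:
    """Frame and nostril-patch geometry for the synthetic thermal sequence."""

    frame_shape: tuple = (48, 64)  # (rows, cols); study camera was 480x640
    patch_shape: tuple = (8, 12)
    start_center: tuple = (24.0, 32.0)  # (row, col)
    background: float = 25.0
    patch_offset: float = 8.0  # mean patch elevation above background
    oscillation_amp: float = 3.0
    pixel_noise_sd: float = 0.05
    drift: str = "none"  # none | linear | sinusoidal
    drift_px_per_frame: tuple = (0.0, 0.0)  # linear drift (rows, cols)
    sway_amp_px: float = 0.0  # sinusoidal sway amplitude (cols)
    sway_freq_hz: float = 0.1


def _patch_centers(geom: ThermalGeometry, n_frames: int, frame_rate: float) -> np.ndarray:
    t = np.arange(n_frames) / frame_rate
    r0, c0 = geom.start_center
    rows = np.full(n_frames, r0)
    cols = np.full(n_frames, c0)
    if geom.drift == "linear":
        rows = r0 + geom.drift_px_per_frame[0] * np.arange(n_frames)
        cols = c0 + geom.drift_px_per_frame[1] * np.arange(n_frames)
    elif geom.drift == "sinusoidal":
        cols = c0 + geom.sway_amp_px * np.sin(2 * np.pi * geom.sway_freq_hz * t)
    elif geom.drift != "none":
        raise ValueError(f"unknown drift mode {geom.drift!r}")
    return np.column_stack([rows, cols])


def synthesize_thermal_sequence(
    profile: SubjectProfile,
    duration_s: float,
    frame_rate_hz: float = 7.5,
    geometry: ThermalGeometry | None = None,
) -> tuple[ThermalSequence, GroundTruth]:
    """Render a thermal frame stack with a breathing nostril patch.

    The patch mean intensity is ``background + offset + amp * sin(phi(t))``
    with ``phi'(t) = 2 pi resp_rate(level(t))``: the instantaneous frequency
    of the patch oscillation follows the level schedule exactly, giving the
    respiration pipeline a closed-form oracle.  The patch centre follows the
    configured drift path so the tracker can be exercised.
    """
    geom = geometry or ThermalGeometry()
    n_frames = int(np.round(duration_s * frame_rate_hz))
    if n_frames < 2:
        raise ValueError("duration too short for the frame rate")
    rows, cols = geom.frame_shape
    ph, pw = geom.patch_shape
    centers = _patch_centers(geom, n_frames, frame_rate_hz)
    top = np.round(centers[:, 0] - ph / 2).astype(int)
    left = np.round(centers[:, 1] - pw / 2).astype(int)
    if (top.min() < 0 or left.min() < 0 or (top + ph).max() > rows
            or (left + pw).max() > cols):
        raise ValueError("nostril patch leaves the frame along the drift path")

    t = np.arange(n_frames) / frame_rate_hz
    inst_rate = np.array([profile.resp_rate_hz[profile.level_at(ti)] for ti in t])
    # phase = 2 pi * cumulative integral of the instantaneous rate
    phase = 2 * np.pi * np.concatenate(
        [[0.0], np.cumsum(0.5 * (inst_rate[1:] + inst_rate[:-1]) / frame_rate_hz)]
    )
    patch_mean = geom.patch_offset + geom.oscillation_amp * np.sin(phase)

    rng = np.random.default_rng(profile.seed + 1)
    frames = np.full((n_frames, rows, cols), geom.background, dtype=np.float32)
    if geom.pixel_noise_sd:
        frames += rng.normal(0.0, geom.pixel_noise_sd, size=frames.shape).astype(
            np.float32
        )
    for i in range(n_frames):
        frames[i, top[i]:top[i] + ph, left[i]:left[i] + pw] += patch_mean[i]
    seq = ThermalSequence(frames=frames, frame_rate_hz=frame_rate_hz)

    def rate_fn(ts):
        lvl = profile.level_at(ts)
        if np.ndim(ts):
            return np.array([profile.resp_rate_hz[l] for l in np.atleast_1d(lvl)])
        return profile.resp_rate_hz[lvl]

    truth = GroundTruth(resp_rate_hz_t=rate_fn, region_center_px_t=centers)
    return seq, truth


def synthesize_ecg_with_snr(
    rr: RRSeries,
    fs_hz: float = 1000.0,
    snr_db: float = 20.0,
    seed: int = 0,
    **kw,
) -> tuple[ECGRecord, GroundTruth]:
    """Synthesize an ECG, then add broadband noise at a given SNR.

    The noise SD is set against the measured RMS of the clean template train,
    so the requested SNR is exact by construction.
    """
    clean, truth = synthesize_ecg(rr, fs_hz=fs_hz, **kw)
    rms = float(np.sqrt(np.mean(clean.samples**2)))
    rng = np.random.default_rng(seed)
    noisy = clean.samples + rng.normal(
        0.0, rms / (10.0 ** (snr_db / 20.0)), size=clean.samples.size
    )
    return ECGRecord(samples=noisy, fs_hz=fs_hz,
                     start_time_s=clean.start_time_s), truth


# ---------------------------------------------------------------------------
# Cohort generation


def _default_schedule(session_length_s: float, levels: tuple) -> tuple:
    seg = session_length_s / len(levels)
    return tuple((seg, l) for l in levels)


@dataclass
class SyntheticSubject:
    """In-memory bundle of one subject's raw data and ground truth."""

    profile: SubjectProfile
    ecg: ECGRecord
    thermal: ThermalSequence
    labels: np.ndarray  # (n_minutes, 2): segment_start_s, ord_score
    ecg_truth: GroundTruth
    thermal_truth: GroundTruth


def simulate_subject(
    profile: SubjectProfile,
    session_length_s: float,
    ecg_fs_hz: float = 1000.0,
    frame_rate_hz: float = 7.5,
    geometry: ThermalGeometry | None = None,
    artifact_spec: ArtifactSpec | None = None,
    ecg_snr_db: float | None = None,
) -> SyntheticSubject:
    rr, _ = generate_rr_series(profile, session_length_s)
    if ecg_snr_db is not None:
        ecg, ecg_truth = synthesize_ecg_with_snr(
            rr, fs_hz=ecg_fs_hz, snr_db=ecg_snr_db, seed=profile.seed + 7
        )
    else:
        ecg, ecg_truth = synthesize_ecg(rr, fs_hz=ecg_fs_hz,
                                        artifact_spec=artifact_spec)
    thermal, th_truth = synthesize_thermal_sequence(
        profile, session_length_s, frame_rate_hz=frame_rate_hz, geometry=geometry
    )
    return SyntheticSubject(
        profile=profile,
        ecg=ecg,
        thermal=thermal,
        labels=profile.minute_labels(session_length_s),
        ecg_truth=ecg_truth,
        thermal_truth=th_truth,
    )


def cohort_profiles(
    n_subjects: int,
    session_length_s: float,
    seed: int,
    levels: tuple = (1, 2, 3, 4, 5),
    noise_sd_ms: float = 10.0,
) -> list[SubjectProfile]:
    """Deterministic per-subject profiles streamed from one cohort seed."""
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    if session_length_s < 120.0:
        raise ValueError("session must cover at least one 2-minute epoch")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_subjects) % (2**31)
    return [
        SubjectProfile(
            subject_id=f"subject_{i + 1:02d}",
            level_schedule=_default_schedule(session_length_s, levels),
            noise_sd_ms=noise_sd_ms,
            seed=int(child_seeds[i]),
        )
        for i in range(n_subjects)
    ]


def generate_cohort(
    n_subjects: int,
    session_length_s: float,
    seed: int,
    out_dir: str | Path | None = None,
    levels: tuple = (1, 2, 3, 4, 5),
    ecg_fs_hz: float = 1000.0,
    frame_rate_hz: float = 7.5,
    geometry: ThermalGeometry | None = None,
    noise_sd_ms: float = 10.0,
    ecg_snr_db: float | None = None,
):
    """Simulate a cohort; optionally write the on-disk layout.

    Each subject's session walks through ``levels`` in order, one equal-length
    segment per level.  A single cohort seed streams deterministic per-subject
    sub-seeds.  With ``out_dir`` set, writes per subject: ``ecg.csv``
    (time_s, mv), ``thermal.tif`` (multi-page float32 TIFF), ``labels.csv``
    (segment_start_s, ord_score) and a cohort ``manifest.json``; returns the
    manifest dict.  Without ``out_dir`` returns the in-memory subject list.
    """
    profiles = cohort_profiles(n_subjects, session_length_s, seed,
                               levels=levels, noise_sd_ms=noise_sd_ms)
    subjects = [
        simulate_subject(
            profile,
            session_length_s,
            ecg_fs_hz=ecg_fs_hz,
            frame_rate_hz=frame_rate_hz,
            geometry=geometry,
            ecg_snr_db=ecg_snr_db,
        )
        for profile in profiles
    ]
    if out_dir is None:
        return subjects

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "n_subjects": n_subjects,
                "session_length_s": session_length_s, "subjects": []}
    for subj in subjects:
        sdir = out / subj.profile.subject_id
        sdir.mkdir(exist_ok=True)
        tt = subj.ecg.times_s
        np.savetxt(
            sdir / "ecg.csv",
            np.column_stack([tt, subj.ecg.samples]),
            fmt="%.4f,%.5f",
            header="time_s,mv",
            comments="",
        )
        tifffile.imwrite(sdir / "thermal.tif", subj.thermal.frames)
        np.savetxt(
            sdir / "labels.csv",
            subj.labels,
            fmt="%.1f,%.3f",
            header="segment_start_s,ord_score",
            comments="",
        )
        manifest["subjects"].append(
            {
                "subject_id": subj.profile.subject_id,
                "ecg": str(sdir / "ecg.csv"),
                "ecg_fs_hz": subj.ecg.fs_hz,
                "thermal": str(sdir / "thermal.tif"),
                "frame_rate_hz": subj.thermal.frame_rate_hz,
                "labels": str(sdir / "labels.csv"),
                "seed": subj.profile.seed,
            }
        )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
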