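"""Epoch dataset construction: alignment, labelling, normalization and folds.

The three channels (4 Hz HRV tachogram, its banded 128-bin spectrum, and the
1 Hz respiration rate) are cut into 2-minute epochs with 60% overlap
(hop 48 s).  Each epoch carries the duration-weighted mean observer
drowsiness score (ORD) of the minutes it spans, mapped to both a 3-level and
a 5-level class label.  Normalization is z-scoring per channel and feature
position, with statistics estimated on training epochs only.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.model_selection import GroupKFold, StratifiedKFold

from .containers import Epoch, EpochDataset
from .ecg import PSD_N_BINS, TACHOGRAM_FS_HZ, hrv_psd

__all__ = [
    "EPOCH_LENGTH_S",
    "EPOCH_OVERLAP",
    "EPOCH_HOP_S",
    "epoch_count",
    "epochize",
    "map_labels",
    "class_weights",
    "make_folds",
    "ChannelZScore",
    "normalize_dataset",
    "build_dataset_from_cohort",
    "build_synthetic_dataset",
]

EPOCH_LENGTH_S = 120.0
EPOCH_OVERLAP = 0.60
EPOCH_HOP_S = EPOCH_LENGTH_S * (1.0 - EPOCH_OVERLAP)  # 48 s
RR_FS_HZ = 1.0

HRV_LEN = int(EPOCH_LENGTH_S * TACHOGRAM_FS_HZ)  # 480
RR_LEN = int(EPOCH_LENGTH_S * RR_FS_HZ)  # 120


def epoch_count(session_length_s: float) -> int:
    """Number of 2-min epochs at 60% overlap fitting in a session."""
    if session_length_s < EPOCH_LENGTH_S:
        return 0
    return int(np.floor((session_length_s - EPOCH_LENGTH_S) / EPOCH_HOP_S)) + 1


def map_labels(ord_score: float, moderate_tol: float = 0.25) -> tuple[int, int]:
    """Map a (possibly fractional) mean ORD score to 3- and 5-level classes.

    3-level: score < 3 -> 0 (wakeful), within ``moderate_tol`` of 3 -> 1
    (moderately drowsy), > 3 -> 2 (extremely drowsy).  The tolerance
    accommodates fractional observer means around the integer anchor.
    5-level: round half-up (toward greater drowsiness) to 1..5, shifted to 0..4.
    """
    s = float(ord_score)
    if not 1.0 <= s <= 5.0:
        raise ValueError(f"ORD score must be in [1, 5], got {s}")
    if abs(s - 3.0) <= moderate_tol:
        label3 = 1
    elif s < 3.0:
        label3 = 0
    else:
        label3 = 2
    label5 = int(min(max(np.floor(s + 0.5), 1), 5)) - 1
    return label3, label5


def _epoch_ord(labels_1min: np.ndarray, t0: float, t1: float) -> float:
    """Duration-weighted mean of 1-minute ORD scores overlapping [t0, t1)."""
    starts = labels_1min[:, 0]
    scores = labels_1min[:, 1]
    ends = np.concatenate([starts[1:], [starts[-1] + 60.0]])
    overlap = np.minimum(ends, t1) - np.maximum(starts, t0)
    overlap = np.clip(overlap, 0.0, None)
    total = overlap.sum()
    if total <= 0:
        raise ValueError("epoch does not overlap any labelled minute")
    return float((scores * overlap).sum() / total)


def epochize(
    hrv_times_s: np.ndarray,
    hrv_ms: np.ndarray,
    rr_times_s: np.ndarray,
    rr_hz: np.ndarray,
    labels_1min: np.ndarray,
    subject_id: str,
    session_length_s: float | None = None,
    moderate_tol: float = 0.25,
) -> list[Epoch]:
    """Cut aligned channels into overlapping 2-minute epochs.

    All inputs share the session clock (seconds from session start).  The
    HRV spectrum channel is computed per epoch from that epoch's tachogram
    segment.  Epoch ORD is the duration-weighted mean of the 1-minute scores
    the epoch spans.
    """
    labels_1min = np.asarray(labels_1min, dtype=float)
    if session_length_s is None:
        session_length_s = float(labels_1min[-1, 0] + 60.0)
    n_epochs = epoch_count(session_length_s)
    if n_epochs == 0:
        warnings.warn("session shorter than one epoch; no epochs produced")
        return []
    epochs = []
    for k in range(n_epochs):
        t0 = k * EPOCH_HOP_S
        t1 = t0 + EPOCH_LENGTH_S
        hrv_grid = t0 + np.arange(HRV_LEN) / TACHOGRAM_FS_HZ
        hrv = np.interp(hrv_grid, hrv_times_s, hrv_ms)
        rr_grid = t0 + np.arange(RR_LEN) / RR_FS_HZ
        rr = np.interp(rr_grid, rr_times_s, rr_hz)
        psd = hrv_psd(hrv, TACHOGRAM_FS_HZ).power
        ord_score = _epoch_ord(labels_1min, t0, t1)
        l3, l5 = map_labels(ord_score, moderate_tol=moderate_tol)
        epochs.append(
            Epoch(hrv=hrv, hrv_psd=psd, rr=rr, label_ord=ord_score,
                  label_3=l3, label_5=l5, subject_id=subject_id, start_time_s=t0)
        )
    return epochs


def class_weights(labels: np.ndarray, n_classes: int | None = None) -> np.ndarray:
    """Inverse-frequency class weights ``w_c = N / (K * n_c)``.

    Mean-one under the class distribution: ``sum_c w_c n_c = N``.
    """
    labels = np.asarray(labels, dtype=int)
    k = n_classes if n_classes is not None else int(labels.max()) + 1
    counts = np.bincount(labels, minlength=k)
    if np.any(counts == 0):
        missing = np.nonzero(counts == 0)[0].tolist()
        raise ValueError(f"classes {missing} have no examples")
    return labels.size / (k * counts.astype(float))


def make_folds(
    labels: np.ndarray,
    k: int = 5,
    seed: int = 0,
    groups: np.ndarray | None = None,
) -> np.ndarray:
    """Per-epoch fold index 0..k-1 (each fold serves once as the 20% test set).

    Stratified by label; with ``groups`` given (subject ids), uses a grouped
    split instead so no subject straddles folds -- epoch-level random splits
    leak subject identity between train and test.
    """
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels)
    folds = np.empty(labels.size, dtype=int)
    if groups is not None:
        splitter = GroupKFold(n_splits=k)
        for f, (_, test_idx) in enumerate(splitter.split(labels, labels, groups)):
            folds[test_idx] = f
        return folds
    if np.any(counts[counts > 0] < k):
        raise ValueError(f"every class needs at least {k} epochs for {k}-fold CV")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for f, (_, test_idx) in enumerate(splitter.split(labels, labels)):
        folds[test_idx] = f
    return folds


class ChannelZScore:
    """Per-channel, per-feature-position z-scoring fit on training epochs only.

    Zero-variance feature positions get their SD clamped to 1 (and are
    recorded), so constant held-out features stay finite.
    """

    def __init__(self, eps: float = 1e-12):
        self.eps = eps

    def fit(self, channels: dict) -> "ChannelZScore":
        self.mean_ = {}
        self.sd_ = {}
        self.clamped_ = {}
        for name, mat in channels.items():
            mat = np.asarray(mat, dtype=float)
            mu = mat.mean(axis=0)
            sd = mat.std(axis=0)
            clamped = sd < self.eps
            sd = np.where(clamped, 1.0, sd)
            self.mean_[name] = mu
            self.sd_[name] = sd
            self.clamped_[name] = clamped
        return self

    def transform(self, channels: dict) -> dict:
        return {
            name: (np.asarray(mat, dtype=float) - self.mean_[name]) / self.sd_[name]
            for name, mat in channels.items()
        }

    def inverse_transform(self, channels: dict) -> dict:
        return {
            name: np.asarray(mat, dtype=float) * self.sd_[name] + self.mean_[name]
            for name, mat in channels.items()
        }

    def stats(self) -> dict:
        return {
            name: {"mean": self.mean_[name], "sd": self.sd_[name],
                   "provenance": "training-epochs-only"}
            for name in self.mean_
        }


def normalize_dataset(
    dataset: EpochDataset,
    train_mask: np.ndarray,
    channels: tuple = ("hrv", "hrv_psd", "rr"),
) -> tuple[dict, dict, ChannelZScore]:
    """Fit z-score stats on training epochs; apply to the whole dataset.

    Returns ``(normalized_channels, stats, scaler)``.  ``train_mask`` selects
    the epochs whose statistics are used; test epochs never contribute.
    """
    train_mask = np.asarray(train_mask, dtype=bool)
    raw = dataset.as_dict(channels)
    scaler = ChannelZScore().fit({c: raw[c][train_mask] for c in channels})
    normalized = scaler.transform(raw)
    dataset.normalization_stats = scaler.stats()
    return normalized, dataset.normalization_stats, scaler


def build_dataset_from_cohort(
    subjects,
    use_ground_truth_rr: bool = False,
    moderate_tol: float = 0.25,
) -> EpochDataset:
    """Run both signal pipelines on a synthetic cohort and epochize.

    ``subjects`` is a list of :class:`~drowsinet.synth.SyntheticSubject`.
    With ``use_ground_truth_rr`` the respiration channel is taken from the
    generator's analytic rate instead of the thermal pipeline (useful for
    isolating the ECG pathway in experiments).
    """
    from .ecg import process_ecg
    from .respiration import process_thermal

    dataset = EpochDataset()
    for subj in subjects:
        hrv_t, hrv, _ = process_ecg(subj.ecg)
        duration = subj.profile.session_length_s
        if use_ground_truth_rr:
            rr_t = np.arange(0.0, np.floor(duration))
            rr = np.asarray(subj.thermal_truth.resp_rate_hz_t(rr_t), dtype=float)
        else:
            rate, _ = process_thermal(subj.thermal)
            rr_t, rr = rate.times_s, rate.rate_hz
        dataset.epochs.extend(
            epochize(hrv_t, hrv, rr_t, rr, subj.labels,
                     subject_id=subj.profile.subject_id,
                     session_length_s=duration, moderate_tol=moderate_tol)
        )
    return dataset


def build_synthetic_dataset(
    n_subjects: int,
    session_length_s: float,
    seed: int,
    levels: tuple = (1, 2, 3, 4, 5),
    ecg_snr_db: float | None = 20.0,
    noise_sd_ms: float = 10.0,
    moderate_tol: float = 0.25,
) -> EpochDataset:
    """Simulate and process a synthetic cohort one subject at a time.

    Equivalent to ``generate_cohort`` + ``build_dataset_from_cohort`` but
    holds only one subject's raw data in memory at once.
    """
    from .synth import cohort_profiles, simulate_subject

    profiles = cohort_profiles(n_subjects, session_length_s, seed,
                               levels=levels, noise_sd_ms=noise_sd_ms)
    dataset = EpochDataset()
    for profile in profiles:
        subj = simulate_subject(profile, session_length_s, ecg_snr_db=ecg_snr_db)
        part = build_dataset_from_cohort([subj], moderate_tol=moderate_tol)
        dataset.epochs.extend(part.epochs)
    return dataset
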