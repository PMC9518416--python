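"""Core data containers shared across the ECG, respiration and dataset pipelines.

All containers are plain dataclasses around NumPy arrays; they carry the
sampling metadata that the downstream stages need and validate their own
invariants at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ECGRecord",
    "RRSeries",
    "PSDSpectrum",
    "ThermalSequence",
    "RegionTrack",
    "RespirationRateSignal",
    "Epoch",
    "EpochDataset",
]


@dataclass
class ECGRecord:
    """Single-channel ECG: sample values in mV at a uniform sampling rate."""

    samples: np.ndarray
    fs_hz: float
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs_hz}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("ECG samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.samples.size) / self.fs_hz


@dataclass
class RRSeries:
    """Beat-to-beat (RR) interval sequence, the raw heart-rate-variability signal.

    ``beat_times_s[i]`` is the time of the *second* beat bounding
    ``intervals_ms[i]``.  ``outlier_mask`` marks intervals flagged by the
    30%-of-last-4 ectopic rule; masked intervals are excluded from spline
    support when resampling.
    """

    intervals_ms: np.ndarray
    beat_times_s: np.ndarray
    outlier_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=float)
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        if self.outlier_mask is None:
            self.outlier_mask = np.zeros(self.intervals_ms.size, dtype=bool)
        else:
            self.outlier_mask = np.asarray(self.outlier_mask, dtype=bool)
        if self.intervals_ms.size != self.beat_times_s.size:
            raise ValueError("intervals and beat times must have equal length")
        if self.intervals_ms.size and np.any(self.intervals_ms <= 0):
            raise ValueError("RR intervals must be positive")
        if np.any(np.diff(self.beat_times_s) <= 0):
            raise ValueError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return self.intervals_ms.size


@dataclass
class PSDSpectrum:
    """One-sided HRV power spectral density (ms^2/Hz) on an increasing grid."""

    freq_hz: np.ndarray
    power: np.ndarray
    band: tuple = (0.04, 0.4)
    total_power_ms2: float = float("nan")  # full-band power, for Parseval checks

    def __post_init__(self) -> None:
        self.freq_hz = np.asarray(self.freq_hz, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.freq_hz) <= 0):
            raise ValueError("frequency grid must be increasing")
        if np.any(self.power < 0):
            raise ValueError("power density must be nonnegative")


@dataclass
class ThermalSequence:
    """Stack of 2-D thermal frames (arbitrary intensity units) at a fixed rate."""

    frames: np.ndarray  # (n_frames, rows, cols)
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, rows, cols) stack")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple:
        return self.frames.shape[1:]


@dataclass
class RegionTrack:
    """Per-frame bounding boxes (row, col, height, width) with confidences."""

    boxes: np.ndarray  # (n_frames, 4) int: top row, left col, height, width
    confidence: np.ndarray  # (n_frames,)
    flagged: np.ndarray  # frames where the tracker held its last position

    def __post_init__(self) -> None:
        self.boxes = np.asarray(self.boxes, dtype=int)
        self.confidence = np.asarray(self.confidence, dtype=float)
        self.flagged = np.asarray(self.flagged, dtype=bool)

    def centers(self) -> np.ndarray:
        """(row, col) center of each per-frame box."""
        return self.boxes[:, :2] + self.boxes[:, 2:] / 2.0


@dataclass
class RespirationRateSignal:
    """Instantaneous respiration rate on a uniform 1 Hz grid."""

    times_s: np.ndarray
    rate_hz: np.ndarray
    quality: np.ndarray = None  # type: ignore[assignment]  # True where reliable

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.rate_hz = np.asarray(self.rate_hz, dtype=float)
        if self.quality is None:
            self.quality = np.ones(self.rate_hz.size, dtype=bool)
        else:
            self.quality = np.asarray(self.quality, dtype=bool)


@dataclass
class Epoch:
    """One 2-minute analysis window with the three classifier input channels.

    hrv: 480 samples (4 Hz x 120 s) of the resampled tachogram, ms
    hrv_psd: 128-bin banded spectrum of this epoch's tachogram, ms^2/Hz
    rr: 120 samples (1 Hz x 120 s) of instantaneous respiration rate, Hz
    """

    hrv: np.ndarray
    hrv_psd: np.ndarray
    rr: np.ndarray
    label_ord: float
    label_3: int
    label_5: int
    subject_id: str
    start_time_s: float


@dataclass
class EpochDataset:
    """Aligned per-epoch channels with labels and cross-validation folds."""

    epochs: list = field(default_factory=list)
    normalization_stats: dict = field(default_factory=dict)
    folds: np.ndarray = None  # type: ignore[assignment]

    def __len__(self) -> int:
        return len(self.epochs)

    def channel_matrix(self, name: str) -> np.ndarray:
        """Stack one channel across epochs into an (n_epochs, length) matrix."""
        return np.stack([getattr(e, name) for e in self.epochs])

    def labels(self, granularity: int) -> np.ndarray:
        if granularity == 3:
            return np.array([e.label_3 for e in self.epochs], dtype=int)
        if granularity == 5:
            return np.array([e.label_5 for e in self.epochs], dtype=int)
        raise ValueError("granularity must be 3 or 5")

    def as_dict(self, channels=("hrv", "hrv_psd", "rr")) -> dict:
        return {c: self.channel_matrix(c) for c in channels}
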