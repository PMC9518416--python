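"""Respiration-rate extraction from thermal frame sequences.

Airflow through the nostrils modulates the local skin/air temperature at the
breathing rate, so the nostril region is the most temporally active area of a
thermal video of a resting face.  The pipeline: localize that region from
accumulated inter-frame changes, track it with the spatiotemporal-context
tracker, average its pixels per frame into a respiration waveform, clean and
low-pass the waveform, and read the instantaneous respiration rate off a
synchrosqueezed time-frequency ridge, resampled to 1 Hz.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy import signal as sps
from skimage import measure

from .containers import RegionTrack, RespirationRateSignal, ThermalSequence
from .ecg import remove_outliers_grubbs
from .sst import sst_instantaneous_frequency
from .tracking import track_region_stc

__all__ = [
    "localize_respiration_region",
    "extract_respiration_waveform",
    "clean_respiration",
    "instantaneous_rate_sst",
    "process_thermal",
    "RATE_BAND_HZ",
]

RATE_BAND_HZ = (0.05, 1.0)
EDGE_GUARD_S = 5.0  # SST ridge ends are edge-affected; marked low-confidence


class NoBreathingRegionError(RuntimeError):
    """Raised when no temporally active region is found in the initial frames."""


def localize_respiration_region(
    seq: ThermalSequence,
    n_init_frames: int = 40,
    smooth_sigma_px: float = 1.5,
    quantile: float = 0.99,
) -> tuple:
    """Locate the breathing region from the first frames of the sequence.

    Accumulates absolute inter-frame differences over ``n_init_frames``,
    smooths the activity map, thresholds it at ``quantile`` and returns the
    bounding box (top, left, height, width) of the largest 8-connected
    supra-threshold component.
    """
    if n_init_frames < 10:
        raise ValueError("need at least 10 initialization frames")
    frames = np.asarray(seq.frames[:n_init_frames], dtype=float)
    if frames.shape[0] < 2:
        raise ValueError("sequence too short")
    activity = np.sum(np.abs(np.diff(frames, axis=0)), axis=0)
    activity = ndimage.gaussian_filter(activity, smooth_sigma_px)
    thresh = np.quantile(activity, quantile)
    mask = activity >= thresh
    if not mask.any() or activity.max() <= activity.mean() + 1e-12:
        raise NoBreathingRegionError("no supra-threshold breathing activity found")
    labels = measure.label(mask, connectivity=2)
    props = measure.regionprops(labels, intensity_image=activity)
    if not props:
        raise NoBreathingRegionError("no connected activity component found")
    best = max(props, key=lambda p: p.area)
    # grow the seed component to the full active region: keep pixels at least
    # half as active as the seed's mean and 8-connected to it
    grow = activity >= 0.5 * best.intensity_mean
    grow_labels = measure.label(grow, connectivity=2)
    seed_label = grow_labels[tuple(np.argwhere(labels == best.label)[0])]
    region = grow_labels == seed_label
    rows_any = np.nonzero(region.any(axis=1))[0]
    cols_any = np.nonzero(region.any(axis=0))[0]
    r0, r1 = rows_any[0], rows_any[-1] + 1
    c0, c1 = cols_any[0], cols_any[-1] + 1
    return (int(r0), int(c0), int(r1 - r0), int(c1 - c0))


def extract_respiration_waveform(seq: ThermalSequence, track: RegionTrack) -> np.ndarray:
    """Per-frame mean of the pixels inside the tracked box."""
    frames = np.asarray(seq.frames, dtype=float)
    if track.boxes.shape[0] != frames.shape[0]:
        raise ValueError("track must cover every frame")
    out = np.empty(frames.shape[0])
    for i, (top, left, h, w) in enumerate(track.boxes):
        if h <= 0 or w <= 0:
            raise ValueError("empty tracking box")
        out[i] = frames[i, top:top + h, left:left + w].mean()
    return out


def clean_respiration(
    waveform: np.ndarray,
    frame_rate_hz: float,
    cutoff_hz: float = 0.6,
    grubbs_alpha: float = 0.05,
    grubbs_window_s: float = 30.0,
) -> np.ndarray:
    """Grubbs outlier removal then a zero-phase 4th-order 0.6 Hz low-pass."""
    if frame_rate_hz <= 2 * cutoff_hz:
        raise ValueError("frame rate must exceed twice the low-pass cutoff")
    cleaned, _ = remove_outliers_grubbs(
        waveform, alpha=grubbs_alpha,
        window=max(int(grubbs_window_s * frame_rate_hz), 3),
    )
    if np.ptp(cleaned) == 0:
        return cleaned  # constant signal: filtering is the identity up to edges
    sos = sps.butter(4, cutoff_hz, btype="lowpass", fs=frame_rate_hz, output="sos")
    mean = cleaned.mean()
    return sps.sosfiltfilt(sos, cleaned - mean) + mean


def instantaneous_rate_sst(
    waveform: np.ndarray,
    frame_rate_hz: float,
    band: tuple = RATE_BAND_HZ,
    voices_per_octave: int = 32,
) -> RespirationRateSignal:
    """Instantaneous respiration rate at 1 Hz via the synchrosqueezed ridge.

    The maximum-energy ridge through the squeezed plane, restricted to
    ``band``, is evaluated at integer seconds.  The first and last 5 s are
    marked low-quality (wavelet edge effects).
    """
    waveform = np.asarray(waveform, dtype=float)
    duration = waveform.size / frame_rate_hz
    if duration < 60.0:
        raise ValueError("need at least 60 s of signal for a stable ridge")
    if np.ptp(waveform) == 0:
        raise ValueError("no respiratory activity in the waveform")
    ridge = sst_instantaneous_frequency(
        waveform, frame_rate_hz, fmin=band[0], fmax=band[1],
        voices_per_octave=voices_per_octave,
    )
    t_frames = np.arange(waveform.size) / frame_rate_hz
    times = np.arange(0.0, np.floor(duration))
    rate = np.interp(times, t_frames, ridge)
    quality = (times >= EDGE_GUARD_S) & (times <= duration - EDGE_GUARD_S)
    return RespirationRateSignal(times_s=times, rate_hz=rate, quality=quality)


def process_thermal(
    seq: ThermalSequence,
    n_init_frames: int = 40,
    tracker_kw: dict | None = None,
) -> tuple[RespirationRateSignal, RegionTrack]:
    """Thermal stack -> 1 Hz respiration-rate signal (full pipeline)."""
    box = localize_respiration_region(seq, n_init_frames=n_init_frames)
    track = track_region_stc(seq, box, **(tracker_kw or {}))
    waveform = extract_respiration_waveform(seq, track)
    cleaned = clean_respiration(waveform, seq.frame_rate_hz)
    rate = instantaneous_rate_sst(cleaned, seq.frame_rate_hz)
    return rate, track
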