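"""ECG processing: artifact removal, R-peak detection and HRV spectral analysis.

The chain mirrors standard HRV practice: windowed Grubbs outlier removal on
the raw trace, a zero-phase 2-40 Hz Butterworth band-pass, Pan-Tompkins
R-peak detection, the 30%-of-last-4 ectopic-interval rule on the tachogram,
cubic-spline resampling to a uniform 4 Hz grid, and a Hann-windowed FFT
periodogram capped to the drowsiness-relevant 0.04-0.4 Hz band.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline
from scipy.stats import t as t_dist

from .containers import ECGRecord, PSDSpectrum, RRSeries

__all__ = [
    "grubbs_critical_value",
    "remove_outliers_grubbs",
    "bandpass_ecg",
    "detect_r_peaks_pan_tompkins",
    "rr_series_from_beats",
    "rr_outlier_filter",
    "resample_tachogram",
    "hrv_psd",
    "lf_hf_ratio",
    "process_ecg",
    "LF_BAND",
    "HF_BAND",
    "PSD_BAND",
    "PSD_N_BINS",
    "TACHOGRAM_FS_HZ",
]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)
PSD_BAND = (0.04, 0.4)
PSD_N_BINS = 128
TACHOGRAM_FS_HZ = 4.0


# ---------------------------------------------------------------------------
# Grubbs outlier removal


@lru_cache(maxsize=4096)
def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value for sample size ``n`` at level ``alpha``."""
    if n < 3:
        return np.inf
    tc = t_dist.ppf(1.0 - alpha / (2.0 * n), df=n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(tc**2 / (n - 2 + tc**2)))


def _grubbs_flag_window(x: np.ndarray, alpha: float,
                        max_fraction: float = 0.01) -> np.ndarray:
    """Indices (into ``x``) flagged by the iterated two-sided Grubbs test.

    At most ``max_fraction`` of the window is removed: genuine movement
    artifacts are sparse, and an uncapped iteration on a heavy-tailed signal
    (raw ECG with its QRS spikes) would keep eating into the signal itself.
    """
    idx = np.arange(x.size)
    flagged = []
    vals = x.copy()
    max_removals = max(int(np.ceil(max_fraction * x.size)), 1)
    while vals.size >= 3 and len(flagged) < max_removals:
        mu, sd = vals.mean(), vals.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(vals - mu)
        k = int(np.argmax(dev))
        g = dev[k] / sd
        if g <= grubbs_critical_value(vals.size, alpha):
            break
        flagged.append(idx[k])
        vals = np.delete(vals, k)
        idx = np.delete(idx, k)
    return np.array(sorted(flagged), dtype=int)


def remove_outliers_grubbs(
    x: np.ndarray,
    alpha: float = 0.05,
    window: int = 10_000,
    max_fraction: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterated two-sided Grubbs test on non-overlapping windows.

    Flagged samples are replaced by linear interpolation of their clean
    neighbours.  Constant windows (zero SD) are left untouched, and the
    operation is idempotent on an already-clean signal.

    Parameters
    ----------
    window : int
        Window length in samples (10 s at 1 kHz by default).  The Grubbs test
        assumes approximately stationary normal data, which holds locally but
        not across a whole drive.
    """
    x = np.asarray(x, dtype=float)
    removed = []
    for start in range(0, x.size, window):
        seg = x[start:start + window]
        if seg.size < 3:
            continue
        removed.extend(start + _grubbs_flag_window(seg, alpha, max_fraction))
    removed = np.array(sorted(removed), dtype=int)
    cleaned = x.copy()
    if removed.size:
        keep = np.setdiff1d(np.arange(x.size), removed)
        cleaned[removed] = np.interp(removed, keep, x[keep])
    return cleaned, removed


# ---------------------------------------------------------------------------
# Filtering and R-peak detection


def bandpass_ecg(record: ECGRecord, lo_hz: float = 2.0, hi_hz: float = 40.0) -> ECGRecord:
    """Zero-phase fourth-order Butterworth band-pass (2-40 Hz).

    Designed at order 2 per band edge (effective band-pass order 4) and
    applied forward-backward so R-peak timing is not shifted.
    """
    if record.fs_hz <= 2 * hi_hz:
        raise ValueError("sampling rate must exceed twice the upper band edge")
    sos = sps.butter(2, [lo_hz, hi_hz], btype="bandpass", fs=record.fs_hz, output="sos")
    filtered = sps.sosfiltfilt(sos, record.samples)
    return ECGRecord(samples=filtered, fs_hz=record.fs_hz,
                     start_time_s=record.start_time_s)


def detect_r_peaks_pan_tompkins(record: ECGRecord) -> np.ndarray:
    """Pan-Tompkins R-peak detection on a band-pass-filtered ECG.

    Classic stages: 5-point derivative, squaring, 150 ms moving-window
    integration, adaptive signal/noise thresholds with a 200 ms refractory
    period, and search-back at 1.66x the running RR estimate when a beat is
    overdue.  Returned times are refined to the local maximum of the filtered
    ECG within +-50 ms of the integrated-signal fiducial.
    """
    x = record.samples
    fs = record.fs_hz
    if x.size < int(2 * fs):
        warnings.warn("record too short for reliable R-peak detection")
    # derivative: y[n] = (1/8)(2x[n] + x[n-1] - x[n-3] - 2x[n-4])
    deriv = np.convolve(x, np.array([2, 1, 0, -1, -2]) / 8.0, mode="same")
    squared = deriv**2
    win = max(int(round(0.150 * fs)), 1)
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(0.200 * fs))
    # candidate local maxima of the integrated signal
    cand, _ = sps.find_peaks(integrated, distance=refractory)
    if cand.size == 0:
        warnings.warn("no candidate peaks found")
        return np.array([])

    # adaptive thresholding (integrated-signal thresholds only; the filtered
    # trace is consulted during refinement)
    init = integrated[: int(2 * fs)]
    spki = 0.25 * np.max(init) if init.size else 0.0
    npki = 0.5 * np.mean(init) if init.size else 0.0
    peaks: list[int] = []
    rr_history: list[float] = []

    def threshold() -> float:
        return npki + 0.25 * (spki - npki)

    i = 0
    while i < cand.size:
        idx = cand[i]
        pk = integrated[idx]
        if pk > threshold():
            if peaks and (idx - peaks[-1]) < refractory:
                i += 1
                continue
            peaks.append(idx)
            spki = 0.125 * pk + 0.875 * spki
            if len(peaks) > 1:
                rr_history.append(peaks[-1] - peaks[-2])
                rr_history[:] = rr_history[-8:]
        else:
            npki = 0.125 * pk + 0.875 * npki
            # search-back: if a beat is overdue by 1.66x the running RR
            # estimate, accept the best sub-threshold candidate at half
            # threshold
            if peaks and rr_history:
                rr_avg = float(np.mean(rr_history))
                if idx - peaks[-1] > 1.66 * rr_avg:
                    window_cand = cand[(cand > peaks[-1] + refractory) & (cand <= idx)]
                    if window_cand.size:
                        best = window_cand[np.argmax(integrated[window_cand])]
                        if integrated[best] > 0.5 * threshold():
                            peaks.append(int(best))
                            peaks.sort()
                            spki = 0.25 * integrated[best] + 0.75 * spki
                            rr_history.append(peaks[-1] - peaks[-2])
                            rr_history[:] = rr_history[-8:]
        i += 1

    if not peaks:
        warnings.warn("no peaks above threshold")
        return np.array([])

    # refine each fiducial to the local max of the filtered ECG within +-50 ms
    half = int(round(0.050 * fs))
    refined = []
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half + 1, x.size)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.unique(refined)
    # enforce refractory after refinement
    keep = [refined[0]]
    for r in refined[1:]:
        if r - keep[-1] >= refractory:
            keep.append(r)
    return record.start_time_s + np.asarray(keep) / fs


def rr_series_from_beats(beat_times_s: np.ndarray) -> RRSeries:
    """Form the tachogram from detected beat times."""
    beat_times_s = np.asarray(beat_times_s, dtype=float)
    if beat_times_s.size < 2:
        raise ValueError("need at least two beats to form RR intervals")
    intervals = np.diff(beat_times_s) * 1000.0
    return RRSeries(intervals_ms=intervals, beat_times_s=beat_times_s[1:])


# ---------------------------------------------------------------------------
# Tachogram cleaning and resampling


def rr_outlier_filter(rr: RRSeries, threshold: float = 0.30) -> RRSeries:
    """Flag RR intervals deviating >30% from the mean of the last 4 clean ones.

    Scanning in time order, interval ``i`` (``i >= 4``) is flagged when
    ``|RR_i - m_i| / m_i > threshold`` with ``m_i`` the mean of the four most
    recent previous *non-flagged* intervals.  The first four intervals are
    never flagged.  Flagged intervals stay in the series but are masked, so
    downstream spline resampling skips them.
    """
    if len(rr) < 5:
        warnings.warn("fewer than 5 intervals; RR outlier filter is a no-op")
        return RRSeries(rr.intervals_ms.copy(), rr.beat_times_s.copy(),
                        rr.outlier_mask.copy())
    x = rr.intervals_ms
    mask = np.zeros(x.size, dtype=bool)
    clean_idx = [0, 1, 2, 3]
    for i in range(4, x.size):
        m = np.mean(x[clean_idx[-4:]])
        if abs(x[i] - m) / m > threshold:
            mask[i] = True
        else:
            clean_idx.append(i)
    return RRSeries(x.copy(), rr.beat_times_s.copy(), mask)


def resample_tachogram(
    rr: RRSeries, fs_out_hz: float = TACHOGRAM_FS_HZ
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-spline resampling of the tachogram onto a uniform grid.

    Masked (ectopic) beats are excluded from the spline support.  The grid
    spans the support of the clean beat times.  Returns ``(times_s, rr_ms)``.
    """
    good = ~rr.outlier_mask
    t = rr.beat_times_s[good]
    y = rr.intervals_ms[good]
    if t.size < 2:
        raise ValueError("need at least two unmasked intervals")
    spline = CubicSpline(t, y)
    n = int(np.floor((t[-1] - t[0]) * fs_out_hz)) + 1
    grid = t[0] + np.arange(n) / fs_out_hz
    return grid, spline(grid)


# ---------------------------------------------------------------------------
# Spectral analysis


def hrv_psd(
    hrv_uniform: np.ndarray,
    fs_hz: float = TACHOGRAM_FS_HZ,
    band: tuple = PSD_BAND,
    n_bins: int = PSD_N_BINS,
    nfft: int = 4096,
) -> PSDSpectrum:
    """Hann-windowed FFT periodogram of the uniform tachogram, band-capped.

    The spectrum is mean-detrended, windowed, zero-padded to ``nfft`` and
    scaled as a one-sided density (ms^2/Hz) whose integral over frequency
    equals the variance of the detrended series (Parseval, up to window
    normalization).  The band-capped spectrum is linearly interpolated onto a
    fixed ``n_bins``-point grid spanning ``band`` so every epoch yields an
    identical-length vector.
    """
    x = np.asarray(hrv_uniform, dtype=float)
    if x.size < 64:
        raise ValueError("need at least 64 samples for the HRV spectrum")
    x = x - x.mean()
    w = np.hanning(x.size)
    xw = x * w
    nfft = max(nfft, x.size)
    spec = np.fft.rfft(xw, n=nfft)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs_hz)
    # one-sided density normalized by the window power, ms^2/Hz
    scale = 1.0 / (fs_hz * np.sum(w**2))
    pxx = (np.abs(spec) ** 2) * scale
    pxx[1:-1] *= 2.0
    total_power = float(np.trapezoid(pxx, freqs))
    grid = np.linspace(band[0], band[1], n_bins)
    power = np.interp(grid, freqs, pxx)
    return PSDSpectrum(freq_hz=grid, power=power, band=band,
                       total_power_ms2=total_power)


def lf_hf_ratio(psd: PSDSpectrum, lf_band: tuple = LF_BAND,
                hf_band: tuple = HF_BAND) -> float:
    """LF/HF band-power ratio (trapezoidal integration), the sympathovagal index."""
    if psd.freq_hz[0] > lf_band[0] + 1e-9 or psd.freq_hz[-1] < hf_band[1] - 1e-9:
        raise ValueError("spectrum does not cover the LF and HF bands")

    def band_power(band):
        sel = (psd.freq_hz >= band[0]) & (psd.freq_hz <= band[1])
        return np.trapezoid(psd.power[sel], psd.freq_hz[sel])

    lf = band_power(lf_band)
    hf = band_power(hf_band)
    if hf <= 0:
        raise ZeroDivisionError("HF band power is zero; LF/HF undefined")
    return float(lf / hf)


# ---------------------------------------------------------------------------
# End-to-end convenience


def process_ecg(
    record: ECGRecord,
    grubbs_alpha: float = 0.05,
    grubbs_window_s: float = 10.0,
) -> tuple[np.ndarray, np.ndarray, RRSeries]:
    """Raw ECG -> uniform 4 Hz tachogram.

    Returns ``(grid_times_s, hrv_ms, rr_series)`` after Grubbs cleaning,
    band-pass filtering, Pan-Tompkins detection and the 30% ectopic rule.
    """
    cleaned, _ = remove_outliers_grubbs(
        record.samples, alpha=grubbs_alpha,
        window=int(grubbs_window_s * record.fs_hz),
    )
    filtered = bandpass_ecg(ECGRecord(cleaned, record.fs_hz, record.start_time_s))
    beats = detect_r_peaks_pan_tompkins(filtered)
    rr = rr_series_from_beats(beats)
    rr = rr_outlier_filter(rr)
    grid, hrv = resample_tachogram(rr)
    return grid, hrv, rr
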