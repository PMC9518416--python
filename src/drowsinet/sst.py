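"""Continuous-wavelet synchrosqueezing and ridge extraction.

The synchrosqueezing transform (SST) sharpens a Morlet continuous wavelet
transform by reassigning each coefficient to its instantaneous frequency,
computed from the phase derivative ``Im(d_b W / W) / 2 pi``.  For a
quasi-sinusoidal signal such as breathing, the squeezed plane concentrates
energy on a thin curve whose location is the instantaneous rate; a
dynamic-programming ridge with a quadratic frequency-jump penalty then reads
that curve off robustly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["cwt_morlet", "synchrosqueeze", "extract_ridge", "sst_instantaneous_frequency"]

MORLET_W0 = 6.0  # Morlet centre angular frequency


def _morlet_hat(omega: np.ndarray) -> np.ndarray:
    """Fourier transform of the analytic Morlet wavelet (zero for omega <= 0)."""
    psi = np.zeros_like(omega)
    pos = omega > 0
    psi[pos] = np.pi**-0.25 * np.exp(-0.5 * (omega[pos] - MORLET_W0) ** 2)
    return psi


def cwt_morlet(
    x: np.ndarray,
    fs: float,
    freqs: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic Morlet CWT evaluated at the requested centre frequencies.

    Returns ``(W, dW)`` where ``W[k, n]`` is the transform at frequency
    ``freqs[k]`` and time ``n / fs`` and ``dW`` its time derivative (for
    phase-based instantaneous-frequency estimation).  The signal is
    mean-removed and zero-padded to the next power of two.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    xhat = np.fft.fft(x - x.mean(), nfft)
    omega = 2 * np.pi * np.fft.fftfreq(nfft, d=1.0 / fs)
    scales = MORLET_W0 / (2 * np.pi * np.asarray(freqs, dtype=float))
    W = np.empty((scales.size, n), dtype=complex)
    dW = np.empty_like(W)
    for k, a in enumerate(scales):
        psi = np.sqrt(a) * _morlet_hat(a * omega)
        prod = xhat * np.conj(psi)
        W[k] = np.fft.ifft(prod)[:n]
        dW[k] = np.fft.ifft(1j * omega * prod)[:n]
    return W, dW


def synchrosqueeze(
    x: np.ndarray,
    fs: float,
    fmin: float = 0.05,
    fmax: float = 1.0,
    voices_per_octave: int = 32,
    n_freq_bins: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Squeeze the Morlet CWT onto a linear frequency grid.

    Returns ``(T, freq_bins)`` where ``T[k, n]`` holds the squared-magnitude
    CWT energy reassigned to the instantaneous frequency ``freq_bins[k]`` at
    time ``n / fs``.
    """
    n_octaves = np.log2(fmax / fmin)
    n_scales = max(int(np.ceil(n_octaves * voices_per_octave)), 2)
    cwt_freqs = fmin * 2 ** (np.arange(n_scales + 1) / voices_per_octave)
    W, dW = cwt_morlet(x, fs, cwt_freqs)
    mag = np.abs(W)
    thresh = 1e-8 * (mag.max() + 1e-300)
    good = mag > thresh
    finst = np.zeros_like(mag)
    finst[good] = np.imag(dW[good] / W[good]) / (2 * np.pi)

    freq_bins = np.linspace(fmin, fmax, n_freq_bins)
    df = freq_bins[1] - freq_bins[0]
    bin_idx = np.round((finst - fmin) / df).astype(int)
    valid = good & (bin_idx >= 0) & (bin_idx < n_freq_bins)
    T = np.zeros((n_freq_bins, W.shape[1]))
    energy = mag**2
    for n_col in range(W.shape[1]):
        v = valid[:, n_col]
        if v.any():
            np.add.at(T[:, n_col], bin_idx[v, n_col], energy[v, n_col])
    return T, freq_bins


def extract_ridge(
    T: np.ndarray,
    freq_bins: np.ndarray,
    jump_penalty: float = 0.5,
    max_jump_bins: int = 10,
) -> np.ndarray:
    """Maximum-energy ridge through the squeezed plane by dynamic programming.

    The path cost is ``-log(T + eps)`` plus ``jump_penalty * (delta_bins)^2``
    per transition, with transitions limited to ``max_jump_bins``.  Returns
    the ridge frequency per time column, refined by an energy-weighted
    centroid over +-2 bins around the discrete path.
    """
    n_bins, n_t = T.shape
    eps = 1e-12 * (T.max() + 1e-300)
    local = -np.log(T + eps)
    cost = local[:, 0].copy()
    back = np.zeros((n_bins, n_t), dtype=np.int16)
    offsets = np.arange(-max_jump_bins, max_jump_bins + 1)
    penalties = jump_penalty * offsets.astype(float) ** 2
    for t in range(1, n_t):
        best = np.full(n_bins, np.inf)
        best_off = np.zeros(n_bins, dtype=np.int16)
        for off, pen in zip(offsets, penalties):
            shifted = np.full(n_bins, np.inf)
            if off >= 0:
                shifted[off:] = cost[: n_bins - off] if off else cost
            else:
                shifted[:off] = cost[-off:]
            cand = shifted + pen
            better = cand < best
            best[better] = cand[better]
            best_off[better] = off
        cost = best + local[:, t]
        back[:, t] = best_off
    path = np.empty(n_t, dtype=int)
    path[-1] = int(np.argmin(cost))
    for t in range(n_t - 1, 0, -1):
        path[t - 1] = path[t] - back[path[t], t]
    # sub-bin refinement: energy-weighted centroid around the discrete ridge
    ridge = np.empty(n_t)
    for t in range(n_t):
        lo = max(path[t] - 2, 0)
        hi = min(path[t] + 3, n_bins)
        w = T[lo:hi, t]
        s = w.sum()
        ridge[t] = (freq_bins[lo:hi] * w).sum() / s if s > 0 else freq_bins[path[t]]
    return ridge


def sst_instantaneous_frequency(
    x: np.ndarray,
    fs: float,
    fmin: float = 0.05,
    fmax: float = 1.0,
    voices_per_octave: int = 32,
    n_freq_bins: int = 512,
    jump_penalty: float = 0.5,
) -> np.ndarray:
    """Instantaneous frequency (Hz) of the dominant component, per sample."""
    T, freq_bins = synchrosqueeze(
        x, fs, fmin=fmin, fmax=fmax,
        voices_per_octave=voices_per_octave, n_freq_bins=n_freq_bins,
    )
    if T.max() <= 0:
        raise ValueError("no oscillatory energy in the analysis band")
    return extract_ridge(T, freq_bins, jump_penalty=jump_penalty)
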