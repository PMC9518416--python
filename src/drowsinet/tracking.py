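"""Spatiotemporal-context (STC) region tracking in thermal frame sequences.

The tracker learns, per frame, a spatial-context model relating the target's
confidence map to the Gaussian-weighted intensity context around it.  The
model is solved in the Fourier domain (an elementwise division), updated
temporally with learning rate ``rho``, and the next position is the argmax of
the confidence map obtained by correlating the model with the new frame's
context.  When confidence collapses the tracker holds its last position and
flags the frame.
"""

from __future__ import annotations

import numpy as np

from .containers import RegionTrack, ThermalSequence

__all__ = ["STCTracker", "track_region_stc"]


def _centered_grid(shape):
    h, w = shape
    r = np.arange(h) - h // 2
    c = np.arange(w) - w // 2
    return np.meshgrid(r, c, indexing="ij")


class STCTracker:
    """Dense spatiotemporal-context tracker over a fixed-size context window.

    Parameters
    ----------
    rho : float
        Temporal learning rate of the context model.
    context_scale : float
        Context window size as a multiple of the target box.
    alpha : float
        Decay length (px) of the target confidence map ``exp(-(|x|/alpha)^beta)``.
    beta : float
        Confidence-map shape exponent.
    reg : float
        Regularizer added to the Fourier-domain denominator.
    conf_floor : float
        Peak-confidence floor below which the position is held and flagged.
    """

    def __init__(self, rho: float = 0.075, context_scale: float = 2.5,
                 alpha: float | None = None, beta: float = 1.0,
                 reg: float = 1e-4, conf_floor: float = 0.05):
        self.rho = rho
        self.context_scale = context_scale
        self.alpha = alpha
        self.beta = beta
        self.reg = reg
        self.conf_floor = conf_floor

    # -- helpers ----------------------------------------------------------

    def _window(self, frame: np.ndarray, center: np.ndarray) -> np.ndarray:
        """Crop the context window around ``center``, clamped to the frame."""
        h, w = self._win_shape
        r0 = int(round(center[0])) - h // 2
        c0 = int(round(center[1])) - w // 2
        rows, cols = frame.shape
        out = np.zeros((h, w), dtype=float)
        r1, c1 = max(r0, 0), max(c0, 0)
        r2, c2 = min(r0 + h, rows), min(c0 + w, cols)
        if r1 < r2 and c1 < c2:
            out[r1 - r0:r2 - r0, c1 - c0:c2 - c0] = frame[r1:r2, c1:c2]
        return out

    def _context_fft(self, win: np.ndarray) -> np.ndarray:
        c = (win - win.mean()) * self._wsigma
        return np.fft.fft2(np.fft.ifftshift(c))

    # -- API ---------------------------------------------------------------

    def init(self, frame: np.ndarray, box: tuple) -> None:
        """Initialize on frame 0 with box = (top_row, left_col, height, width)."""
        top, left, bh, bw = box
        rows, cols = frame.shape
        if not (0 <= top and 0 <= left and top + bh <= rows and left + bw <= cols):
            raise ValueError("initial box must lie within the frame")
        self.box_shape = (int(bh), int(bw))
        h = int(np.ceil(bh * self.context_scale))
        w = int(np.ceil(bw * self.context_scale))
        self._win_shape = (h + h % 2, w + w % 2)
        gr, gc = _centered_grid(self._win_shape)
        dist = np.sqrt(gr.astype(float) ** 2 + gc.astype(float) ** 2)
        sigma = 0.5 * np.hypot(bh, bw)
        self._wsigma = np.exp(-(dist**2) / (2 * sigma**2))
        alpha = self.alpha if self.alpha is not None else 0.25 * np.hypot(bh, bw)
        m = np.exp(-((dist / alpha) ** self.beta))
        self._m_fft = np.fft.fft2(np.fft.ifftshift(m))
        self.center = np.array([top + bh / 2.0, left + bw / 2.0])
        self._H_fft = self._learn(frame)
        self._peak_ref = None

    def _learn(self, frame: np.ndarray) -> np.ndarray:
        cf = self._context_fft(self._window(frame, self.center))
        denom = cf + self.reg * np.abs(cf).max() + 1e-12
        return self._m_fft / denom

    def update(self, frame: np.ndarray) -> tuple:
        """Track into a new frame; returns (center, confidence, flagged)."""
        win = self._window(frame, self.center)
        if win.std() == 0:
            return self.center.copy(), 0.0, True
        cf = self._context_fft(win)
        conf = np.real(np.fft.fftshift(np.fft.ifft2(self._H_fft * cf)))
        peak = float(conf.max())
        if self._peak_ref is None:
            self._peak_ref = peak
        flagged = peak < self.conf_floor * self._peak_ref
        if not flagged and peak > 0:
            k = np.unravel_index(np.argmax(conf), conf.shape)
            offset = np.array([k[0] - self._win_shape[0] // 2,
                               k[1] - self._win_shape[1] // 2], dtype=float)
            self.center = self.center + offset
            self._peak_ref = (1 - self.rho) * self._peak_ref + self.rho * peak
            h_new = self._learn(frame)
            self._H_fft = (1 - self.rho) * self._H_fft + self.rho * h_new
        return self.center.copy(), peak, bool(flagged)


def track_region_stc(
    seq: ThermalSequence, init_box: tuple, **tracker_kw
) -> RegionTrack:
    """Track ``init_box`` (top, left, h, w) through the whole sequence."""
    frames = np.asarray(seq.frames, dtype=float)
    tracker = STCTracker(**tracker_kw)
    tracker.init(frames[0], init_box)
    bh, bw = tracker.box_shape
    n = frames.shape[0]
    boxes = np.zeros((n, 4), dtype=int)
    confs = np.zeros(n)
    flags = np.zeros(n, dtype=bool)

    def center_to_box(center):
        top = int(round(center[0] - bh / 2.0))
        left = int(round(center[1] - bw / 2.0))
        top = min(max(top, 0), frames.shape[1] - bh)
        left = min(max(left, 0), frames.shape[2] - bw)
        return (top, left, bh, bw)

    boxes[0] = center_to_box(tracker.center)
    confs[0] = 1.0
    for i in range(1, n):
        center, conf, flagged = tracker.update(frames[i])
        boxes[i] = center_to_box(center)
        confs[i] = conf
        flags[i] = flagged
    return RegionTrack(boxes=boxes, confidence=confs, flagged=flags)
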