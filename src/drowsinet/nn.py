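"""Minimal NumPy neural-network core: layers, BiLSTM, Adam, weighted CE.

Implements exactly the pieces the drowsiness classifiers need -- 1-D
convolution with 'same' padding, batch normalization, ReLU, max/global
average pooling, dropout, dense layers, (bi)directional LSTM, a softmax
cross-entropy with class weights, and the Adam optimizer.  Every layer
provides ``forward``/``backward`` and an ``out_shape`` used by the
architecture audit; gradients are verified against finite differences in the
test suite.

Array convention: temporal tensors are ``(batch, length, channels)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv1D",
    "BatchNorm",
    "ReLU",
    "MaxPool1D",
    "GlobalAvgPool1D",
    "Dropout",
    "Dense",
    "BiLSTM",
    "Sequential",
    "softmax",
    "weighted_cross_entropy",
    "Adam",
    "layer_shapes",
]


class Param:
    """A learnable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Layer:
    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    def params(self) -> list:
        return []

    def buffers(self) -> list:
        """Non-trainable state (e.g. batch-norm running stats) to checkpoint."""
        return []

    def out_shape(self, shape: tuple) -> tuple:
        return shape


class Conv1D(Layer):
    """1-D convolution, stride 1, 'same' zero padding, odd kernel length."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        if k % 2 == 0:
            raise ValueError("kernel length must be odd for 'same' padding")
        std = np.sqrt(2.0 / (k * c_in))  # He initialization (ReLU follows)
        self.w = Param(rng.normal(0.0, std, size=(k, c_in, c_out)), "conv_w")
        self.b = Param(np.zeros(c_out), "conv_b")
        self.k = k

    def forward(self, x, training=False):
        p = self.k // 2
        if x.shape[1] < self.k:
            raise ValueError("input shorter than the convolution kernel")
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        self._win = sliding_window_view(xp, self.k, axis=1)  # (N, L, C, k)
        return np.einsum("nlck,kcf->nlf", self._win, self.w.value,
                         optimize=True) + self.b.value

    def backward(self, dy):
        p = self.k // 2
        self.b.grad += dy.sum(axis=(0, 1))
        self.w.grad += np.einsum("nlck,nlf->kcf", self._win, dy, optimize=True)
        dyp = np.pad(dy, ((0, 0), (p, p), (0, 0)))
        dywin = sliding_window_view(dyp, self.k, axis=1)  # (N, L, F, k)
        wflip = self.w.value[::-1]  # (k, C, F) reversed along k
        return np.einsum("nlfk,kcf->nlc", dywin, wflip, optimize=True)

    def params(self):
        return [self.w, self.b]

    def out_shape(self, shape):
        return (shape[0], self.w.value.shape[2])


class BatchNorm(Layer):
    """Batch normalization over all axes but the last (channel) axis."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(c), "bn_gamma")
        self.beta = Param(np.zeros(c), "bn_beta")
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mu, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        self._m = int(np.prod([x.shape[a] for a in axes]))
        self._training = training
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dy):
        axes = tuple(range(dy.ndim - 1))
        self.gamma.grad += (dy * self._xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * self.gamma.value
        if not self._training:
            return dxhat / self._std
        m = self._m
        return (dxhat - dxhat.mean(axis=axes)
                - self._xhat * (dxhat * self._xhat).mean(axis=axes)) / self._std

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return ["running_mean", "running_var"]

    def get_buffers(self):
        return [self.running_mean, self.running_var]

    def set_buffers(self, values):
        self.running_mean, self.running_var = [v.copy() for v in values]


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool1D(Layer):
    """Pool size 2, stride 2; an odd trailing sample is dropped."""

    def forward(self, x, training=False):
        n, length, c = x.shape
        lo = length // 2
        xr = x[:, : 2 * lo].reshape(n, lo, 2, c)
        self._arg = xr.argmax(axis=2)  # (N, Lo, C) in {0, 1}
        self._in_shape = x.shape
        return xr.max(axis=2)

    def backward(self, dy):
        n, lo, c = dy.shape
        dxr = np.zeros((n, lo, 2, c))
        np.put_along_axis(dxr, self._arg[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros(self._in_shape)
        dx[:, : 2 * lo] = dxr.reshape(n, 2 * lo, c)
        return dx

    def out_shape(self, shape):
        return (shape[0] // 2, shape[1])


class GlobalAvgPool1D(Layer):
    def forward(self, x, training=False):
        self._length = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy):
        return np.repeat(dy[:, None, :], self._length, axis=1) / self._length

    def out_shape(self, shape):
        return (shape[1],)


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / d_in)
        self.w = Param(rng.normal(0.0, std, size=(d_in, d_out)), "dense_w")
        self.b = Param(np.zeros(d_out), "dense_b")

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T

    def params(self):
        return [self.w, self.b]

    def out_shape(self, shape):
        return (self.w.value.shape[1],)


class _LSTMCellWeights:
    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        s_x = np.sqrt(1.0 / d_in)
        s_h = np.sqrt(1.0 / hidden)
        self.wx = Param(rng.uniform(-s_x, s_x, size=(d_in, 4 * hidden)), "lstm_wx")
        self.wh = Param(rng.uniform(-s_h, s_h, size=(hidden, 4 * hidden)), "lstm_wh")
        b = np.zeros(4 * hidden)
        b[hidden: 2 * hidden] = 1.0  # forget-gate bias
        self.b = Param(b, "lstm_b")
        self.hidden = hidden


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class _LSTMDirection:
    """One direction of an LSTM over (N, T, D) sequences."""

    def __init__(self, d_in, hidden, rng):
        self.w = _LSTMCellWeights(d_in, hidden, rng)

    def forward(self, x):
        n, t, _ = x.shape
        h = self.w.hidden
        self._x = x
        self._cache = []
        hs = np.zeros((n, t, h))
        h_t = np.zeros((n, h))
        c_t = np.zeros((n, h))
        for step in range(t):
            z = x[:, step] @ self.w.wx.value + h_t @ self.w.wh.value + self.w.b.value
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h: 2 * h])
            g = np.tanh(z[:, 2 * h: 3 * h])
            o = _sigmoid(z[:, 3 * h:])
            c_new = f * c_t + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            self._cache.append((h_t, c_t, i, f, g, o, c_new, tanh_c))
            h_t, c_t = h_new, c_new
            hs[:, step] = h_new
        return hs

    def backward(self, dhs):
        x = self._x
        n, t, _ = x.shape
        h = self.w.hidden
        dx = np.zeros_like(x)
        dh_next = np.zeros((n, h))
        dc_next = np.zeros((n, h))
        for step in range(t - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, c_new, tanh_c = self._cache[step]
            dh = dhs[:, step] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g**2), do * o * (1 - o)], axis=1
            )
            self.w.wx.grad += x[:, step].T @ dz
            self.w.wh.grad += h_prev.T @ dz
            self.w.b.grad += dz.sum(axis=0)
            dx[:, step] = dz @ self.w.wx.value.T
            dh_next = dz @ self.w.wh.value.T
            dc_next = dc * f
        return dx

    def params(self):
        return [self.w.wx, self.w.wh, self.w.b]


class BiLSTM(Layer):
    """Bidirectional LSTM; output is the forward/backward concatenation.

    With ``return_sequences`` the output is ``(N, T, 2*cells)``; otherwise the
    final states of both directions are concatenated into ``(N, 2*cells)``.
    """

    def __init__(self, d_in: int, cells: int, rng: np.random.Generator,
                 return_sequences: bool = True):
        self.fwd = _LSTMDirection(d_in, cells, rng)
        self.bwd = _LSTMDirection(d_in, cells, rng)
        self.cells = cells
        self.return_sequences = return_sequences

    def forward(self, x, training=False):
        self._t = x.shape[1]
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(x[:, ::-1])
        if self.return_sequences:
            return np.concatenate([hf, hb[:, ::-1]], axis=2)
        return np.concatenate([hf[:, -1], hb[:, -1]], axis=1)

    def backward(self, dy):
        h = self.cells
        if self.return_sequences:
            dhf = dy[:, :, :h]
            dhb = dy[:, ::-1, h:]
        else:
            n = dy.shape[0]
            dhf = np.zeros((n, self._t, h))
            dhf[:, -1] = dy[:, :h]
            dhb = np.zeros((n, self._t, h))
            dhb[:, -1] = dy[:, h:]
        dx = self.fwd.backward(dhf)
        dx += self.bwd.backward(dhb)[:, ::-1]
        return dx

    def params(self):
        return self.fwd.params() + self.bwd.params()

    def out_shape(self, shape):
        if self.return_sequences:
            return (shape[0], 2 * self.cells)
        return (2 * self.cells,)


class Sequential(Layer):
    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def stateful_layers(self):
        return [l for l in self.layers if hasattr(l, "get_buffers")]

    def out_shape(self, shape):
        for layer in self.layers:
            shape = layer.out_shape(shape)
        return shape


def layer_shapes(seq: Sequential, input_shape: tuple) -> list:
    """(layer class name, output shape) for each layer, for architecture audits."""
    shapes = []
    shape = input_shape
    for layer in seq.layers:
        shape = layer.out_shape(shape)
        shapes.append((type(layer).__name__, shape))
    return shapes


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray, y: np.ndarray, class_w: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Class-weighted softmax cross-entropy; returns (loss, dlogits).

    The loss is the weight-normalized mean ``-sum_i w_{y_i} log p_{i,y_i} /
    sum_i w_{y_i}``, so for uniform predictions it equals ``ln(K)``
    regardless of the class weights.
    """
    n, k = logits.shape
    p = softmax(logits)
    w = np.ones(n) if class_w is None else np.asarray(class_w)[y]
    logp = np.log(np.clip(p[np.arange(n), y], 1e-300, None))
    wsum = w.sum()
    loss = float(-(w * logp).sum() / wsum)
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits *= (w / wsum)[:, None]
    return loss, dlogits


class Adam:
    def __init__(self, params: list, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
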