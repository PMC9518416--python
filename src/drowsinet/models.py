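"""Drowsiness classifiers: parallel-branch CNN and hybrid CNN-BiLSTM.

Both models share the same per-channel feature extractor: a stack of six 1-D
convolutions (filter schedule F, F, 2F, 2F, 4F, 4F with base F = 64 and
kernel length 5), each followed by batch normalization and ReLU, with a
pool-2 max-pooling after each pair of the first four convolutions and a
global average pooling + dropout after the last, yielding one 4F-vector per
input channel (HRV tachogram, banded HRV spectrum, respiration rate).

The CNN model concatenates the branch vectors and classifies through dense
layers of size 4F and 2F.  The hybrid model instead treats the branch
vectors as a length-``n_channels`` sequence, runs it through two
bidirectional LSTM layers (4F and 2F cells) and classifies through dense
layers of size 2F and F.  Training uses class-weighted cross-entropy, Adam,
and early stopping on a validation split of the training data.

The classifiers follow the scikit-learn estimator contract
(``fit`` / ``predict`` / ``predict_proba``, ``get_params``, fitted
attributes with trailing underscores).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError

from . import nn
from .dataset import class_weights as compute_class_weights

__all__ = [
    "build_cnn_branch",
    "build_model",
    "ParallelNetwork",
    "CNNClassifier",
    "CNNBiLSTMClassifier",
    "branch_shapes",
    "parameter_count",
    "DEFAULT_CHANNELS",
]

DEFAULT_CHANNELS = ("hrv", "hrv_psd", "rr")


def build_cnn_branch(
    base_filters: int = 64,
    kernel_len: int = 5,
    dropout_rate: float = 0.5,
    rng: np.random.Generator | None = None,
) -> nn.Sequential:
    """One per-channel CNN feature extractor ending in a 4F-vector."""
    rng = rng or np.random.default_rng(0)
    f = base_filters
    layers: list[nn.Layer] = []
    c_in = 1
    for block, filters in enumerate((f, 2 * f, 4 * f)):
        for _ in range(2):
            layers.append(nn.Conv1D(c_in, filters, kernel_len, rng))
            layers.append(nn.BatchNorm(filters))
            layers.append(nn.ReLU())
            c_in = filters
        if block < 2:
            layers.append(nn.MaxPool1D())
    layers.append(nn.GlobalAvgPool1D())
    layers.append(nn.Dropout(dropout_rate, rng))
    return nn.Sequential(layers)


class ParallelNetwork:
    """Parallel per-channel CNN branches with a CNN or CNN-BiLSTM head."""

    def __init__(self, channels: tuple, n_classes: int, model_type: str,
                 base_filters: int = 64, kernel_len: int = 5,
                 dropout_rate: float = 0.5, seed: int = 0):
        if not channels:
            raise ValueError("need at least one input channel")
        if model_type not in ("cnn", "cnn_lstm"):
            raise ValueError(f"unknown model type {model_type!r}")
        rng = np.random.default_rng(seed)
        f = base_filters
        self.channels = tuple(channels)
        self.n_classes = n_classes
        self.model_type = model_type
        self.base_filters = f
        self.branches = {
            c: build_cnn_branch(f, kernel_len, dropout_rate, rng)
            for c in self.channels
        }
        n_b = len(self.channels)
        if model_type == "cnn":
            head_layers = [
                nn.Dense(4 * f * n_b, 4 * f, rng), nn.ReLU(),
                nn.Dense(4 * f, 2 * f, rng), nn.ReLU(),
                nn.Dense(2 * f, n_classes, rng),
            ]
        else:
            head_layers = [
                nn.BiLSTM(4 * f, 4 * f, rng, return_sequences=True),
                nn.BiLSTM(8 * f, 2 * f, rng, return_sequences=False),
                nn.Dense(4 * f, 2 * f, rng), nn.ReLU(),
                nn.Dense(2 * f, f, rng), nn.ReLU(),
                nn.Dense(f, n_classes, rng),
            ]
        self.head = nn.Sequential(head_layers)

    def _combine(self, outs: list) -> np.ndarray:
        if self.model_type == "cnn":
            return np.concatenate(outs, axis=1)
        return np.stack(outs, axis=1)  # (N, n_channels, 4F) sequence

    def forward(self, xs: dict, training: bool = False) -> np.ndarray:
        outs = [
            self.branches[c].forward(xs[c][:, :, None], training=training)
            for c in self.channels
        ]
        self._branch_dim = outs[0].shape[1]
        return self.head.forward(self._combine(outs), training=training)

    def backward(self, dlogits: np.ndarray) -> None:
        dcomb = self.head.backward(dlogits)
        d = self._branch_dim
        for i, c in enumerate(self.channels):
            if self.model_type == "cnn":
                dbranch = dcomb[:, i * d:(i + 1) * d]
            else:
                dbranch = dcomb[:, i, :]
            self.branches[c].backward(dbranch)

    def params(self) -> list:
        out = []
        for c in self.channels:
            out.extend(self.branches[c].params())
        out.extend(self.head.params())
        return out

    def _stateful_layers(self) -> list:
        out = []
        for c in self.channels:
            out.extend(self.branches[c].stateful_layers())
        out.extend(self.head.stateful_layers())
        return out

    def state(self) -> dict:
        """Snapshot of all weights and batch-norm running statistics."""
        return {
            "params": [p.value.copy() for p in self.params()],
            "buffers": [[b.copy() for b in l.get_buffers()]
                        for l in self._stateful_layers()],
        }

    def load_state(self, state: dict) -> None:
        for p, v in zip(self.params(), state["params"]):
            p.value[...] = v
        for layer, bufs in zip(self._stateful_layers(), state["buffers"]):
            layer.set_buffers(bufs)


def build_model(
    channels: tuple = DEFAULT_CHANNELS,
    n_classes: int = 3,
    model_type: str = "cnn",
    **kw,
) -> ParallelNetwork:
    """Construct an untrained network (functional alias for the estimators)."""
    return ParallelNetwork(channels, n_classes, model_type, **kw)


def branch_shapes(branch: nn.Sequential, input_len: int) -> list:
    """Per-layer output shapes of a branch for one input of length ``input_len``."""
    return nn.layer_shapes(branch, (input_len, 1))


def parameter_count(net: ParallelNetwork) -> int:
    return sum(p.value.size for p in net.params())


class _BaseNetClassifier(BaseEstimator, ClassifierMixin):
    """Shared scikit-learn estimator machinery for both model types."""

    _model_type = ""

    def __init__(self, channels=DEFAULT_CHANNELS, base_filters=64, kernel_len=5,
                 dropout_rate=0.5, batch_size=64, learning_rate=1e-4,
                 max_epochs=300, patience=20, val_fraction=0.1,
                 class_weight="balanced", random_state=0):
        self.channels = channels
        self.base_filters = base_filters
        self.kernel_len = kernel_len
        self.dropout_rate = dropout_rate
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.class_weight = class_weight
        self.random_state = random_state

    # -- data handling -----------------------------------------------------

    def _as_channel_dict(self, X) -> dict:
        if isinstance(X, dict):
            xs = {c: np.asarray(X[c], dtype=float) for c in self.channels}
        elif len(self.channels) == 1:
            xs = {self.channels[0]: np.asarray(X, dtype=float)}
        else:
            raise ValueError(
                "X must be a dict of channel -> (n_epochs, length) arrays "
                f"covering channels {self.channels}"
            )
        sizes = {x.shape[0] for x in xs.values()}
        if len(sizes) != 1:
            raise ValueError("all channels must have the same number of epochs")
        for c, x in xs.items():
            if x.ndim != 2:
                raise ValueError(f"channel {c!r} must be 2-D (epochs x length)")
            if not np.all(np.isfinite(x)):
                raise ValueError(f"channel {c!r} contains non-finite values")
        return xs

    def _check_fitted_channels(self, xs: dict) -> None:
        if not hasattr(self, "network_"):
            raise NotFittedError("call fit before predict")
        for c in self.channels:
            if xs[c].shape[1] != self.channel_lengths_[c]:
                raise ValueError(
                    f"channel {c!r} length {xs[c].shape[1]} does not match "
                    f"training length {self.channel_lengths_[c]}"
                )

    # -- training ----------------------------------------------------------

    def fit(self, X, y):
        xs = self._as_channel_dict(X)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n_classes = self.classes_.size
        if n_classes < 2:
            raise ValueError("need at least two classes")
        n = y_idx.size
        rng = np.random.default_rng(self.random_state)
        self.channel_lengths_ = {c: xs[c].shape[1] for c in self.channels}

        self.network_ = ParallelNetwork(
            tuple(self.channels), n_classes, self._model_type,
            base_filters=self.base_filters, kernel_len=self.kernel_len,
            dropout_rate=self.dropout_rate, seed=int(rng.integers(2**31)),
        )
        if self.class_weight == "balanced":
            cw = compute_class_weights(y_idx, n_classes)
        elif self.class_weight is None:
            cw = np.ones(n_classes)
        else:
            cw = np.asarray([self.class_weight[c] for c in self.classes_], dtype=float)
        self.class_weight_ = cw

        # stratified validation split for early stopping (never the test fold)
        val_mask = np.zeros(n, dtype=bool)
        if self.val_fraction > 0:
            for cls in range(n_classes):
                idx = np.nonzero(y_idx == cls)[0]
                rng.shuffle(idx)
                n_val = max(int(round(self.val_fraction * idx.size)), 1)
                val_mask[idx[:n_val]] = True
        train_idx = np.nonzero(~val_mask)[0]
        val_idx = np.nonzero(val_mask)[0]

        opt = nn.Adam(self.network_.params(), lr=self.learning_rate)
        self.loss_curve_ = []
        self.val_loss_curve_ = []
        best_val = np.inf
        best_state = self.network_.state()
        best_epoch = 0
        wait = 0
        for epoch in range(self.max_epochs):
            order = train_idx.copy()
            rng.shuffle(order)
            losses = []
            for start in range(0, order.size, self.batch_size):
                batch = order[start:start + self.batch_size]
                xb = {c: xs[c][batch] for c in self.channels}
                logits = self.network_.forward(xb, training=True)
                # batch norm keeps renormalizing even exploded weights, so
                # divergence shows up as absurd logit magnitudes, not just NaN
                if not np.isfinite(logits).all() or np.abs(logits).max() > 1e15:
                    raise FloatingPointError(
                        f"training diverged at epoch {epoch}"
                    )
                loss, dlogits = nn.weighted_cross_entropy(logits, y_idx[batch], cw)
                opt.zero_grad()
                self.network_.backward(dlogits)
                opt.step()
                losses.append(loss)
            self.loss_curve_.append(float(np.mean(losses)))
            if val_idx.size:
                val_logits = self._forward_batched(
                    {c: xs[c][val_idx] for c in self.channels}
                )
                val_loss, _ = nn.weighted_cross_entropy(val_logits, y_idx[val_idx], cw)
            else:
                val_loss = self.loss_curve_[-1]
            self.val_loss_curve_.append(float(val_loss))
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_state = self.network_.state()
                best_epoch = epoch
                wait = 0
            else:
                wait += 1
                if wait >= self.patience:
                    break
        self.network_.load_state(best_state)
        self.n_iter_ = len(self.loss_curve_)
        self.best_epoch_ = best_epoch
        self.best_val_loss_ = float(best_val)
        return self

    def _forward_batched(self, xs: dict, batch: int = 256) -> np.ndarray:
        n = next(iter(xs.values())).shape[0]
        out = []
        for start in range(0, n, batch):
            xb = {c: xs[c][start:start + batch] for c in self.channels}
            out.append(self.network_.forward(xb, training=False))
        return np.concatenate(out, axis=0)

    # -- inference ---------------------------------------------------------

    def predict_proba(self, X) -> np.ndarray:
        xs = self._as_channel_dict(X)
        self._check_fitted_channels(xs)
        return nn.softmax(self._forward_batched(xs))

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class CNNClassifier(_BaseNetClassifier):
    """Parallel-branch CNN with dense head (sizes 4F and 2F)."""

    _model_type = "cnn"


class CNNBiLSTMClassifier(_BaseNetClassifier):
    """Hybrid model: CNN branches feeding two BiLSTM layers then dense head.

    The branch outputs form a length-``n_channels`` sequence of 4F-vectors;
    the BiLSTMs have 4F and 2F cells, the dense layers 2F and F units.
    Default batch size 32 (the smaller batch the hybrid model trains with).
    """

    _model_type = "cnn_lstm"

    def __init__(self, channels=DEFAULT_CHANNELS, base_filters=64, kernel_len=5,
                 dropout_rate=0.5, batch_size=32, learning_rate=1e-4,
                 max_epochs=300, patience=20, val_fraction=0.1,
                 class_weight="balanced", random_state=0):
        super().__init__(
            channels=channels, base_filters=base_filters, kernel_len=kernel_len,
            dropout_rate=dropout_rate, batch_size=batch_size,
            learning_rate=learning_rate, max_epochs=max_epochs,
            patience=patience, val_fraction=val_fraction,
            class_weight=class_weight, random_state=random_state,
        )
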