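"""Cross-validated evaluation: confusion matrices and macro metrics.

Metrics follow the one-vs-rest multi-class convention: per-class sensitivity
TP/(TP+FN), specificity TN/(TN+FP) and precision TP/(TP+FP), with the
reported scalars being their unweighted (macro) means; accuracy is the trace
of the raw confusion matrix over the total count.  Per-class values with a
zero denominator are excluded from the macro mean and flagged.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .containers import EpochDataset
from .dataset import make_folds, normalize_dataset
from .models import CNNBiLSTMClassifier, CNNClassifier, DEFAULT_CHANNELS

__all__ = [
    "confusion_matrix",
    "multiclass_metrics",
    "crossval_evaluate",
    "all_input_combinations",
]


def confusion_matrix(y_true, y_pred, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Raw and row-normalized K x K confusion matrices.

    Entry (i, j) counts epochs with true class i predicted as j.  Rows with
    no true examples are left as zeros in the normalized matrix.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size and (y_true.min() < 0 or y_true.max() >= k
                        or y_pred.min() < 0 or y_pred.max() >= k):
        raise ValueError(f"labels must lie in 0..{k - 1}")
    raw = _sk_confusion(y_true, y_pred, labels=np.arange(k))
    row_sums = raw.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(row_sums > 0, raw / row_sums, 0.0)
    return raw, norm


def multiclass_metrics(raw_confusion: np.ndarray) -> dict:
    """Accuracy and macro one-vs-rest sensitivity/specificity/precision."""
    cm = np.asarray(raw_confusion, dtype=float)
    k = cm.shape[0]
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = total - tp - fn - fp

    def safe_ratio(num, den):
        out = np.full(k, np.nan)
        ok = den > 0
        out[ok] = num[ok] / den[ok]
        return out

    sens = safe_ratio(tp, tp + fn)
    spec = safe_ratio(tn, tn + fp)
    prec = safe_ratio(tp, tp + fp)
    return {
        "accuracy": float(tp.sum() / total),
        "sensitivity": float(np.nanmean(sens)),
        "specificity": float(np.nanmean(spec)),
        "precision": float(np.nanmean(prec)),
        "per_class_sensitivity": sens,
        "per_class_specificity": spec,
        "per_class_precision": prec,
        "undefined_classes": np.nonzero(np.isnan(sens) | np.isnan(prec))[0].tolist(),
    }


def all_input_combinations(channels: tuple = DEFAULT_CHANNELS) -> list:
    """All non-empty channel subsets (7 for the three standard inputs)."""
    combos = []
    for r in range(1, len(channels) + 1):
        combos.extend(itertools.combinations(channels, r))
    return combos


_MODEL_CLASSES = {"cnn": CNNClassifier, "cnn_lstm": CNNBiLSTMClassifier}


def crossval_evaluate(
    dataset: EpochDataset,
    model_types: tuple = ("cnn", "cnn_lstm"),
    input_combos: list | None = None,
    granularities: tuple = (3, 5),
    n_folds: int = 5,
    seed: int = 0,
    group_by_subject: bool = False,
    estimator_kw: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Rotate each fold through the test role for every configuration.

    For each (model type x input combination x label granularity), trains on
    the other folds (normalization statistics fit on training epochs only),
    tests on the held-out fold, and averages the four metrics across folds.
    Returns the results table plus the summed raw confusion matrix per
    configuration.  A failing fold is recorded in the table rather than
    aborting the run.
    """
    estimator_kw = dict(estimator_kw or {})
    input_combos = input_combos or all_input_combinations()
    rows = []
    confusions: dict = {}
    for granularity in granularities:
        y = dataset.labels(granularity)
        groups = (np.array([e.subject_id for e in dataset.epochs])
                  if group_by_subject else None)
        folds = make_folds(y, k=n_folds, seed=seed, groups=groups)
        for model_type in model_types:
            for combo in input_combos:
                key = (model_type, "+".join(combo), granularity)
                fold_metrics = []
                cm_sum = np.zeros((granularity, granularity), dtype=int)
                failure = None
                for f in range(n_folds):
                    train_mask = folds != f
                    try:
                        normalized, _, _ = normalize_dataset(
                            dataset, train_mask, channels=combo
                        )
                        cls = _MODEL_CLASSES[model_type]
                        est = cls(channels=combo,
                                  random_state=seed + 1000 * f, **estimator_kw)
                        xtr = {c: normalized[c][train_mask] for c in combo}
                        xte = {c: normalized[c][~train_mask] for c in combo}
                        est.fit(xtr, y[train_mask])
                        y_pred = est.predict(xte)
                        raw, _ = confusion_matrix(y[~train_mask], y_pred, granularity)
                        cm_sum += raw
                        fold_metrics.append(multiclass_metrics(raw))
                    except Exception as exc:  # record, keep the table partial
                        failure = f"fold {f}: {exc}"
                        break
                row = {"model": model_type, "inputs": "+".join(combo),
                       "n_levels": granularity, "n_folds_done": len(fold_metrics),
                       "failure": failure}
                for m in ("accuracy", "sensitivity", "specificity", "precision"):
                    vals = [fm[m] for fm in fold_metrics]
                    row[m] = float(np.mean(vals)) if vals else np.nan
                rows.append(row)
                confusions[key] = cm_sum
    return pd.DataFrame(rows), confusions
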