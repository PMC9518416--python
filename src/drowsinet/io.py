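"""On-disk formats: delimited-text signals, TIFF stacks, dataset archives."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .containers import ECGRecord, Epoch, EpochDataset, ThermalSequence

__all__ = [
    "read_ecg_csv",
    "read_labels_csv",
    "read_thermal_tiff",
    "save_dataset",
    "load_dataset",
]


def read_ecg_csv(path: str | Path) -> ECGRecord:
    """Two-column delimited text (time_s, mv) with a header row."""
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    t, mv = data[:, 0], data[:, 1]
    fs = 1.0 / np.median(np.diff(t))
    return ECGRecord(samples=mv, fs_hz=float(np.round(fs, 6)), start_time_s=float(t[0]))


def read_labels_csv(path: str | Path) -> np.ndarray:
    """(segment_start_s, ord_score) rows."""
    return np.atleast_2d(np.loadtxt(path, delimiter=",", skiprows=1))


def read_thermal_tiff(path: str | Path, frame_rate_hz: float = 7.5) -> ThermalSequence:
    return ThermalSequence(frames=tifffile.imread(path), frame_rate_hz=frame_rate_hz)


def save_dataset(dataset: EpochDataset, path: str | Path) -> None:
    """Array archive + JSON sidecar with folds and normalization provenance."""
    path = Path(path)
    arrays = {
        "hrv": dataset.channel_matrix("hrv"),
        "hrv_psd": dataset.channel_matrix("hrv_psd"),
        "rr": dataset.channel_matrix("rr"),
        "label_ord": np.array([e.label_ord for e in dataset.epochs]),
        "label_3": dataset.labels(3),
        "label_5": dataset.labels(5),
        "start_time_s": np.array([e.start_time_s for e in dataset.epochs]),
        "subject_id": np.array([e.subject_id for e in dataset.epochs]),
    }
    if dataset.folds is not None:
        arrays["folds"] = np.asarray(dataset.folds)
    np.savez_compressed(path, **arrays)
    sidecar = {
        "n_epochs": len(dataset),
        "channels": {"hrv": "4 Hz tachogram, ms",
                     "hrv_psd": "0.04-0.4 Hz density, ms^2/Hz",
                     "rr": "1 Hz respiration rate, Hz"},
        "has_folds": dataset.folds is not None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_dataset(path: str | Path) -> EpochDataset:
    with np.load(path, allow_pickle=False) as z:
        n = z["hrv"].shape[0]
        epochs = [
            Epoch(
                hrv=z["hrv"][i], hrv_psd=z["hrv_psd"][i], rr=z["rr"][i],
                label_ord=float(z["label_ord"][i]),
                label_3=int(z["label_3"][i]), label_5=int(z["label_5"][i]),
                subject_id=str(z["subject_id"][i]),
                start_time_s=float(z["start_time_s"][i]),
            )
            for i in range(n)
        ]
        folds = z["folds"] if "folds" in z.files else None
    ds = EpochDataset(epochs=epochs)
    ds.folds = folds
    return ds
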