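# drowsinet

Multi-level driver-drowsiness staging from simultaneously recorded
cardiorespiratory signals: single-channel ECG and thermal face video.

Drowsiness at the wheel progresses through stages, and a warning system that
only distinguishes "awake" from "asleep" tends to fire too late.  Two
autonomic signatures track that progression non-intrusively: the
low-frequency to high-frequency power ratio of heart-rate variability
(LF/HF, 0.04–0.15 Hz vs 0.15–0.4 Hz) falls as drowsiness deepens, and the
respiration rate slows.  `drowsinet` implements the full chain from raw
signals to a 3- or 5-level drowsiness classification against observer
ratings of drowsiness (ORD, 1 = wakeful … 5 = extremely drowsy, one score
per driving minute):

* **ECG pipeline** — windowed Grubbs outlier removal, zero-phase 2–40 Hz
  Butterworth band-pass, Pan–Tompkins R-peak detection, the
  30%-of-last-four ectopic-interval rule, cubic-spline resampling of the
  tachogram to 4 Hz, and a Hann-windowed FFT periodogram capped to
  0.04–0.4 Hz on a fixed 128-bin grid.
* **Respiration pipeline** — nostril-region localization from accumulated
  inter-frame thermal changes, spatiotemporal-context (STC) tracking with a
  Fourier-domain context model, per-frame region-mean respiration waveform,
  0.6 Hz low-pass, and instantaneous respiration rate from the
  maximum-energy ridge of a Morlet synchrosqueezing transform, downsampled
  to 1 Hz.
* **Dataset builder** — 2-minute epochs with 60% overlap, duration-weighted
  ORD labels, z-score normalization fit on training epochs only, stratified
  5-fold cross-validation and inverse-frequency class weights
  `w_c = N / (K n_c)`.
* **Classifiers** — per-channel 1-D CNN branches (filter schedule
  64, 64, 128, 128, 256, 256; kernel length 5; batch norm + ReLU; two
  pool-2 max-poolings; global average pooling + dropout) feeding either a
  dense head (256, 128 units) or a hybrid head with two bidirectional LSTM
  layers (256 and 128 cells) and dense layers (128, 64).  Training uses
  class-weighted cross-entropy, Adam, and early stopping on a validation
  split.  The neural network core (forward and backward passes, Adam) is
  implemented in NumPy and gradient-checked against finite differences.
* **Synthetic cohort generator** — the study data this design targets are
  private, so the package ships a generator producing raw ECG, thermal
  breathing video and per-minute ORD labels with analytic ground truth
  (R-peak times, instantaneous respiration rate, region center per frame).

The two classifiers follow the scikit-learn estimator contract
(`fit` / `predict` / `predict_proba`, `get_params`).

## Worked example

```python
import numpy as np
from drowsinet.dataset import build_synthetic_dataset, make_folds, normalize_dataset
from drowsinet.models import CNNBiLSTMClassifier

# 6 synthetic subjects, 480 s sessions walking through ORD levels 1, 3, 5;
# raw ECG (1 kHz, 20 dB SNR) and thermal video are processed end to end
ds = build_synthetic_dataset(6, 480.0, seed=11, levels=(1, 3, 5),
                             ecg_snr_db=20.0)
y = ds.labels(3)
folds = make_folds(y, k=5, seed=1)
train = folds != 0
x, _, _ = normalize_dataset(ds, train)

clf = CNNBiLSTMClassifier(base_filters=16, learning_rate=1e-3,
                          max_epochs=50, patience=8, random_state=1)
clf.fit({c: x[c][train] for c in x}, y[train])
acc = clf.score({c: x[c][~train] for c in x}, y[~train])
print(f"epochs: {len(ds)}, test accuracy: {acc:.3f}")
```

prints

```
epochs: 48, test accuracy: 1.000
```

48 epochs because each 480 s session yields `floor((480-120)/48)+1 = 8`
overlapping 2-minute epochs; the held-out fold is classified perfectly
because the generator's default class separation (mean RR 850→1050 ms,
LF/HF amplitude ratio 4→0.15, respiration 0.30→0.14 Hz across levels) is
deliberately wide.

A command-line interface runs the same stages on on-disk cohorts:

```bash
drowsinet simulate --n-subjects 4 --session-length 480 --seed 0 --out-dir cohort/
drowsinet ecg  --cohort-dir cohort/
drowsinet resp --cohort-dir cohort/
drowsinet build-dataset --cohort-dir cohort/ --out cohort/dataset.npz
drowsinet evaluate --dataset cohort/dataset.npz --out cohort/results.csv
```

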