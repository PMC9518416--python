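# Methods

## Problem and signals

The package stages driver drowsiness on the 5-level observer rating of
drowsiness (ORD) scale, and on a coarsened 3-level scale (ORD < 3 wakeful,
ORD = 3 moderately drowsy, ORD > 3 extremely drowsy), from two autonomic
signals that can be acquired without interfering with driving: heart-rate
variability (HRV) derived from a single-channel ECG, and the respiration
rate extracted from thermal video of the face.  Both carry known
drowsiness signatures: the LF/HF ratio of the HRV spectrum
(LF 0.04–0.15 Hz, HF 0.15–0.4 Hz — the sympathovagal balance index) falls
progressively with drowsiness, and the respiration rate slows.

Three channels feed the classifiers per 2-minute epoch: the uniformly
resampled tachogram (480 samples at 4 Hz, ms), its band-capped power
spectral density (128 bins over 0.04–0.4 Hz, ms²/Hz), and the
instantaneous respiration rate (120 samples at 1 Hz).

## ECG pipeline

1. **Grubbs outlier removal.**  The iterated two-sided Grubbs test is run
   on non-overlapping 10 s windows at alpha = 0.05; flagged samples are
   replaced by linear interpolation.  The test assumes approximately
   stationary normal data, which holds locally but not across a whole
   drive — hence the windowing.  At most 1% of a window may be removed:
   raw ECG is heavy-tailed by construction (QRS spikes), and an uncapped
   iteration would keep eating the signal itself rather than artifacts.
2. **Band-pass.**  "Fourth-order Butterworth band-pass, 2–40 Hz" is
   realized as a design order of 2 per band edge (effective band-pass
   order 4), applied forward–backward (`sosfiltfilt`) so the phase is zero
   and R-peak timing is preserved.
3. **Pan–Tompkins.**  Classic stages: 5-point derivative, squaring, 150 ms
   moving-window integration, adaptive signal/noise thresholds with a
   200 ms refractory period, search-back at 1.66x the running RR estimate,
   and refinement of each fiducial to the local maximum of the filtered
   trace within +-50 ms.  These constants are the canonical published ones.
4. **Ectopic rule.**  Scanning in time order, an interval deviating more
   than 30% from the mean of the four most recent non-flagged intervals is
   masked; the first four intervals are never flagged.  Masked beats are
   excluded from the spline support rather than deleted.
5. **Resampling.**  Cubic-spline interpolation of (beat time, interval)
   onto a uniform 4 Hz grid.  4 Hz is the standard HRV choice: comfortably
   Nyquist-safe for the 0.4 Hz band edge while keeping epochs short.
6. **Spectrum.**  Mean-detrended, Hann-windowed periodogram zero-padded to
   4096 points, scaled as a one-sided density whose integral over frequency
   equals the windowed variance (the tests assert this Parseval identity to
   5%).  The density is then interpolated onto a fixed 128-point grid over
   0.04–0.4 Hz so every epoch produces an identical-length vector.  The
   spectrum is computed per epoch (the only reading compatible with
   fixed-length network inputs).

## Respiration pipeline

1. **Localization.**  Nostril airflow makes the nostril region the most
   temporally active area of the video.  Absolute inter-frame differences
   are accumulated over the first 40 frames (~5 s at 7.5 fps), smoothed
   (Gaussian, sigma 1.5 px), thresholded at the 0.99 activity quantile, and
   the largest 8-connected component is grown to all connected pixels at
   least half as active as the component mean.  The growing step matters
   because a high quantile necessarily selects fewer pixels than the true
   region when the region exceeds 1% of the frame.
2. **Tracking.**  The spatiotemporal-context tracker learns, per frame, a
   spatial model `h` relating a Gaussian-decaying target confidence map to
   the Gaussian-weighted intensity context, by elementwise division in the
   Fourier domain (regularized).  The model is updated temporally as
   `H <- (1-rho) H + rho h` with rho = 0.075, and the next position is the
   argmax of the correlation of `H` with the new frame's context.  Context
   window 2.5x the box, confidence-map decay length 0.25 of the box
   diagonal.  If the peak confidence falls below 5% of its running
   reference, the position is held and the frame flagged.
3. **Waveform.**  Per-frame arithmetic mean of the pixels in the tracked
   box; Grubbs-cleaned; low-passed with a zero-phase 4th-order Butterworth
   at 0.6 Hz.
4. **Instantaneous rate.**  Analytic Morlet CWT (center frequency 6 rad/s,
   32 voices per octave over 0.05–1 Hz), synchrosqueezed by reassigning
   each coefficient's energy to its phase-derivative instantaneous
   frequency on a 512-bin linear grid, then a dynamic-programming
   maximum-energy ridge with a quadratic frequency-jump penalty
   (transitions limited to +-10 bins per frame) and sub-bin refinement by
   an energy-weighted centroid over +-2 bins.  The ridge is sampled at
   integer seconds (1 Hz); the first and last 5 s are marked low-quality
   because of wavelet edge effects.  The rate estimate is invariant to
   affine intensity rescaling of the video.

## Dataset construction

Epochs are 120 s with 60% overlap (hop 48 s); a session of length `T`
yields `floor((T-120)/48)+1` epochs.  Each epoch's ORD is the
duration-weighted mean of the 1-minute scores it spans.  Fractional means
within +-0.25 of 3 map to "moderately drowsy"; the 5-level label rounds
half-up, i.e. toward greater drowsiness (the safety-conservative
direction).  Normalization is z-scoring per channel and feature position
with statistics from training epochs only (zero-variance positions clamp
their SD to 1 and are flagged).  Cross-validation is stratified 5-fold at
the epoch level — matching the stated 80/20 procedure — with an optional
subject-grouped mode, provided because epoch-level splits of overlapping
epochs leak subject identity between train and test; results obtained with
the default split should be read with that caveat.  Class weights are
inverse-frequency, `w_c = N/(K n_c)`, so `sum_c w_c n_c = N`.

## Classifiers

Each input channel has its own CNN branch: six 1-D convolutions (kernel
length 5, stride 1, 'same' padding; filters F, F, 2F, 2F, 4F, 4F with
F = 64), each followed by batch normalization and ReLU, max-pooling
(size 2, stride 2) after each of the first two convolution pairs, then
global average pooling and dropout (rate 0.5), producing one 4F-vector per
channel.  'Same' padding keeps the six-layer stack valid for the shortest
input (120 samples).

*CNN model*: branch vectors concatenated (768 wide for three channels) →
dense 256 → dense 128 → softmax.  *Hybrid model*: the branch vectors form
a length-`n_channels` sequence fed to two bidirectional LSTM layers (256
and 128 cells; the second returns its final states, 256 wide) → dense 128
→ dense 64 → softmax.  Treating the branch outputs as a sequence is the
design choice for connecting a flat concatenation to a recurrent block; it
gives the BiLSTM a temporal axis over input modalities.

Training: class-weighted softmax cross-entropy, Adam (learning rate 1e-4
by default, batch 64 for the CNN and 32 for the hybrid model), up to 300
epochs with early stopping (patience 20) on a stratified 10% validation
split of the training fold — never the test fold.  The checkpoint with the
lowest validation loss is restored, *including* the batch-norm running
statistics: restoring weights without their matching statistics makes
eval-mode inference inconsistent and can collapse whole classes.

The layers (convolution, batch norm, pooling, dropout, dense, BiLSTM) and
Adam are implemented directly in NumPy; the test suite checks every
gradient path against central finite differences and audits all layer
shapes against hand propagation.

## Synthetic cohort generator

The generator emulates the statistical structure the classifiers rely on,
with closed-form ground truth for every pipeline oracle:

* RR intervals: `RR_n = mean_rr(level) + lf_amp sin(2 pi 0.1 t_n) +
  hf_amp sin(2 pi 0.25 t_n) + N(0, noise_sd^2)`, beat times by cumulative
  summation.  0.1 and 0.25 Hz are the mid-points of the LF and HF bands,
  so band assignment is unambiguous.
* ECG: a fixed P-QRS-T template (five Gaussians; the R Gaussian dominates,
  so the template maximum is analytically at the beat time) placed at each
  beat, with optional baseline wander, powerline, broadband noise at a
  specified SNR, and sparse outlier spikes.
* Thermal video: constant background plus pixel noise and a rectangular
  nostril patch whose mean intensity oscillates sinusoidally with
  instantaneous frequency equal to the level's respiration rate; the patch
  center can drift linearly or sway sinusoidally to exercise the tracker.
* Labels: one ORD score per minute from the level schedule.

Per-level defaults (mean RR 850, 900, 950, 1000, 1050 ms; LF amplitude 40,
30, 20, 12, 6 ms; HF amplitude 10, 15, 22, 30, 40 ms; respiration 0.30,
0.26, 0.22, 0.18, 0.14 Hz for levels 1–5) encode the physiological effect
directions — LF/HF falling, breathing slowing, heart rate slowing — with
magnitudes chosen once to give clearly separable classes, since no
population effect sizes per ORD level are established.  One cohort seed
streams per-subject sub-seeds, so a fixed seed reproduces a cohort
bit-identically.

What the generator does **not** emulate: realistic ECG morphology
variation or pathology, respiratory amplitude modulation, head pose and
occlusion, camera physics, inter-subject overlap of class distributions,
or label noise from disagreeing observers.  Classification results on
synthetic cohorts therefore verify the machinery (pipelines, training,
evaluation), not field performance: with the default separation both
models reach ~100% on held-out epochs, which no real cohort would yield.

## Verification problem sizes

The end-to-end learning check uses 30 synthetic subjects with 480 s
sessions over levels {1, 3, 5} (240 epochs), a scaled-down model
(base filters 16, learning rate 1e-3, at most 50 epochs, patience 8) and
three training seeds per model; signal-level checks use 5-minute ECG
records at 20 dB SNR and 300 s respiration records.  These sizes keep the
full verification run to a few minutes on one CPU while leaving every
pipeline stage at its study-scale defaults (1 kHz ECG, 7.5 fps video,
2-minute epochs).

## Known limitations

* The Grubbs removal cap (1% per window) is a pragmatic guard, not part of
  the canonical test; extremely dense artifact bursts will be only partly
  removed.
* The STC tracker has no scale adaptation; box size is fixed at the
  localization result.
* The ridge extractor assumes a single dominant respiratory component;
  bimodal breathing (e.g. speech) will snap to the stronger branch.
* Epoch-level cross-validation on overlapping epochs is optimistic; use
  the grouped mode for subject-generalization claims.
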