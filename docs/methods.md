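# Methods

`mechanoecg` reconstructs the single-lead ECG waveform from two
electrode-free chest signals: the seismocardiogram (SCG), the micro-vibration
of the chest wall recorded by a tri-axial MEMS accelerometer, and the
phonocardiogram (PCG), the heart-sound audio recorded by a MEMS microphone.
The physiological basis is excitation–contraction coupling: every electrical
activation (P–QRS–T) is followed, at short and fairly stable latencies, by
mechanical events — the S1 sound and the aortic-valve-opening (AO) vibration
near the QRS complex, the S2 sound and aortic closure (AC) near the end of
the T wave.  A sequence model that sees both mechanical channels can
therefore regress the electrical waveform sample by sample.

## SCG preprocessing

The raw accelerometer signal is dominated by the gravity projection
(9.81 m/s², orders of magnitude above the ~0.05 m/s² cardiac vibration) and
by slow respiratory/postural drift.  The chain:

1. **Offset calibration.**  Constant per-axis biases are estimated from a
   static window (≥ 1 s, default the first second) as the difference between
   the static mean and the expected gravity projection.  If the static-mean
   magnitude deviates from g by more than 1% the window was probably not
   static and a warning is logged.
2. **Tilt estimation.**  With the convention that a level, motionless sensor
   reads (0, 0, −g), the gravity projections under roll φ and pitch θ are
   `ax = g sinθ`, `ay = −g sinφ cosθ`, `az = −g cosφ cosθ` (they satisfy
   `ax² + ay² + az² = g²` identically), inverted per sample as
   `θ = asin(ax/g)`, `φ = atan2(−ay, −az)`.  Samples with |ax| > g (dynamic
   bursts) are clipped to the asin domain with a warning; the smoother
   absorbs the spikes.
3. **Kalman smoothing.**  Each angle is filtered independently by a scalar
   random-walk Kalman filter.  Defaults q = 1e−5 rad² (process), r = 1e−2
   rad² (measurement): posture changes over seconds, while the instantaneous
   angles are noisy at every sample because cardiac accelerations masquerade
   as tilt.
4. **Gravity compensation.**  With `R = (Rx(φ) Ry(θ))ᵀ` mapping sensor to
   world coordinates (sign convention fixed by requiring that the static
   reading maps exactly to world (0, 0, −g)), the world gravity vector is
   subtracted and the result rotated back.  Algebraically this reduces to
   subtracting the predicted per-sample gravity projection, which the
   implementation does directly; a static sensor at any tilt compensates to
   zero to machine precision when exact angles are supplied.
5. **Filtering and normalization.**  The dorso-ventral (z) channel — the
   axis that carries the AO/AC wavelets; a vector-magnitude option exists —
   is band-passed 2–50 Hz with a zero-phase FIR (forward–backward linear-
   phase filter, ~1 Hz transitions), high-passed at 0.5 Hz (zero-phase
   Butterworth, order 4) to remove residual baseline wander, resampled to
   250 Hz if needed, and standardized (zero mean, unit variance).  The
   band-pass-then-high-pass order follows the stated experimental protocol
   even though the 0.5 Hz edge is largely redundant below the 2 Hz edge.

## PCG preprocessing

48 kHz WAV audio is band-passed 20–200 Hz (zero-phase Butterworth at the
native rate), resampled to 250 Hz (polyphase with built-in anti-alias
low-pass), rectified (absolute value, which preserves amplitude units),
smoothed by a centred 50 ms moving average, and standardized.  The 50 ms
envelope window sits between one acoustic oscillation (~15 ms) and the
S1–S2 spacing (~300 ms), so the two heart sounds remain resolved as
separate energy bumps.  The model consumes the envelope by default; a
`waveform` mode skips envelope extraction.

## The fusion model

The regressor maps a fused (PCG, SCG) window to an ECG window of the same
length:

* **Early fusion**: the two 250 Hz channels are stacked at the feature
  dimension, giving a (T, 2) input.  A `per_modality` option encodes each
  channel with its own LSTM stack and concatenates the outputs.
* **Encoder**: two stacked bidirectional LSTM layers, 128 hidden units per
  direction, dropout 0.2 after each layer.  Bidirectionality lets a time
  step see both the S1 before and the S2 after it.
* **Projection + positional encoding**: a linear map to d_model = 256 (the
  natural width of the concatenated bidirectional state), plus the standard
  sinusoidal table (even columns sine, odd cosine, geometric wavelengths).
* **Transformer encoder**: four post-norm layers, 8 heads, feed-forward
  width 1024 (4 × d_model), dropout 0.1 after the attention and
  feed-forward sublayers, residual connections and layer normalization
  around both.
* **Decoder**: a time-distributed MLP — 128 ReLU units then a scalar output
  per time step — so output length always equals input length.

Training minimizes MSE with Adam, initial learning rate 1e−3, batch 64, an
80/20 split **at record level** (windows of one recording never appear on
both sides), per-epoch train/validation logging, best-validation checkpoint
restoration, and learning-rate halving after 10 validation-stagnant epochs.
Targets and both input channels are standardized per training window.
All randomness (split, batching, initialization, dropout) flows from the
seed in `TrainConfig`.

The network and its optimizer are implemented on a small reverse-mode
autodiff core (`mechanoecg.nn`) written directly on numpy: a `Tensor` tape
with hand-written fused backward passes for the LSTM sequence, softmax and
layer norm.  Two engineering points matter in practice: backward passes
release the tape (the closures otherwise form reference cycles holding
large activations), and evaluation-mode forwards run under `no_grad()`.
Gradients of every primitive are verified against central differences in
the test suite.

## Evaluation

* **PCC / RMSE** between predicted and reference ECG, computed on the
  pooled (concatenated) windows of each record, with the reference
  standardized per window exactly like the training targets (RMSE is in
  standardized units on simulated data; on mV-calibrated references it is
  in mV).
* **R-peak pipeline**: detection by amplitude threshold (default 0.6 of the
  global max) plus strict local-maximum search within non-overlapping 1 s
  windows, ties to the earliest index.  Reference peaks are paired with the
  predicted local maximum within ±48 ms; reported are the amplitude RMSE,
  the bias as a percentage of the mean reference amplitude, and the SD of
  the paired differences.
* **Aggregation**: records are averaged within subject, then across-subject
  mean ± t-distribution 95% CI half-width (`t_{0.975, n−1}·sd/√n`; n ≥ 2
  required, a single subject yields a point estimate only).
* **Ablation harness**: multimodal, PCG-only and SCG-only models trained on
  identical data, split and seeds, differing only in which input column is
  zeroed.
* **Saliency probe**: gradient magnitude of the predicted QRS region with
  respect to the inputs, averaged over the 100 ms before each R peak versus
  a mid-diastole control span (0.5–0.6 s after R, clear of S2 and the next
  P wave).
* **Cough probe**: reconstruction PCC inside ±0.5 s cough windows versus
  outside, on the same record.

## The simulator

Every test input is generated by the coupled cardiac simulator.  Per beat
(RR intervals lognormal around the configured heart rate, so intervals stay
positive with HRV-like right skew; R times snapped to the 250 Hz grid):

* **ECG**: sum of per-wave Gaussians (P, Q, R, S, T) with physiological
  default amplitudes/offsets/widths; the R Gaussian absorbs the tails of
  the other waves at its centre so the rendered R-peak amplitude equals the
  configured value exactly — a closed-form ground truth for amplitude
  tests.
* **PCG**: S1 and S2 as Gabor bursts (60 / 85 Hz carriers, σ 20 / 15 ms) in
  48 kHz audio at their electromechanical offsets — S1 40 ms after QRS
  onset, S2 10 ms after T end.
* **SCG**: AO and AC Gabor wavelets (25 / 35 Hz, inside the 5–100 Hz SCG
  band; AO 35 ms after R, AC 5 ms before S2) on the dorso-ventral axis.
* **Raw accelerometer**: the clean vibration embedded in a slowly tilting
  sensor frame (mean tilt (0.10, −0.15) rad, ±0.02 rad sway at 0.05 Hz)
  with the gravity projection, constant axis offsets, a 0.25 Hz respiratory
  component, and white noise.
* **Noise asymmetry**: accelerometer noise 0.02 m/s² per axis against
  0.05 m/s² wavelets, audio noise 0.01 against unit S1 — the SCG channel is
  deliberately the noisier modality, which is what makes the modality
  ablation ordering (multimodal ≤ PCG-only ≤ SCG-only in RMSE) a
  non-trivial, directional prediction.
* **Coughs**: 0.3 s Hann-enveloped broadband bursts, ≥ 5 × S1 amplitude,
  added to audio and (scaled) to the accelerometer, logged as events.

What the simulator does **not** emulate: realistic SCG morphology beyond
band-limited wavelets, inter-beat morphology dynamics, pathological
rhythms, motion artifacts other than smooth tilt/respiration, sensor clock
skew, or room acoustics.  Passing tests therefore demonstrate that the
pipeline and model behave correctly and learn the mechano-electrical
timing structure — not that the architecture reaches any particular
accuracy on real patients.

## Study sizes

The default `ModelConfig` carries the full reference architecture.  The
desk-scale studies in the test suite and `scripts/acceptance.py` use the
reduced preset (`presets.study_model_config`): hidden 24 per direction,
d_model 48, two transformer layers, 4 heads, feed-forward 96, 1 s windows
(250 samples), batch 8, learning rate 3e−3; cohorts of 2–20 simulated
subjects at 10–20 s per record.  The simulated mapping has far lower
intrinsic dimensionality than real multi-subject data, and at this size a
full train-plus-ablation study runs in minutes on one CPU while every
architectural component is exercised.  Batch 8 bounds the
O(batch·heads·T²) attention memory.

## Numerical choices and edge cases

* Zero-variance segments raise `StandardizationError` in the signal chains
  (filter chain, envelope), where a constant segment signals a dead sensor
  or a degenerate configuration; training-window
  standardization uses a 1e−8 variance floor instead, since a quiet window
  of a valid record should not abort a training run.
* Alignment snaps series onto a common grid by `t0` with a 2 ms tolerance;
  inferred rates from text timestamps are snapped to the nearest integer
  within 1e−4 relative.
* R-peak detector ties resolve to the earliest index (argmax semantics).
* Angle clipping at |ax| = g; Kalman state initialized at the first
  measurement with variance r.
* Filter attenuation tests measure band power with a Hann-window
  periodogram; a boxcar window leaks tone power into neighbouring bands and
  masks the true attenuation.

## Known limitations

* The waveform-level RMSE on simulated data is in standardized units; the
  mV scale of a real reference ECG is only recovered when the reference is
  supplied in calibrated mV.
* The per-modality fusion variant shares the training protocol but has not
  been tuned; early fusion is the canonical path.
* The saliency probe is directional (pre-R vs mid-diastole), not a
  localization guarantee.
* No pre-training on public heart-sound corpora is included; the training
  entry point accepts any list of aligned records should such data be
  available in the package's file formats.
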