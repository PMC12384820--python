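# mechanoecg

Electrode-free ECG reconstruction from chest-wall vibration and heart
sounds.

Long-term cardiac monitoring with adhesive ECG electrodes irritates the
skin and degrades over days of wear.  `mechanoecg` implements an
alternative: a chest-worn tri-axial accelerometer records the
seismocardiogram (SCG, the micro-vibration of the chest wall), a microphone
records the phonocardiogram (PCG, the S1/S2 heart sounds), and a hybrid
BiLSTM–transformer network regresses the ECG waveform sample by sample from
the fused mechano-acoustic channels.  The physiological basis is
excitation–contraction coupling: S1 and the aortic-opening (AO) vibration
track the QRS complex, S2 and aortic closure (AC) track the end of the T
wave, so the mechanical channels carry the timing and strength of the
underlying electrical events.

The package is aimed at physiological-signal researchers who want a fully
testable, self-contained pipeline: every stage runs on simulated data with
closed-form ground truth, so no recordings are required to develop against
it.

## What is inside

| Module | Role |
|---|---|
| `mechanoecg.signals_io` | WAV / delimited-text readers and writers, reference-ECG conditioning (0.5–40 Hz bandpass, optional mains notch), timestamp alignment and windowing |
| `mechanoecg.scg_preprocess` | offset calibration, roll/pitch tilt estimation `θ = asin(aₓ/g)`, `φ = atan2(−a_y, −a_z)`, per-angle scalar Kalman smoothing, geometric gravity compensation `a* = a − R⁻¹(0,0,−g)ᵀ`, 2–50 Hz zero-phase FIR + 0.5 Hz high-pass, standardization |
| `mechanoecg.pcg_preprocess` | 20–200 Hz bandpass at 48 kHz, polyphase resampling to 250 Hz, rectified 50 ms moving-average envelope, standardization |
| `mechanoecg.fusion_model` | early-fusion BiLSTM (2 × 128/direction) → linear projection → sinusoidal positional encoding → 4-layer transformer encoder → time-distributed MLP decoder; Adam/MSE training with record-level 80/20 split; reconstruction, saliency maps, checkpointing |
| `mechanoecg.evaluation` | PCC, RMSE, R-peak detection and amplitude error, per-subject t-distribution 95% CIs, three-way modality ablation, saliency and cough probes |
| `mechanoecg.cardiac_simulator` | coupled ECG/PCG/SCG generator with per-beat event logs, tilt + gravity + respiration + noise embedding, cough transients, multi-subject cohorts |
| `mechanoecg.nn` | the numpy reverse-mode autodiff core and layers the model is built on |

The quality metrics are the Pearson correlation coefficient and the
root-mean-square error between predicted and reference ECG,

PCC = Σᵢ(xᵢ−x̄)(yᵢ−ȳ) / √(Σᵢ(xᵢ−x̄)² Σᵢ(yᵢ−ȳ)²),  RMSE = √(Σᵢ(xᵢ−x̃ᵢ)²/n),

aggregated across subjects as mean ± t₀.₉₇₅,ₙ₋₁·sd/√n.

## Worked example

Simulate two subjects, preprocess, train a small model, reconstruct and
evaluate — entirely from the shell:

```sh
mechanoecg simulate --out sessions --seed 4 --subjects 2 --duration 10
mechanoecg preprocess --manifest sessions/S01/manifest.txt --out S01.npz --window-len 250
mechanoecg preprocess --manifest sessions/S02/manifest.txt --out S02.npz --window-len 250
mechanoecg train --records S01.npz --records S02.npz --out model.npz --seed 1 --epochs 2 --window-len 250
mechanoecg evaluate --model model.npz --records S01.npz --records S02.npz
```

which prints (two epochs only, so the model has barely started learning):

```
wrote sessions/S01/manifest.txt
wrote sessions/S02/manifest.txt
wrote S01.npz (10 windows of 250)
wrote S02.npz (10 windows of 250)
epoch   0  train 1.51860  val 62.56789  lr 1.00e-03
epoch   1  train 58.54301  val 1.16572  lr 1.00e-03
wrote model.npz (best val MSE 1.16572)
subject_id     rmse       pcc
       S01 1.079009  0.015735
       S02 1.079683 -0.041510
metric      mean  ci95_half_width       sd
  rmse  1.079346         0.004280 0.000476
   pcc -0.012888         0.363685 0.040479
```

`rmse` is in standardized (unit-variance) ECG units; `pcc` is the waveform
correlation; `ci95_half_width` is the across-subject t-distribution 95%
confidence half-width.  A properly trained study-scale model (see
`docs/methods.md`, ~18 epochs on a 6-subject cohort) reaches per-subject
PCC ≈ 0.9 on held-out simulated records with both channels, degrades
mildly when only the PCG envelope is supplied, and sharply when only the
noisy SCG channel is.

The same pipeline is available as library calls
(`cardiac_simulator.make_dataset` → `cardiac_simulator.to_cardiac_record`
→ `fusion_model.train` → `evaluation.evaluate_records` /
`evaluation.run_ablation`).

## Scope

Hardware, firmware, wireless transport and real-time streaming are out of
scope: the package starts at recorded WAV/CSV sessions.  See
`docs/methods.md` for the model details, simulator assumptions, study
sizes, and known limitations.
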