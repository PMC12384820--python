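"""Waveform-fidelity metrics, R-peak analysis and subject-level aggregation.

Reconstruction quality is measured by the Pearson correlation coefficient
(PCC) and the root-mean-square error (RMSE) between predicted and
reference ECG, pooled per record, then aggregated across subjects with
95% confidence intervals from the t distribution.  R-peak amplitude
fidelity is assessed by pairing detected reference peaks with predicted
local maxima and reporting the RMSE, the mean bias as a percentage of the
mean reference amplitude, and the standard deviation of the paired
differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EvaluationError, InputError
from .fusion_model import (ModelConfig, TrainConfig, TrainedModel, reconstruct,
                           train)
from .types import CardiacRecord, UniformSeries

__all__ = ["PeakSet", "EvalReport", "pcc", "rmse", "detect_rpeaks",
           "rpeak_amplitude_error", "aggregate_subjects", "evaluate_records",
           "run_ablation"]


@dataclass
class PeakSet:
    """Detected R peaks: sample indices (strictly increasing, at most one
    per detection window) and amplitudes at those samples."""

    indices: np.ndarray
    amplitudes: np.ndarray
    window_s: float = 1.0

    def __len__(self) -> int:
        return self.indices.size


@dataclass
class EvalReport:
    """Per-record metrics with across-subject aggregation."""

    per_record: pd.DataFrame           # columns: subject_id, rmse, pcc
    aggregate: dict                    # metric -> (mean, ci_half_width, sd)
    rpeak: Optional[dict] = None       # rmse, bias_pct, sd
    modality: str = "multimodal"

    def to_frame(self) -> pd.DataFrame:
        rows = [{"metric": m, "mean": v[0], "ci95_half_width": v[1], "sd": v[2]}
                for m, v in self.aggregate.items()]
        return pd.DataFrame(rows)


def pcc(x, y) -> float:
    """Pearson correlation coefficient between two equal-length signals."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError(f"pcc needs equal-length vectors, got {x.shape}, {y.shape}")
    if x.size < 2:
        raise InputError("pcc needs at least two samples")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc * xc) * np.sum(yc * yc))
    if denom == 0.0:
        raise EvaluationError("pcc undefined for a constant input")
    return float(np.sum(xc * yc) / denom)


def rmse(truth, pred) -> float:
    """Root-mean-square error between ground truth and prediction."""
    truth = np.asarray(truth, dtype=np.float64)
    pred = np.asarray(pred, dtype=np.float64)
    if truth.shape != pred.shape:
        raise InputError(f"length mismatch: {truth.shape} vs {pred.shape}")
    return float(np.sqrt(np.mean((truth - pred) ** 2)))


def detect_rpeaks(ecg: UniformSeries, threshold_frac: float = 0.6,
                  window_s: float = 1.0) -> PeakSet:
    """Amplitude-threshold + local-maximum R-peak detector.

    The series is tiled into non-overlapping windows of ``window_s``.  In
    each window the maximum sample is accepted as a peak iff it exceeds
    ``threshold_frac`` times the global maximum and is a strict local
    maximum of the full series (ties resolve to the earliest index).
    """
    if not (0.0 < threshold_frac < 1.0):
        raise InputError(f"threshold_frac must be in (0, 1), got {threshold_frac}")
    x = ecg.samples
    if x.size == 0:
        raise InputError("empty series")
    n_window = max(int(round(window_s * ecg.fs)), 1)
    threshold = threshold_frac * x.max()
    indices = []
    for start in range(0, x.size, n_window):
        seg = x[start:start + n_window]
        k = start + int(np.argmax(seg))  # argmax -> earliest index on ties
        if x[k] <= threshold:
            continue
        left_ok = k == 0 or x[k] > x[k - 1]
        right_ok = k == x.size - 1 or x[k] > x[k + 1]
        # A tie with the next sample would make this a plateau, not a strict
        # local max; accept the earliest plateau sample only if it still
        # strictly dominates both plateau edges.
        if left_ok and right_ok:
            indices.append(k)
    indices = np.asarray(indices, dtype=int)
    return PeakSet(indices=indices, amplitudes=x[indices], window_s=window_s)


def rpeak_amplitude_error(truth_peaks: PeakSet, pred_ecg: UniformSeries,
                          tolerance: int = 12) -> tuple[float, float, float]:
    """Amplitude agreement of paired R peaks.

    Each reference peak is paired with the local maximum of the predicted
    ECG within ``tolerance`` samples (default 12 = 48 ms at 250 Hz).  A
    reference peak whose matching window contains no strict local maximum
    is reported as unmatched and excluded.  Returns ``(rmse, bias_pct,
    sd)`` where ``bias_pct = 100 * rmse / mean reference amplitude`` and
    ``sd`` is the standard deviation of the paired amplitude differences.
    """
    pred = pred_ecg.samples
    paired_truth, paired_pred = [], []
    unmatched = 0
    for idx, amp in zip(truth_peaks.indices, truth_peaks.amplitudes):
        lo = max(idx - tolerance, 0)
        hi = min(idx + tolerance + 1, pred.size)
        if hi <= lo:
            unmatched += 1
            continue
        seg = pred[lo:hi]
        k = lo + int(np.argmax(seg))
        # require an interior strict local max unless clipped by the edges
        left_ok = k == 0 or pred[k] >= pred[k - 1]
        right_ok = k == pred.size - 1 or pred[k] >= pred[k + 1]
        if not (left_ok and right_ok):
            unmatched += 1
            continue
        paired_truth.append(amp)
        paired_pred.append(pred[k])
    if not paired_truth:
        raise EvaluationError("no reference R peaks could be paired with the "
                              "predicted ECG")
    t = np.asarray(paired_truth)
    p = np.asarray(paired_pred)
    amp_rmse = rmse(t, p)
    mean_truth = float(np.mean(t))
    if mean_truth == 0.0:
        raise EvaluationError("mean reference R-peak amplitude is zero")
    bias_pct = 100.0 * amp_rmse / mean_truth
    diffs = p - t
    sd = float(np.std(diffs, ddof=1)) if diffs.size > 1 else 0.0
    return amp_rmse, bias_pct, sd


def aggregate_subjects(per_record: Sequence[tuple[str, float, float]],
                       confidence: float = 0.95) -> EvalReport:
    """Aggregate per-record (subject_id, rmse, pcc) rows across subjects.

    Records are first averaged within subject; the across-subject mean is
    then reported with the two-sided t-distribution confidence half-width
    ``t_{1-(1-c)/2, n-1} * sd / sqrt(n)``.  Requires n >= 2 subjects.
    """
    if not per_record:
        raise InputError("per_record is empty")
    frame = pd.DataFrame(per_record, columns=["subject_id", "rmse", "pcc"])
    by_subject = frame.groupby("subject_id")[["rmse", "pcc"]].mean()
    n = by_subject.shape[0]
    aggregate = {}
    for metric in ("rmse", "pcc"):
        values = by_subject[metric].to_numpy()
        mean = float(values.mean())
        if n < 2:
            raise EvaluationError(
                f"confidence interval undefined for n=1 subject "
                f"(point estimate {metric}={mean:.4f})")
        sd = float(values.std(ddof=1))
        t_crit = float(stats.t.ppf(0.5 + confidence / 2.0, df=n - 1))
        aggregate[metric] = (mean, t_crit * sd / np.sqrt(n), sd)
    return EvalReport(per_record=frame, aggregate=aggregate)


def _aggregate_lenient(rows: Sequence[tuple[str, float, float]]) -> EvalReport:
    """Like :func:`aggregate_subjects` but degrades to a point estimate
    (NaN half-width/sd) when only one subject is present."""
    try:
        return aggregate_subjects(rows)
    except EvaluationError:
        frame = pd.DataFrame(rows, columns=["subject_id", "rmse", "pcc"])
        aggregate = {m: (float(frame[m].mean()), float("nan"), float("nan"))
                     for m in ("rmse", "pcc")}
        return EvalReport(per_record=frame, aggregate=aggregate)


def evaluate_records(model: TrainedModel, records: Sequence[CardiacRecord],
                     modality: str = "multimodal") -> EvalReport:
    """Reconstruct every record and score it against its reference ECG.

    Metrics are computed on the concatenated (pooled) windows of each
    record; the reference ECG windows are standardized exactly as the
    training targets were, so RMSE is in standardized units.
    """
    from .fusion_model import _standardize_windows  # shared convention
    rows = []
    for record in records:
        if record.ecg is None:
            raise InputError(f"record {record.subject_id} lacks a reference ECG")
        pred = reconstruct(model, record.scg, record.pcg)
        w = model.config.window_len
        n_windows = len(pred) // w
        truth = _standardize_windows(
            record.ecg.samples[:n_windows * w].reshape(n_windows, w)).reshape(-1)
        rows.append((record.subject_id, rmse(truth, pred.samples),
                     pcc(truth, pred.samples)))
    report = _aggregate_lenient(rows)
    report.modality = modality
    return report


def saliency_timing_probe(model: TrainedModel, record: CardiacRecord,
                          r_times: np.ndarray, pre_s: float = 0.1,
                          control_s: tuple[float, float] = (0.5, 0.6),
                          qrs_half_width: int = 12
                          ) -> tuple[float, float, int]:
    """Compare input saliency just before the R peak against mid-diastole.

    For every beat whose R peak sits far enough inside a window, the
    gradient magnitude of the predicted QRS region (R +- ``qrs_half_width``
    samples) w.r.t. the fused inputs is averaged over the ``pre_s`` seconds
    before the R peak and over a mid-diastole control span ``control_s``
    after it (after the S2 burst, before the next P wave).  Returns
    ``(mean_pre_r, mean_control, n_beats)``.

    A pre-R mean exceeding the control mean indicates the model is keyed to
    the early mechanical cues (S1, pre-ejection vibration) that precede
    electrical ventricular activation.
    """
    from .fusion_model import _standardize_windows, fuse_inputs, saliency_map
    fs = record.fs
    w = model.config.window_len
    scg_w, pcg_w, _ = record.windows()
    fused = fuse_inputs(_standardize_windows(scg_w), _standardize_windows(pcg_w),
                        mask=model.train_config.mask)
    n_pre = int(round(pre_s * fs))
    c_lo, c_hi = (int(round(s * fs)) for s in control_s)
    pre_vals, control_vals = [], []
    for r in np.asarray(r_times):
        idx = int(round(r * fs))
        k, pos = divmod(idx, w)
        if k >= fused.shape[0]:
            continue
        if pos - n_pre < 0 or pos + c_hi >= w:
            continue
        sal = saliency_map(model, fused[k],
                           output_indices=np.arange(pos - qrs_half_width,
                                                    pos + qrs_half_width + 1))
        pre_vals.append(sal[pos - n_pre:pos].mean())
        control_vals.append(sal[pos + c_lo:pos + c_hi].mean())
    if not pre_vals:
        raise EvaluationError("no beat sits far enough inside a window for "
                              "the saliency probe")
    return float(np.mean(pre_vals)), float(np.mean(control_vals)), len(pre_vals)


def run_ablation(dataset: Sequence[CardiacRecord], mcfg: ModelConfig,
                 tcfg: TrainConfig, verbose: bool = False) -> list[EvalReport]:
    """Train and evaluate the three modality settings on identical data.

    The record-level split and all seeds are shared across settings; the
    only difference is which input channel is zeroed.  Returns reports for
    ``multimodal``, ``pcg_only`` and ``scg_only`` in that order.
    """
    from dataclasses import replace

    from .fusion_model import _record_split
    rng = np.random.default_rng(tcfg.seed)
    train_idx, val_idx = _record_split(len(dataset), tcfg.split, rng)
    test_records = [dataset[i] for i in val_idx] or list(dataset)
    reports = []
    for mask, label in (("none", "multimodal"), ("pcg_only", "pcg_only"),
                        ("scg_only", "scg_only")):
        model = train(dataset, mcfg, replace(tcfg, mask=mask), verbose=verbose)
        report = evaluate_records(model, test_records, modality=label)
        reports.append(report)
    return reports
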