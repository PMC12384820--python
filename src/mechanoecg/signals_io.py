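"""Readers, writers, reference-ECG conditioning, and record alignment.

File formats
------------
* PCG audio: WAV (PCM or IEEE float).  A sidecar ``<name>.t0`` text file
  holding a single number supplies the start timestamp; absent sidecar means
  ``t0 = 0``.
* Accelerometer: delimited text with header ``t,ax,ay,az`` (seconds, m/s^2).
* Reference ECG: delimited text with header ``t,ecg_mV``.
* Session manifest: ``key = value`` text binding the three files plus
  ``subject_id``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.io import wavfile

from .errors import InputError, StandardizationError
from .types import CardiacRecord, TriaxialSeries, UniformSeries

logger = logging.getLogger(__name__)

__all__ = [
    "read_pcg_wav",
    "write_pcg_wav",
    "read_accel_table",
    "write_accel_table",
    "read_ecg_table",
    "write_ecg_table",
    "read_manifest",
    "write_manifest",
    "standardize",
    "condition_ecg",
    "align_and_segment",
]

#: Maximum timestamp disagreement tolerated when snapping series onto a
#: common sample grid (seconds).
ALIGN_TOLERANCE_S = 2e-3

_INT_SCALE = {np.dtype("int16"): 2**15, np.dtype("int32"): 2**31,
              np.dtype("uint8"): 2**7}


def _snap_rate(fs: float, rel_tol: float = 1e-4) -> float:
    """Snap a rate inferred from finite-precision timestamps to the nearest
    integer when it is within ``rel_tol`` of it."""
    nearest = round(fs)
    if nearest > 0 and abs(fs - nearest) <= rel_tol * nearest:
        return float(nearest)
    return fs


def _read_t0_sidecar(path: Path) -> float:
    sidecar = path.with_suffix(path.suffix + ".t0")
    if sidecar.exists():
        return float(sidecar.read_text().strip())
    return 0.0


def read_pcg_wav(path) -> UniformSeries:
    """Read heart-sound audio from a WAV file.

    Returns the first channel as an ``a.u.`` :class:`UniformSeries` with the
    sampling rate from the header.  Integer PCM is scaled to [-1, 1);
    float data is returned as stored.
    """
    path = Path(path)
    try:
        fs, data = wavfile.read(path)
    except Exception as exc:  # scipy raises ValueError/struct.error/EOFError
        raise InputError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise InputError(f"WAV file {path} contains no samples")
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype in _INT_SCALE:
        data = data.astype(np.float64) / _INT_SCALE[data.dtype]
    return UniformSeries(samples=np.asarray(data, dtype=np.float64), fs=float(fs),
                         t0=_read_t0_sidecar(path), units="a.u.")


def write_pcg_wav(path, series: UniformSeries) -> None:
    """Write a series as 32-bit float WAV (plus ``.t0`` sidecar if t0 != 0)."""
    path = Path(path)
    wavfile.write(path, int(round(series.fs)), series.samples.astype(np.float32))
    if series.t0 != 0.0:
        path.with_suffix(path.suffix + ".t0").write_text(repr(series.t0))


def read_accel_table(path) -> TriaxialSeries:
    """Read a delimited accelerometer table (columns t, ax, ay, az).

    The sampling rate is inferred from the median time step; non-uniform
    timestamps (jitter beyond 10% of the median step) are resampled onto a
    uniform grid by linear interpolation.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"cannot read accelerometer table {path}: {exc}") from exc
    required = ["t", "ax", "ay", "az"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path} is missing columns {missing}")
    t = df["t"].to_numpy(dtype=np.float64)
    if t.size < 2:
        raise InputError(f"{path} must contain at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise InputError(f"{path} time column is not strictly increasing")
    step = float(np.median(dt))
    fs = _snap_rate(1.0 / step)
    a = df[["ax", "ay", "az"]].to_numpy(dtype=np.float64)
    if np.max(np.abs(dt - step)) > 0.1 * step:
        # Jittery clock: re-grid by linear interpolation.
        t_uniform = t[0] + np.arange(int(np.floor((t[-1] - t[0]) / step)) + 1) * step
        a = np.column_stack([np.interp(t_uniform, t, a[:, k]) for k in range(3)])
        t0 = float(t_uniform[0])
    else:
        t0 = float(t[0])
    return TriaxialSeries.from_stacked(a, fs=fs, t0=t0, frame="sensor")


def write_accel_table(path, series: TriaxialSeries) -> None:
    df = pd.DataFrame({"t": series.times(), "ax": series.ax,
                       "ay": series.ay, "az": series.az})
    df.to_csv(path, index=False, float_format="%.9g")


def read_ecg_table(path) -> UniformSeries:
    """Read a delimited reference-ECG table (columns t, ecg_mV)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"cannot read ECG table {path}: {exc}") from exc
    for col in ("t", "ecg_mV"):
        if col not in df.columns:
            raise InputError(f"{path} is missing column {col!r}")
    t = df["t"].to_numpy(dtype=np.float64)
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise InputError(f"{path} time column is not strictly increasing")
    fs = _snap_rate(1.0 / float(np.median(np.diff(t))))
    return UniformSeries(samples=df["ecg_mV"].to_numpy(dtype=np.float64),
                         fs=fs, t0=float(t[0]), units="mV")


def write_ecg_table(path, series: UniformSeries) -> None:
    df = pd.DataFrame({"t": series.times(), "ecg_mV": series.samples})
    df.to_csv(path, index=False, float_format="%.9g")


def read_manifest(path) -> dict:
    """Parse a ``key = value`` session manifest; file paths resolve relative
    to the manifest's directory."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"manifest {path} does not exist")
    out: dict = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise InputError(f"malformed manifest line: {line!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        out[key] = value
    for key in ("accel", "pcg", "ecg"):
        if key in out:
            out[key] = str((path.parent / out[key]).resolve())
    return out


def write_manifest(path, entries: dict) -> None:
    lines = [f"{k} = {v}" for k, v in entries.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def standardize(x: np.ndarray, what: str = "segment") -> np.ndarray:
    """Subtract the mean and divide by the standard deviation.

    Raises :class:`StandardizationError` for zero-variance input.
    """
    x = np.asarray(x, dtype=np.float64)
    sd = float(np.std(x))
    if sd == 0.0 or not np.isfinite(sd):
        raise StandardizationError(f"cannot standardize zero-variance {what}")
    return (x - np.mean(x)) / sd


def condition_ecg(ecg: UniformSeries, mode: str = "custom",
                  notch_hz: float = 50.0) -> UniformSeries:
    """Condition a reference ECG for use as a regression target.

    ``custom`` mode applies a zero-phase 0.5-40 Hz bandpass followed by
    standardization.  ``public`` mode additionally applies a powerline notch
    (default 50 Hz, configurable to 60 Hz) before the bandpass, for corpora
    recorded without mains shielding.
    """
    if mode not in ("custom", "public"):
        raise InputError(f"unknown conditioning mode {mode!r}")
    if ecg.fs < 100.0:
        raise InputError(f"ECG sampling rate {ecg.fs} Hz too low (need >= 100 Hz)")
    x = ecg.samples
    if mode == "public":
        if notch_hz >= ecg.fs / 2:
            raise InputError(f"notch frequency {notch_hz} Hz at or above Nyquist")
        b, a = sps.iirnotch(notch_hz, Q=30.0, fs=ecg.fs)
        x = sps.filtfilt(b, a, x)
    sos = sps.butter(4, [0.5, 40.0], btype="bandpass", fs=ecg.fs, output="sos")
    x = sps.sosfiltfilt(sos, x)
    x = standardize(x, "ECG record")
    return ecg.copy_with(samples=x, units="a.u.")


def _crop_to(series: UniformSeries, t_start: float, n: int) -> UniformSeries:
    offset_exact = (t_start - series.t0) * series.fs
    offset = int(round(offset_exact))
    if abs(offset - offset_exact) / series.fs > ALIGN_TOLERANCE_S:
        raise InputError(
            f"series timestamps misaligned with the common grid by more than "
            f"{ALIGN_TOLERANCE_S * 1e3:.0f} ms")
    return series.copy_with(samples=series.samples[offset:offset + n],
                            t0=series.t0 + offset / series.fs)


def align_and_segment(scg: UniformSeries, pcg: UniformSeries,
                      ecg: Optional[UniformSeries] = None,
                      window_len: int = 1000,
                      subject_id: str = "unknown") -> CardiacRecord:
    """Crop SCG/PCG(/ECG) to their common time support and segment.

    All inputs must share the sampling rate (nominally 250 Hz).  The common
    support is computed from the ``t0`` values with nearest-sample snapping
    (tolerance 2 ms), then every series is truncated to a whole number of
    ``window_len`` windows.
    """
    series = [scg, pcg] + ([ecg] if ecg is not None else [])
    rates = {s.fs for s in series}
    if len(rates) != 1:
        raise InputError(f"sampling rates differ across series: {sorted(rates)}")
    fs = scg.fs
    t_start = max(s.t0 for s in series)
    t_end = min(s.t_end for s in series)
    n_common = int(np.floor((t_end - t_start) * fs + 0.5)) + 1
    if n_common < window_len:
        raise InputError(
            f"common time support ({max(n_common, 0)} samples) is shorter than "
            f"one window ({window_len} samples)")
    n = (n_common // window_len) * window_len
    cropped = [_crop_to(s, t_start, n) for s in series]
    return CardiacRecord(scg=cropped[0], pcg=cropped[1],
                         ecg=cropped[2] if ecg is not None else None,
                         subject_id=subject_id, window_len=window_len)
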