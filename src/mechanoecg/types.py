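"""Core data containers shared by every stage of the pipeline.

All waveforms are uniformly sampled.  Time is kept as seconds in 64-bit
floats (``t0`` is either epoch or session-relative; the two only need to be
consistent within one recording session).  Sample values are float64
throughout: the signals here are small (minutes at a few hundred hertz) and
exactness in the preprocessing chain matters more than memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import InputError

__all__ = [
    "UniformSeries",
    "TriaxialSeries",
    "AngleTrack",
    "CardiacRecord",
    "G",
]

#: Standard gravity magnitude used for tilt estimation and compensation (m/s^2).
G = 9.81


def _as_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 1 or arr.size < 1:
        raise InputError(f"{name} must be a non-empty 1-D array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InputError(f"{name} contains non-finite samples")
    return arr


@dataclass
class UniformSeries:
    """A uniformly sampled scalar waveform.

    Parameters
    ----------
    samples : array-like
        Signal values; finite, length >= 1.
    fs : float
        Sampling rate in Hz, > 0.
    t0 : float
        Time of the first sample in seconds.
    units : str
        Physical units label: ``"mV"``, ``"m/s^2"`` or ``"a.u."``.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    units: str = "a.u."

    def __post_init__(self) -> None:
        self.samples = _as_vector(self.samples, "samples")
        if not self.fs > 0:
            raise InputError(f"fs must be positive, got {self.fs}")
        self.fs = float(self.fs)
        self.t0 = float(self.t0)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Duration in seconds (n / fs)."""
        return self.samples.size / self.fs

    @property
    def t_end(self) -> float:
        """Time of the last sample."""
        return self.t0 + (self.samples.size - 1) / self.fs

    def times(self) -> np.ndarray:
        """Per-sample timestamps in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    def copy_with(self, **kw) -> "UniformSeries":
        return replace(self, **kw)


@dataclass
class TriaxialSeries:
    """Calibrated 3-axis acceleration with an explicit frame label.

    ``frame`` is ``"sensor"`` for raw device-axis data and ``"world"`` after
    rotation into the gravity-aligned frame.  The dorso-ventral direction is
    the sensor z axis by convention; a level, motionless sensor reads
    ``(0, 0, -g)``.
    """

    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    fs: float
    t0: float = 0.0
    frame: str = "sensor"

    def __post_init__(self) -> None:
        self.ax = _as_vector(self.ax, "ax")
        self.ay = _as_vector(self.ay, "ay")
        self.az = _as_vector(self.az, "az")
        if not (self.ax.size == self.ay.size == self.az.size):
            raise InputError("ax, ay, az must have equal lengths")
        if not self.fs > 0:
            raise InputError(f"fs must be positive, got {self.fs}")
        if self.frame not in ("sensor", "world"):
            raise InputError(f"frame must be 'sensor' or 'world', got {self.frame!r}")
        self.fs = float(self.fs)
        self.t0 = float(self.t0)

    def __len__(self) -> int:
        return self.ax.size

    def times(self) -> np.ndarray:
        """Per-sample timestamps in seconds."""
        return self.t0 + np.arange(self.ax.size) / self.fs

    def stacked(self) -> np.ndarray:
        """(n, 3) array with columns (ax, ay, az)."""
        return np.column_stack([self.ax, self.ay, self.az])

    @classmethod
    def from_stacked(
        cls, a: np.ndarray, fs: float, t0: float = 0.0, frame: str = "sensor"
    ) -> "TriaxialSeries":
        a = np.asarray(a, dtype=np.float64)
        return cls(ax=a[:, 0], ay=a[:, 1], az=a[:, 2], fs=fs, t0=t0, frame=frame)


@dataclass
class AngleTrack:
    """Roll/pitch tilt-angle time series with the trailing Kalman state.

    ``kalman_state`` maps each angle name to an ``(estimate, variance)``
    pair at the last sample; it is ``None`` until :func:`kalman_smooth`
    has run.
    """

    roll: np.ndarray
    pitch: np.ndarray
    fs: float
    kalman_state: Optional[dict] = None

    def __post_init__(self) -> None:
        self.roll = _as_vector(self.roll, "roll")
        self.pitch = _as_vector(self.pitch, "pitch")
        if self.roll.size != self.pitch.size:
            raise InputError("roll and pitch must have equal lengths")
        if not self.fs > 0:
            raise InputError(f"fs must be positive, got {self.fs}")
        self.fs = float(self.fs)

    def __len__(self) -> int:
        return self.roll.size


@dataclass
class CardiacRecord:
    """An aligned SCG/PCG(/ECG) triplet at a common sampling rate.

    After :func:`align_and_segment` all present series share ``fs`` and
    length, and the length is a whole multiple of ``window_len``.
    """

    scg: UniformSeries
    pcg: UniformSeries
    ecg: Optional[UniformSeries] = None
    subject_id: str = "unknown"
    window_len: int = 1000

    def __post_init__(self) -> None:
        series = [self.scg, self.pcg] + ([self.ecg] if self.ecg is not None else [])
        fs = {s.fs for s in series}
        if len(fs) != 1:
            raise InputError(f"series sampling rates differ: {sorted(fs)}")
        n = {len(s) for s in series}
        if len(n) != 1:
            raise InputError(f"series lengths differ: {sorted(n)}")
        if self.window_len < 1:
            raise InputError("window_len must be >= 1")

    @property
    def fs(self) -> float:
        return self.scg.fs

    @property
    def n_samples(self) -> int:
        return len(self.scg)

    @property
    def n_windows(self) -> int:
        return self.n_samples // self.window_len

    def windows(self) -> tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
        """Return (scg, pcg, ecg) arrays of shape (n_windows, window_len).

        Trailing samples beyond a whole number of windows are dropped.
        """
        n = self.n_windows * self.window_len

        def seg(s: Optional[UniformSeries]):
            if s is None:
                return None
            return s.samples[:n].reshape(self.n_windows, self.window_len)

        return seg(self.scg), seg(self.pcg), seg(self.ecg)
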