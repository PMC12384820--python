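"""Orientation-invariant SCG extraction from raw tri-axial accelerometry.

The chest-mounted accelerometer records the cardiac micro-vibrations
(roughly 5-100 Hz, fractions of m/s^2) superimposed on a gravity projection
that is orders of magnitude larger and slowly rotating with posture and
respiration.  The pipeline is:

1. offset calibration against a static window,
2. per-sample tilt estimation (roll phi, pitch theta) from the gravity
   projections,
3. Kalman smoothing of each angle (scalar random-walk model),
4. geometric gravity compensation: rotate to the world frame, subtract the
   gravity vector, rotate back,
5. high-pass + zero-phase FIR bandpass + resample + per-segment
   standardization of the selected dorso-ventral channel.

Axis convention: a level, motionless sensor reads ``(0, 0, -g)``, i.e. the
sensor z axis points away from the chest, so at phi = theta = 0 gravity
projects entirely onto -z.  The gravity projections under tilt are::

    ax = g sin(theta)
    ay = -g sin(phi) cos(theta)
    az = -g cos(phi) cos(theta)

which satisfy ax^2 + ay^2 + az^2 = g^2 identically and invert as
``theta = asin(ax / g)``, ``phi = atan2(-ay, -az)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, InputError, StandardizationError
from .signals_io import standardize
from .types import AngleTrack, G, TriaxialSeries, UniformSeries

logger = logging.getLogger(__name__)

__all__ = [
    "GravityModel",
    "rotation_x",
    "rotation_y",
    "sensor_to_world",
    "gravity_in_sensor_frame",
    "calibrate_offsets",
    "estimate_tilt",
    "kalman_smooth",
    "compensate_gravity",
    "scg_filter_chain",
    "preprocess_scg",
]


@dataclass
class GravityModel:
    """Per-axis constant bias estimated from a static calibration window."""

    offsets: np.ndarray  # (3,) m/s^2
    g: float = G

    def apply(self, raw: TriaxialSeries) -> TriaxialSeries:
        """Return the offset-corrected series."""
        a = raw.stacked() - self.offsets[None, :]
        return TriaxialSeries.from_stacked(a, fs=raw.fs, t0=raw.t0, frame=raw.frame)


def rotation_x(phi: float) -> np.ndarray:
    """Rotation matrix about the x axis."""
    c, s = np.cos(phi), np.sin(phi)
    return np.array([[1.0, 0.0, 0.0],
                     [0.0, c, s],
                     [0.0, -s, c]])


def rotation_y(theta: float) -> np.ndarray:
    """Rotation matrix about the y axis."""
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, 0.0, -s],
                     [0.0, 1.0, 0.0],
                     [s, 0.0, c]])


def sensor_to_world(phi: float, theta: float) -> np.ndarray:
    """Rotation mapping sensor-frame vectors into the gravity-aligned world
    frame, ``R = (Rx(phi) Ry(theta))^T``.

    The sign convention is fixed by requiring that the static gravity
    reading maps exactly onto the world vector ``(0, 0, -g)``.
    """
    return (rotation_x(phi) @ rotation_y(theta)).T


def gravity_in_sensor_frame(phi, theta, g: float = G) -> np.ndarray:
    """Gravity projections onto the sensor axes at tilt (phi, theta).

    Accepts scalars or equal-length arrays; returns shape (..., 3).
    """
    phi = np.asarray(phi, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    ax = g * np.sin(theta)
    ay = -g * np.sin(phi) * np.cos(theta)
    az = -g * np.cos(phi) * np.cos(theta)
    return np.stack([ax, ay, az], axis=-1)


def calibrate_offsets(raw: TriaxialSeries, static_window: tuple[int, int],
                      assume_level: bool = True) -> GravityModel:
    """Estimate per-axis constant bias from a motionless window.

    With ``assume_level`` the sensor is taken to be in the level pose during
    the window, so the bias is the static mean minus ``(0, 0, -g)``.
    Otherwise the tilt is first estimated from the (bias-contaminated)
    static mean and the expected gravity projection at that tilt is
    subtracted instead — adequate when biases are small against g.

    If the corrected static vector magnitude deviates from g by more than
    1%, a warning is logged and the model is returned anyway.
    """
    lo, hi = static_window
    n = len(raw)
    if not (0 <= lo < hi <= n):
        raise InputError(f"static window [{lo}, {hi}) outside series of length {n}")
    if (hi - lo) < raw.fs - 0.5:  # tolerate rate round-off from file readers
        raise InputError("static calibration window must span at least 1 s")
    mean = raw.stacked()[lo:hi].mean(axis=0)
    magnitude = float(np.linalg.norm(mean))
    if abs(magnitude - G) > 0.01 * G:
        # The static mean should be (bias + gravity); a magnitude far from g
        # means the window was not static or the sensor scale is off.
        logger.warning(
            "static-window acceleration magnitude %.3f m/s^2 deviates from g "
            "by more than 1%%; calibration window may not be static", magnitude)
    if assume_level:
        expected = np.array([0.0, 0.0, -G])
    else:
        theta = np.arcsin(np.clip(mean[0] / G, -1.0, 1.0))
        phi = np.arctan2(-mean[1], -mean[2])
        expected = gravity_in_sensor_frame(phi, theta)
    offsets = mean - expected
    return GravityModel(offsets=offsets)


def estimate_tilt(calibrated: TriaxialSeries) -> AngleTrack:
    """Per-sample roll/pitch from the gravity projections.

    ``theta = asin(ax / g)``; ``phi = atan2(-ay, -az)`` so that the level
    pose ``(0, 0, -g)`` yields phi = theta = 0.  Samples with |ax| > g
    (dynamic bursts exceeding gravity) are clipped to the asin domain with a
    warning; the Kalman smoother absorbs the resulting spikes.
    """
    if calibrated.frame != "sensor":
        raise InputError("tilt estimation expects sensor-frame data")
    ratio = calibrated.ax / G
    n_clip = int(np.sum(np.abs(ratio) > 1.0))
    if n_clip:
        logger.warning("clipped %d samples with |ax| > g during tilt estimation",
                       n_clip)
    theta = np.arcsin(np.clip(ratio, -1.0, 1.0))
    phi = np.arctan2(-calibrated.ay, -calibrated.az)
    return AngleTrack(roll=phi, pitch=theta, fs=calibrated.fs)


def _kalman_1d(z: np.ndarray, q: float, r: float) -> tuple[np.ndarray, float]:
    """Scalar random-walk Kalman filter: predict x_k = x_{k-1} (variance + q),
    update against measurement z_k (variance r).  Initialized at the first
    measurement with variance r."""
    x = z[0]
    p = r
    out = np.empty_like(z)
    out[0] = x
    for k in range(1, z.size):
        p = p + q
        gain = p / (p + r)
        x = x + gain * (z[k] - x)
        p = (1.0 - gain) * p
        out[k] = x
    return out, p


def kalman_smooth(angles: AngleTrack, q: float = 1e-5, r: float = 1e-2) -> AngleTrack:
    """Kalman-filter each tilt angle independently.

    Parameters
    ----------
    q : float
        Process variance per step (rad^2); encodes the slow-tilt prior.
    r : float
        Measurement variance (rad^2) of the instantaneous accelerometer
        angles, which are corrupted by cardiac and motion accelerations.
    """
    if q <= 0 or r <= 0:
        raise ConfigError(f"Kalman variances must be positive (q={q}, r={r})")
    roll, p_roll = _kalman_1d(angles.roll, q, r)
    pitch, p_pitch = _kalman_1d(angles.pitch, q, r)
    return AngleTrack(
        roll=roll, pitch=pitch, fs=angles.fs,
        kalman_state={"roll": (float(roll[-1]), p_roll),
                      "pitch": (float(pitch[-1]), p_pitch)})


def compensate_gravity(calibrated: TriaxialSeries, angles: AngleTrack) -> TriaxialSeries:
    """Remove the gravity projection using the estimated orientation.

    Per sample: rotate the sensor reading into the world frame, subtract
    the world gravity vector ``(0, 0, -g)``, and rotate back, so a static
    sensor at any tilt compensates to the zero vector.  Rotating back keeps
    the dynamic acceleration in the sensor frame, preserving the
    dorso-ventral channel used for the SCG.
    """
    if calibrated.frame != "sensor":
        raise InputError("gravity compensation expects sensor-frame data")
    if len(calibrated) != len(angles):
        raise InputError(
            f"series length {len(calibrated)} != angle track length {len(angles)}")
    a = calibrated.stacked()
    # R a = world-frame acceleration; subtracting gravity and rotating back
    # with R^T is algebraically a - R^T (0,0,-g) = a - g_sensor(phi, theta):
    # the per-sample rotation reduces to subtracting the predicted gravity
    # projection, which is exact and avoids n explicit 3x3 products.
    g_proj = gravity_in_sensor_frame(angles.roll, angles.pitch)
    dynamic = a - g_proj
    return TriaxialSeries.from_stacked(dynamic, fs=calibrated.fs, t0=calibrated.t0,
                                       frame="sensor")


def _zero_phase_fir_bandpass(x: np.ndarray, fs: float, lo: float, hi: float,
                             numtaps: int | None = None) -> np.ndarray:
    """Forward-backward application of a linear-phase FIR bandpass."""
    if numtaps is None:
        numtaps = int(2 * fs) + 1  # ~1 Hz transition width, >=40 dB with Hamming
    taps = sps.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)
    padlen = min(3 * numtaps, x.size - 1)
    return sps.filtfilt(taps, [1.0], x, padlen=padlen)


def scg_filter_chain(dynamic: TriaxialSeries, axis_select: str = "z",
                     target_fs: float = 250.0,
                     band: tuple[float, float] = (2.0, 50.0),
                     highpass_hz: float = 0.5) -> UniformSeries:
    """Band-limit, resample and standardize the selected SCG channel.

    Applies the 2-50 Hz zero-phase FIR bandpass to isolate the cardiac
    vibration band, then a 0.5 Hz zero-phase high-pass to remove residual
    respiratory/postural baseline wander, resamples to ``target_fs`` and
    standardizes (zero mean, unit variance).

    ``axis_select`` is ``"x"``, ``"y"``, ``"z"`` (dorso-ventral default) or
    ``"magnitude"`` for the vector norm.
    """
    if dynamic.fs < 125.0:
        raise InputError(f"sampling rate {dynamic.fs} Hz too low for the 50 Hz band edge")
    if axis_select == "magnitude":
        x = np.linalg.norm(dynamic.stacked(), axis=1)
    elif axis_select in ("x", "y", "z"):
        x = getattr(dynamic, "a" + axis_select)
    else:
        raise ConfigError(f"unknown axis_select {axis_select!r}")
    x = _zero_phase_fir_bandpass(x, dynamic.fs, band[0], band[1])
    sos = sps.butter(4, highpass_hz, btype="highpass", fs=dynamic.fs, output="sos")
    x = sps.sosfiltfilt(sos, x)
    if dynamic.fs != target_fs:
        up, down = (np.round([target_fs, dynamic.fs]) /
                    np.gcd(int(round(target_fs)), int(round(dynamic.fs)))).astype(int)
        x = sps.resample_poly(x, up, down)
    try:
        x = standardize(x, "SCG segment")
    except StandardizationError:
        raise StandardizationError(
            "SCG segment has zero variance after filtering; cannot standardize")
    return UniformSeries(samples=x, fs=target_fs, t0=dynamic.t0, units="a.u.")


def write_angle_track(path, angles: AngleTrack, t0: float = 0.0) -> None:
    """Dump a roll/pitch track as delimited text (columns t, roll, pitch),
    e.g. for tilt-trace diagnostic plots."""
    import pandas as pd
    t = t0 + np.arange(len(angles)) / angles.fs
    pd.DataFrame({"t": t, "roll": angles.roll, "pitch": angles.pitch}).to_csv(
        path, index=False, float_format="%.9g")


def preprocess_scg(raw: TriaxialSeries,
                   static_window: tuple[int, int] | None = None,
                   angles: AngleTrack | None = None,
                   q: float = 1e-5, r: float = 1e-2,
                   axis_select: str = "z") -> tuple[UniformSeries, AngleTrack]:
    """Full raw-accelerometer -> SCG chain.

    ``static_window`` defaults to the first second.  ``angles`` may be
    supplied externally (e.g. simulator ground truth) to bypass estimation;
    otherwise tilt is estimated and Kalman-smoothed.  Returns the SCG series
    and the angle track used.
    """
    if static_window is None:
        static_window = (0, int(np.ceil(raw.fs)))
    model = calibrate_offsets(raw, static_window)
    calibrated = model.apply(raw)
    if angles is None:
        angles = kalman_smooth(estimate_tilt(calibrated), q=q, r=r)
    dynamic = compensate_gravity(calibrated, angles)
    return scg_filter_chain(dynamic, axis_select=axis_select), angles
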