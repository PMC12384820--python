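"""Heart-sound (PCG) conditioning: bandpass, downsample, envelope.

The 48 kHz stethoscope audio carries the S1/S2 valve-closure sounds in
roughly the 20-200 Hz band, buried under low-frequency respiratory rumble
and high-frequency ambient noise.  The chain isolates that band, resamples
to the common 250 Hz rate, and converts to a rectified moving-average
envelope so that the model sees smooth S1/S2 energy bumps aligned with the
QRS complex and the end of the T wave.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, InputError
from .signals_io import standardize
from .types import UniformSeries

__all__ = ["PcgConfig", "pcg_bandpass", "pcg_downsample", "pcg_envelope",
           "preprocess_pcg"]


@dataclass
class PcgConfig:
    """Tunables of the PCG chain.

    band : passband in Hz, inside (0, fs/2).
    target_fs : common model rate (Hz).
    envelope_window : moving-average length in seconds.  50 ms sits between
        a single acoustic oscillation (~10-20 ms at S1/S2 frequencies) and
        the S1-S2 spacing (~300 ms), so the two sounds stay resolved.
    mode : ``"envelope"`` (default model input) or ``"waveform"`` to skip
        envelope extraction and feed the band-limited waveform itself.
    """

    band: tuple[float, float] = (20.0, 200.0)
    target_fs: float = 250.0
    envelope_window: float = 0.05
    mode: str = "envelope"

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (0.0 < lo < hi):
            raise ConfigError(f"invalid PCG band {self.band}")
        if self.envelope_window <= 0:
            raise ConfigError("envelope_window must be positive")
        if self.mode not in ("envelope", "waveform"):
            raise ConfigError(f"unknown PCG mode {self.mode!r}")


def pcg_bandpass(raw: UniformSeries, cfg: PcgConfig | None = None) -> UniformSeries:
    """Zero-phase 20-200 Hz bandpass at the native audio rate."""
    cfg = cfg or PcgConfig()
    if raw.fs <= 400.0:
        raise InputError(f"PCG sampling rate {raw.fs} Hz too low (need > 400 Hz)")
    if cfg.band[1] >= raw.fs / 2:
        raise ConfigError(
            f"band edge {cfg.band[1]} Hz at or above Nyquist ({raw.fs / 2} Hz)")
    sos = sps.butter(4, cfg.band, btype="bandpass", fs=raw.fs, output="sos")
    return raw.copy_with(samples=sps.sosfiltfilt(sos, raw.samples))


def pcg_downsample(filtered: UniformSeries, cfg: PcgConfig | None = None) -> UniformSeries:
    """Anti-aliased rational-rate resampling to the common 250 Hz grid."""
    cfg = cfg or PcgConfig()
    fs_in = int(round(filtered.fs))
    fs_out = int(round(cfg.target_fs))
    if fs_in == fs_out:
        return filtered
    common = np.gcd(fs_in, fs_out)
    up, down = fs_out // common, fs_in // common
    # resample_poly applies its own Kaiser-window anti-alias low-pass at the
    # output Nyquist (125 Hz) before decimation.
    out = sps.resample_poly(filtered.samples, up, down)
    return UniformSeries(samples=out, fs=float(fs_out), t0=filtered.t0,
                         units=filtered.units)


def pcg_envelope(downsampled: UniformSeries, cfg: PcgConfig | None = None,
                 do_standardize: bool = True) -> UniformSeries:
    """Rectified centered moving-average envelope, then standardization.

    Rectification is the absolute value (not squaring) so the envelope keeps
    the amplitude units of the waveform.
    """
    cfg = cfg or PcgConfig()
    n_window = int(round(cfg.envelope_window * downsampled.fs))
    if n_window < 2:
        raise ConfigError(
            f"envelope window {cfg.envelope_window}s is shorter than 2 samples "
            f"at {downsampled.fs} Hz")
    kernel = np.full(n_window, 1.0 / n_window)
    env = np.convolve(np.abs(downsampled.samples), kernel, mode="same")
    if do_standardize:
        env = standardize(env, "PCG segment")
    return downsampled.copy_with(samples=env)


def preprocess_pcg(raw: UniformSeries, cfg: PcgConfig | None = None) -> UniformSeries:
    """Full 48 kHz audio -> 250 Hz model-input chain."""
    cfg = cfg or PcgConfig()
    out = pcg_downsample(pcg_bandpass(raw, cfg), cfg)
    if cfg.mode == "envelope":
        return pcg_envelope(out, cfg)
    return out.copy_with(samples=standardize(out.samples, "PCG segment"))
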