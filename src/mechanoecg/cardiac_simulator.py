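"""Coupled cardiac-cycle simulator: consistent ECG / PCG / SCG ground truth.

The simulator renders, per heartbeat, the electrical waveform (P-QRS-T as a
sum of Gaussians, mV) and the mechanical consequences that excitation-
contraction coupling ties to it: S1/S2 heart-sound bursts in the 48 kHz
audio channel and AO/AC vibration wavelets in the chest-acceleration
channel.  The raw accelerometer stream then embeds the clean cardiac
vibration into a tilted sensor frame with gravity, constant axis offsets,
respiratory drift, and white noise — exactly the nuisances the SCG
preprocessing chain exists to remove.

Every per-beat fiducial (R peak, T end, S1, S2, AO, AC) is logged, so
detector and timing tests can assert against closed-form ground truth.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .pcg_preprocess import PcgConfig, preprocess_pcg
from .signals_io import (standardize, write_accel_table, write_ecg_table,
                         write_manifest, write_pcg_wav)
from .types import AngleTrack, CardiacRecord, TriaxialSeries, UniformSeries

__all__ = ["Wave", "SimConfig", "SimRecord", "simulate_record", "inject_cough",
           "make_dataset", "write_session"]


@dataclass
class Wave:
    """One Gaussian ECG wave: amplitude (mV), center offset from the R peak
    (s, negative = earlier), and Gaussian sigma (s)."""

    amplitude: float
    offset: float
    sigma: float


def default_morphology() -> dict[str, Wave]:
    """Resting adult single-lead morphology, normalized to a 1 mV R peak."""
    return {
        "P": Wave(0.15, -0.200, 0.025),
        "Q": Wave(-0.10, -0.040, 0.010),
        "R": Wave(1.00, 0.000, 0.012),
        "S": Wave(-0.20, 0.040, 0.010),
        "T": Wave(0.30, 0.300, 0.050),
    }


@dataclass
class SimConfig:
    """Simulation conditions.

    Heart rate is (mean, sd) in bpm; beat-to-beat RR jitter is lognormal so
    intervals stay positive with an HRV-like right skew.  Mechanical delays
    follow the electromechanical sequence: S1 shortly after QRS onset, AO
    after the R peak, S2 just after the end of the T wave, AC just before
    S2.  The SCG noise floor is deliberately higher (relative to its
    wavelet amplitude) than the audio noise floor: chest vibration is the
    weaker, artifact-prone modality.
    """

    fs_out: float = 250.0
    fs_audio: float = 48000.0
    duration: float = 30.0
    heart_rate: tuple[float, float] = (60.0, 2.0)
    morphology: dict[str, Wave] = field(default_factory=default_morphology)
    # Electromechanical timing (s)
    qrs_onset_before_r: float = 0.050
    s1_after_qrs_onset: float = 0.040
    ao_after_r: float = 0.035
    t_end_after_r: float = 0.400
    s2_after_t_end: float = 0.010
    ac_before_s2: float = 0.005
    # Mechanical waveforms
    s1_freq: float = 60.0       # Hz, inside the 20-200 Hz heart-sound band
    s2_freq: float = 85.0
    s1_sigma: float = 0.020     # s
    s2_sigma: float = 0.015
    s1_amplitude: float = 1.0   # a.u. audio
    s2_amplitude: float = 0.7
    ao_freq: float = 25.0       # Hz, inside the 5-100 Hz SCG band
    ac_freq: float = 35.0
    ao_sigma: float = 0.025     # s
    ac_sigma: float = 0.018
    ao_amplitude: float = 0.05  # m/s^2
    ac_amplitude: float = 0.03
    # Nuisances
    accel_noise_sd: float = 0.02   # m/s^2 white noise per axis
    audio_noise_sd: float = 0.01   # a.u.
    accel_offsets: tuple[float, float, float] = (0.05, -0.03, 0.02)  # m/s^2
    tilt_mean: tuple[float, float] = (0.10, -0.15)   # (phi, theta) rad
    tilt_amplitude: float = 0.02   # rad, slow postural sway
    tilt_rate: float = 0.05        # Hz
    respiration_amplitude: float = 0.05  # m/s^2 on the dorso-ventral axis
    respiration_rate: float = 0.25       # Hz
    cough_times: tuple[float, ...] = ()
    cough_amplitude: float = 5.0   # multiples of s1_amplitude

    def __post_init__(self) -> None:
        if self.fs_out <= 0 or self.fs_audio <= 0 or self.duration <= 0:
            raise ConfigError("rates and duration must be positive")
        if self.heart_rate[0] <= 0 or self.heart_rate[1] < 0:
            raise ConfigError(f"invalid heart rate {self.heart_rate}")
        for name, value in [("s1_after_qrs_onset", self.s1_after_qrs_onset),
                            ("ao_after_r", self.ao_after_r),
                            ("s2_after_t_end", self.s2_after_t_end),
                            ("ac_before_s2", self.ac_before_s2)]:
            if value < 0:
                raise ConfigError(f"{name} must be >= 0")
        if any(t < 0 or t > self.duration for t in self.cough_times):
            raise ConfigError("cough times must fall within the record duration")
        # The full mechanical sequence must fit inside the shortest plausible
        # cycle (mean - 3 sd of the rate law).
        hr_hi = self.heart_rate[0] + 3.0 * self.heart_rate[1]
        min_rr = 60.0 / hr_hi
        tail = self.t_end_after_r + self.s2_after_t_end + 3.0 * self.s2_sigma
        if tail + self.qrs_onset_before_r >= min_rr:
            raise ConfigError(
                f"electromechanical delays ({tail:.3f}s after R) do not fit the "
                f"shortest cardiac cycle ({min_rr:.3f}s at {hr_hi:.0f} bpm)")


@dataclass
class SimRecord:
    """One simulated session: clean aligned truth plus raw sensor streams."""

    truth: CardiacRecord
    raw_accel: TriaxialSeries
    raw_audio: UniformSeries
    angles_true: AngleTrack
    event_log: dict[str, np.ndarray]
    seed: int
    config: SimConfig

    def events_frame(self) -> pd.DataFrame:
        rows = [(name, t) for name, times in self.event_log.items() for t in times]
        return (pd.DataFrame(rows, columns=["event", "t"])
                .sort_values(["t", "event"]).reset_index(drop=True))


def _rr_intervals(cfg: SimConfig, rng: np.random.Generator, n_max: int) -> np.ndarray:
    mean_rr = 60.0 / cfg.heart_rate[0]
    sd_rr = mean_rr * cfg.heart_rate[1] / cfg.heart_rate[0]
    if sd_rr == 0.0:
        return np.full(n_max, mean_rr)
    # Lognormal parametrized to the target mean/sd of the interval itself.
    var = np.log1p((sd_rr / mean_rr) ** 2)
    mu = np.log(mean_rr) - var / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(var), size=n_max)


def _gabor(t: np.ndarray, center: float, sigma: float, freq: float,
           amplitude: float) -> np.ndarray:
    """Gaussian-windowed sinusoid (sine phase so the burst starts softly)."""
    dt = t - center
    return amplitude * np.exp(-0.5 * (dt / sigma) ** 2) * np.sin(2 * np.pi * freq * dt)


def _gaussian(t: np.ndarray, center: float, sigma: float,
              amplitude: float) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _render_ecg(t: np.ndarray, r_times: np.ndarray, fs: float,
                morphology: dict[str, Wave]) -> np.ndarray:
    """Sum-of-Gaussians ECG whose value at each R-peak sample is exactly the
    configured R amplitude (the R Gaussian absorbs the tails of the other
    waves at its center)."""
    ecg = np.zeros_like(t)
    for name, wave in morphology.items():
        if name == "R":
            continue
        for r in r_times:
            ecg += _gaussian(t, r + wave.offset, wave.sigma, wave.amplitude)
    r_wave = morphology["R"]
    r_idx = np.round(r_times * fs).astype(int)
    for r, idx in zip(r_times, r_idx):
        ecg += _gaussian(t, r, r_wave.sigma, r_wave.amplitude - ecg[idx])
    return ecg


def simulate_record(cfg: SimConfig, seed: int, subject_id: str = "sim") -> SimRecord:
    """Simulate one session; bitwise reproducible per (cfg, seed)."""
    rng = np.random.default_rng(seed)
    fs, fs_a = cfg.fs_out, cfg.fs_audio
    n = int(round(cfg.duration * fs))
    n_a = int(round(cfg.duration * fs_a))
    t = np.arange(n) / fs
    t_a = np.arange(n_a) / fs_a

    # --- Beat schedule: R peaks snapped onto the 250 Hz grid so that the
    # configured R amplitude lands exactly on a sample.
    mean_rr = 60.0 / cfg.heart_rate[0]
    first_r = mean_rr / 2.0
    tail = cfg.t_end_after_r + cfg.s2_after_t_end + 3 * cfg.s2_sigma
    rr = _rr_intervals(cfg, rng, n_max=int(np.ceil(cfg.duration / mean_rr * 2)) + 4)
    r_times = first_r + np.concatenate([[0.0], np.cumsum(rr)])
    r_times = r_times[r_times < cfg.duration - tail]
    r_times = np.round(r_times * fs) / fs
    if r_times.size == 0:
        raise ConfigError("duration too short to contain a single beat")

    qrs_onset = r_times - cfg.qrs_onset_before_r
    s1 = qrs_onset + cfg.s1_after_qrs_onset
    ao = r_times + cfg.ao_after_r
    t_end = r_times + cfg.t_end_after_r
    s2 = t_end + cfg.s2_after_t_end
    ac = s2 - cfg.ac_before_s2
    event_log = {"qrs_onset": qrs_onset, "r_peak": r_times, "t_end": t_end,
                 "s1": s1, "s2": s2, "ao": ao, "ac": ac}

    # --- Electrical channel (mV, 250 Hz)
    ecg = _render_ecg(t, r_times, fs, cfg.morphology)

    # --- Acoustic channel (a.u., 48 kHz)
    audio = np.zeros_like(t_a)
    for ts1, ts2 in zip(s1, s2):
        audio += _gabor(t_a, ts1, cfg.s1_sigma, cfg.s1_freq, cfg.s1_amplitude)
        audio += _gabor(t_a, ts2, cfg.s2_sigma, cfg.s2_freq, cfg.s2_amplitude)
    raw_audio = audio + cfg.audio_noise_sd * rng.standard_normal(n_a)

    # --- Mechanical channel (m/s^2, 250 Hz, dorso-ventral)
    scg_clean = np.zeros_like(t)
    for tao, tac in zip(ao, ac):
        scg_clean += _gabor(t, tao, cfg.ao_sigma, cfg.ao_freq, cfg.ao_amplitude)
        scg_clean += _gabor(t, tac, cfg.ac_sigma, cfg.ac_freq, cfg.ac_amplitude)

    # --- Raw accelerometer: cardiac vibration on the sensor z axis, plus
    # gravity under the (slowly varying) tilt, respiration, offsets, noise.
    from .scg_preprocess import gravity_in_sensor_frame  # local: avoid cycle
    phi = cfg.tilt_mean[0] + cfg.tilt_amplitude * np.sin(2 * np.pi * cfg.tilt_rate * t)
    theta = cfg.tilt_mean[1] + cfg.tilt_amplitude * np.cos(2 * np.pi * cfg.tilt_rate * t)
    angles_true = AngleTrack(roll=phi, pitch=theta, fs=fs)
    accel = np.zeros((n, 3))
    accel[:, 2] += scg_clean
    accel[:, 2] += cfg.respiration_amplitude * np.sin(2 * np.pi * cfg.respiration_rate * t)
    accel += gravity_in_sensor_frame(phi, theta)
    accel += np.asarray(cfg.accel_offsets)[None, :]
    accel += cfg.accel_noise_sd * rng.standard_normal((n, 3))
    raw_accel = TriaxialSeries.from_stacked(accel, fs=fs, t0=0.0, frame="sensor")

    # --- Clean aligned truth (model-domain units)
    truth_scg = UniformSeries(standardize(scg_clean, "simulated SCG"), fs=fs,
                              units="a.u.")
    audio_series = UniformSeries(audio, fs=fs_a, units="a.u.")
    truth_pcg = preprocess_pcg(audio_series, PcgConfig())
    truth_ecg = UniformSeries(ecg, fs=fs, units="mV")
    truth = CardiacRecord(scg=truth_scg, pcg=truth_pcg, ecg=truth_ecg,
                          subject_id=subject_id, window_len=1000)

    record = SimRecord(truth=truth, raw_accel=raw_accel,
                       raw_audio=UniformSeries(raw_audio, fs=fs_a, units="a.u."),
                       angles_true=angles_true, event_log=event_log,
                       seed=seed, config=cfg)
    if cfg.cough_times:
        record = inject_cough(record, list(cfg.cough_times),
                              cfg.cough_amplitude * cfg.s1_amplitude)
    return record


def inject_cough(record: SimRecord, times: list[float], amplitude: float,
                 duration: float = 0.3) -> SimRecord:
    """Add broadband cough transients to the raw audio and accelerometer.

    A cough is an enveloped white-noise burst, far louder than S1, that
    spectrally overlaps the heart-sound band and corrupts S1/S2 cues.  The
    returned record is a copy; cough onset times are appended to the event
    log under ``"cough"``.
    """
    rec_duration = len(record.raw_audio) / record.raw_audio.fs
    for ct in times:
        if not (0.0 <= ct <= rec_duration):
            raise InputError(f"cough time {ct}s outside record of {rec_duration}s")
    out = copy.deepcopy(record)
    rng = np.random.default_rng(np.random.SeedSequence([record.seed, 0xC0F]))
    for ct in sorted(times):
        # audio burst
        fs_a = out.raw_audio.fs
        n_burst = int(round(duration * fs_a))
        lo = int(round(ct * fs_a))
        hi = min(lo + n_burst, len(out.raw_audio))
        window = np.hanning(n_burst)[: hi - lo]
        out.raw_audio.samples[lo:hi] += (amplitude * window *
                                         rng.standard_normal(hi - lo))
        # mechanical burst (chest wall moves too), scaled to the SCG amplitude
        fs = out.raw_accel.fs
        n_b = int(round(duration * fs))
        lo_b = int(round(ct * fs))
        hi_b = min(lo_b + n_b, len(out.raw_accel))
        window_b = np.hanning(n_b)[: hi_b - lo_b]
        mech_amp = amplitude * out.config.ao_amplitude / out.config.s1_amplitude
        out.raw_accel.az[lo_b:hi_b] += (5.0 * mech_amp * window_b *
                                        rng.standard_normal(hi_b - lo_b))
    existing = out.event_log.get("cough", np.empty(0))
    out.event_log["cough"] = np.sort(np.concatenate([existing, np.asarray(times,
                                                                          dtype=float)]))
    return out


def make_dataset(cfg: SimConfig, n_subjects: int, seed: int) -> list[SimRecord]:
    """Simulate a cohort with per-subject morphology and timing variation.

    Each subject draws, once, an R-peak amplitude factor (lognormal, ~10%),
    a resting heart-rate mean (+- 8 bpm uniform), and small jitters of the
    electromechanical delays; records are then simulated with per-subject
    seeds spawned from the master seed.
    """
    if n_subjects < 1:
        raise InputError("n_subjects must be >= 1")
    master = np.random.SeedSequence(seed)
    records = []
    for i, child in enumerate(master.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        morphology = {k: replace(w) for k, w in cfg.morphology.items()}
        amp_factor = float(rng.lognormal(mean=0.0, sigma=0.1))
        for wave in morphology.values():
            wave.amplitude *= amp_factor
        hr_mean = cfg.heart_rate[0] + float(rng.uniform(-8.0, 8.0))
        sub_cfg = replace(
            cfg,
            morphology=morphology,
            heart_rate=(hr_mean, cfg.heart_rate[1]),
            ao_after_r=cfg.ao_after_r * float(rng.uniform(0.9, 1.1)),
            s1_after_qrs_onset=cfg.s1_after_qrs_onset * float(rng.uniform(0.9, 1.1)),
        )
        record_seed = int(rng.integers(0, 2**31 - 1))
        records.append(simulate_record(sub_cfg, seed=record_seed,
                                       subject_id=f"S{i + 1:02d}"))
    return records


def to_cardiac_record(record: SimRecord, window_len: int = 1000,
                      angles: str = "estimated") -> CardiacRecord:
    """Run the raw simulated streams through the preprocessing chains.

    ``angles``: ``"estimated"`` uses the full tilt-estimation + Kalman path;
    ``"true"`` bypasses it with the simulator's exact tilt schedule.  The
    reference ECG stays in mV (standardization happens per training
    window downstream).
    """
    from .scg_preprocess import preprocess_scg
    from .signals_io import align_and_segment
    if angles not in ("estimated", "true"):
        raise ConfigError(f"angles must be 'estimated' or 'true', got {angles!r}")
    known = record.angles_true if angles == "true" else None
    scg, _ = preprocess_scg(record.raw_accel, angles=known)
    pcg = preprocess_pcg(record.raw_audio, PcgConfig())
    return align_and_segment(scg, pcg, record.truth.ecg, window_len=window_len,
                             subject_id=record.truth.subject_id)


def write_session(record: SimRecord, directory) -> Path:
    """Write a simulated session in the exact formats the readers consume.

    Emits ``pcg.wav``, ``accel.csv``, ``ecg.csv``, ``events.csv`` and a
    ``manifest.txt`` binding them; returns the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_pcg_wav(directory / "pcg.wav", record.raw_audio)
    write_accel_table(directory / "accel.csv", record.raw_accel)
    assert record.truth.ecg is not None
    write_ecg_table(directory / "ecg.csv", record.truth.ecg)
    record.events_frame().to_csv(directory / "events.csv", index=False)
    manifest = directory / "manifest.txt"
    write_manifest(manifest, {
        "subject_id": record.truth.subject_id,
        "accel": "accel.csv",
        "pcg": "pcg.wav",
        "ecg": "ecg.csv",
        "seed": record.seed,
    })
    return manifest
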