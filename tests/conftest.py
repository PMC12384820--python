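"""Shared fixtures: simulated records and a small trained model.

Expensive artifacts (simulated cohorts, one trained network) are
session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from mechanoecg.cardiac_simulator import (SimConfig, make_dataset,
                                          simulate_record, to_cardiac_record)
from mechanoecg.fusion_model import train
from mechanoecg.presets import (study_model_config, study_sim_config,
                                study_train_config)


@pytest.fixture(scope="session")
def quiet_sim_config() -> SimConfig:
    """Noise-free, fixed-tilt conditions for signal-recovery tests."""
    return SimConfig(duration=20.0, heart_rate=(60.0, 0.0),
                     accel_noise_sd=0.0, audio_noise_sd=0.0,
                     tilt_amplitude=0.0, respiration_amplitude=0.0)


@pytest.fixture(scope="session")
def quiet_record(quiet_sim_config):
    return simulate_record(quiet_sim_config, seed=11)


@pytest.fixture(scope="session")
def default_record():
    """One record under the default (noisy, tilting, breathing) conditions."""
    return simulate_record(study_sim_config(), seed=23)


@pytest.fixture(scope="session")
def small_cohort():
    """Four simulated subjects preprocessed into aligned 1 s-window records."""
    sims = make_dataset(study_sim_config(duration=16.0), n_subjects=4, seed=5)
    return sims, [to_cardiac_record(s, window_len=250) for s in sims]


@pytest.fixture(scope="session")
def trained_small_model(small_cohort):
    """A small BiLSTM-transformer trained on the 4-subject cohort."""
    _, records = small_cohort
    return train(records, study_model_config(),
                 study_train_config(epochs=12, seed=3))
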