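"""Study-scale presets shared by the test-bench and the evaluation scripts.

The default :class:`~mechanoecg.fusion_model.ModelConfig` carries the full
reference architecture (2x128 BiLSTM, d_model 256, four transformer
layers).  For the simulated desk-scale studies in this repository we train
a proportionally reduced model on shorter windows: the simulated mapping
(two clean-ish channels, Gaussian-wave ECG) has far lower intrinsic
dimensionality than real multi-subject recordings, and the reduced model
keeps a full training-plus-ablation study on one CPU in minutes while
exercising every architectural component.
"""

from __future__ import annotations

from .cardiac_simulator import SimConfig
from .fusion_model import ModelConfig, TrainConfig

__all__ = ["study_model_config", "study_train_config", "study_sim_config"]

#: Window length for desk-scale studies: 1 s at 250 Hz (>= 1 cardiac cycle).
STUDY_WINDOW = 250


def study_model_config(**overrides) -> ModelConfig:
    """Reduced architecture: same topology, ~1/5 width, 1 s windows."""
    kw = dict(lstm_hidden=24, d_model=48, n_transformer_layers=2, n_heads=4,
              ffn_dim=96, decoder_hidden=32, window_len=STUDY_WINDOW)
    kw.update(overrides)
    return ModelConfig(**kw)


def study_train_config(**overrides) -> TrainConfig:
    """Training protocol at study scale.

    Batch size 8 bounds the O(batch * heads * T^2) attention memory; the
    learning rate 3e-3 compensates for the smaller batches.
    """
    kw = dict(lr=3e-3, batch_size=8, epochs=15, seed=0)
    kw.update(overrides)
    return TrainConfig(**kw)


def study_sim_config(**overrides) -> SimConfig:
    """Simulation conditions for model studies (defaults of SimConfig)."""
    kw = dict(duration=20.0)
    kw.update(overrides)
    return SimConfig(**kw)
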