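"""Hybrid BiLSTM-transformer sequence-to-sequence ECG regressor.

Architecture: the PCG and SCG channels are fused at the feature dimension
(early fusion), encoded by two stacked bidirectional LSTM layers (local
temporal context), projected to the model dimension, summed with sinusoidal
positional encodings, refined by a stack of transformer encoder layers
(global self-attention aligning acoustic and vibrational events), and
decoded by a time-distributed MLP producing one ECG amplitude per input
time step.

Training minimizes the MSE between the predicted and reference ECG with
Adam (initial learning rate 1e-3, halved after plateaus of the validation
loss), on an 80/20 record-level split so no recording contributes windows
to both sides.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError, InputError
from .nn.autograd import Tensor, no_grad
from .nn.layers import (BiLSTM, Dropout, Linear, Module, TransformerEncoderLayer,
                        positional_encoding)  # noqa: F401  (re-exported)
from .types import CardiacRecord, UniformSeries

__all__ = ["ModelConfig", "TrainConfig", "EcgRegressor", "TrainedModel",
           "fuse_inputs", "positional_encoding", "train", "reconstruct",
           "saliency_map", "save_checkpoint", "load_checkpoint"]

_STD_EPS = 1e-8


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the reference design: two stacked BiLSTM layers with
    128 hidden units per direction (dropout 0.2 after each), a linear
    projection to ``d_model`` = 256 (the natural size of the concatenated
    bidirectional state), four transformer encoder layers with 8 heads and
    a 4x feed-forward expansion (dropout 0.1), and a 128-unit ReLU MLP
    decoder with a scalar output head.
    """

    lstm_layers: int = 2
    lstm_hidden: int = 128
    lstm_dropout: float = 0.2
    d_model: int = 256
    n_transformer_layers: int = 4
    n_heads: int = 8
    ffn_dim: int = 1024
    transformer_dropout: float = 0.1
    decoder_hidden: int = 128
    window_len: int = 1000
    fusion: str = "early"

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ConfigError(
                f"d_model {self.d_model} must be divisible by n_heads {self.n_heads}")
        for name in ("lstm_layers", "lstm_hidden", "d_model", "n_transformer_layers",
                     "n_heads", "ffn_dim", "decoder_hidden", "window_len"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.fusion not in ("early", "per_modality"):
            raise ConfigError(f"unknown fusion mode {self.fusion!r}")


@dataclass
class TrainConfig:
    """Optimization protocol."""

    lr: float = 1e-3
    batch_size: int = 64
    split: float = 0.8
    epochs: int = 30
    seed: int = 0
    lr_decay: float = 0.5
    lr_patience: int = 10
    mask: str = "none"  # none | scg_only | pcg_only (modality ablations)

    def __post_init__(self) -> None:
        if not (0.0 < self.split < 1.0):
            raise ConfigError(f"split must be in (0, 1), got {self.split}")
        if self.lr <= 0:
            raise ConfigError("lr must be positive")
        if self.mask not in ("none", "scg_only", "pcg_only"):
            raise ConfigError(f"unknown mask {self.mask!r}")


def fuse_inputs(scg_window: np.ndarray, pcg_window: np.ndarray,
                mode: str = "early", mask: str = "none") -> np.ndarray:
    """Stack the two channels per time step into a (T, 2) matrix.

    Column order is fixed as ``(pcg, scg)``.  ``mask`` zeroes the absent
    channel for single-modality baselines: ``scg_only`` zeroes the PCG
    column, ``pcg_only`` the SCG column.
    """
    scg_window = np.asarray(scg_window, dtype=np.float64)
    pcg_window = np.asarray(pcg_window, dtype=np.float64)
    if scg_window.shape != pcg_window.shape:
        raise InputError(
            f"window length mismatch: scg {scg_window.shape} vs pcg "
            f"{pcg_window.shape}")
    fused = np.stack([pcg_window, scg_window], axis=-1)
    if mask == "scg_only":
        fused[..., 0] = 0.0
    elif mask == "pcg_only":
        fused[..., 1] = 0.0
    elif mask != "none":
        raise InputError(f"unknown mask {mask!r}")
    return fused


class EcgRegressor(Module):
    """The network itself.  Instantiate with a seeded Generator."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.rng = rng
        h = cfg.lstm_hidden
        if cfg.fusion == "early":
            self.encoders = [self._make_lstm_stack(rng, 2, h)]
            enc_out = 2 * h
        else:  # per-modality encoders, outputs concatenated
            self.encoders = [self._make_lstm_stack(rng, 1, h),
                             self._make_lstm_stack(rng, 1, h)]
            enc_out = 4 * h
        self.project = Linear(rng, enc_out, cfg.d_model)
        self.pe = positional_encoding(cfg.window_len, cfg.d_model)
        self.layers = [TransformerEncoderLayer(rng, cfg.d_model, cfg.n_heads,
                                               cfg.ffn_dim, cfg.transformer_dropout)
                       for _ in range(cfg.n_transformer_layers)]
        self.dec_hidden = Linear(rng, cfg.d_model, cfg.decoder_hidden)
        self.dec_out = Linear(rng, cfg.decoder_hidden, 1)

    @staticmethod
    def _make_lstm_stack(rng, n_in: int, hidden: int) -> list[Module]:
        stack: list[Module] = []
        cfg_in = n_in
        for _ in range(2):
            stack.append(BiLSTM(rng, cfg_in, hidden))
            cfg_in = 2 * hidden
        return stack

    def parameters(self) -> list[Tensor]:
        params = []
        for enc in self.encoders:
            for layer in enc:
                params.extend(layer.parameters())
        params.extend(self.project.parameters())
        for layer in self.layers:
            params.extend(layer.parameters())
        params.extend(self.dec_hidden.parameters())
        params.extend(self.dec_out.parameters())
        return params

    def set_training(self, flag: bool) -> None:
        super().set_training(flag)
        for enc in self.encoders:
            for layer in enc:
                layer.set_training(flag)
        for layer in self.layers:
            layer.set_training(flag)

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def _dropout(self, x: Tensor, rate: float) -> Tensor:
        if not self.training or rate <= 0.0:
            return x
        keep = 1.0 - rate
        mask = (self.rng.random(x.data.shape) < keep) / keep
        return x * Tensor(mask)

    def __call__(self, fused: Tensor) -> Tensor:
        """(B, T, 2) -> (B, T) predicted ECG amplitudes."""
        batch, steps, _ = fused.data.shape
        if steps > self.cfg.window_len:
            raise InputError(
                f"window of {steps} samples exceeds the positional-encoding "
                f"table ({self.cfg.window_len} samples)")
        if self.cfg.fusion == "early":
            x = fused
            for layer in self.encoders[0]:
                x = self._dropout(layer(x), self.cfg.lstm_dropout)
        else:
            streams = []
            for ch, enc in enumerate(self.encoders):
                x = fused[:, :, ch:ch + 1]
                for layer in enc:
                    x = self._dropout(layer(x), self.cfg.lstm_dropout)
                streams.append(x)
            from .nn.autograd import concat
            x = concat(streams, axis=-1)
        x = self.project(x) + Tensor(self.pe[:steps])
        for layer in self.layers:
            x = layer(x)
        x = self.dec_hidden(x).relu()
        x = self.dec_out(x)
        return x.reshape(batch, steps)


@dataclass
class TrainedModel:
    """A trained network plus its full provenance."""

    config: ModelConfig
    train_config: TrainConfig
    network: EcgRegressor
    history: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def forward(self, fused: np.ndarray, chunk: int = 16) -> np.ndarray:
        """Deterministic evaluation-mode forward pass.

        ``fused``: (T, 2) or (B, T, 2); returns matching (T,) or (B, T).
        Batches are processed in chunks to bound the attention-score
        memory (O(chunk * heads * T^2)).
        """
        single = fused.ndim == 2
        if single:
            fused = fused[None, :, :]
        self.network.set_training(False)
        with no_grad():
            parts = [self.network(Tensor(fused[i:i + chunk])).data
                     for i in range(0, fused.shape[0], chunk)]
        out = np.concatenate(parts, axis=0)
        return out[0] if single else out


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params: Sequence[Tensor], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            m_hat = self.m[i] / (1 - b1 ** self.t)
            v_hat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def _standardize_windows(windows: np.ndarray) -> np.ndarray:
    """Per-window standardization with a variance floor (training windows of
    a quiet channel can be near-constant)."""
    mean = windows.mean(axis=1, keepdims=True)
    sd = windows.std(axis=1, keepdims=True)
    return (windows - mean) / np.maximum(sd, _STD_EPS)


def assemble_windows(records: Sequence[CardiacRecord], mask: str = "none",
                     fusion: str = "early") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack per-record windows into (X, y, record_index) training arrays.

    X: (N, T, 2) fused inputs, y: (N, T) standardized ECG targets; every
    window of every channel is standardized independently.
    """
    xs, ys, idx = [], [], []
    for k, record in enumerate(records):
        if record.ecg is None:
            raise InputError(f"record {record.subject_id} has no reference ECG")
        scg_w, pcg_w, ecg_w = record.windows()
        if scg_w.shape[0] == 0:
            continue
        fused = fuse_inputs(_standardize_windows(scg_w),
                            _standardize_windows(pcg_w), mode=fusion, mask=mask)
        xs.append(fused)
        ys.append(_standardize_windows(ecg_w))
        idx.extend([k] * fused.shape[0])
    if not xs:
        raise InputError("no training windows could be assembled")
    return np.concatenate(xs), np.concatenate(ys), np.asarray(idx)


def _record_split(n_records: int, split: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    order = rng.permutation(n_records)
    n_train = int(round(split * n_records))
    n_train = min(max(n_train, 1), n_records - 1) if n_records > 1 else 1
    return np.sort(order[:n_train]), np.sort(order[n_train:])


def _mse(pred: np.ndarray, target: np.ndarray) -> float:
    return float(np.mean((pred - target) ** 2))


def train(dataset: Sequence[CardiacRecord], mcfg: ModelConfig,
          tcfg: TrainConfig, verbose: bool = False) -> TrainedModel:
    """Train the regressor on simulated or recorded cardiac records.

    The 80/20 split is at record level to avoid temporal leakage between
    train and test windows of the same recording.  Each epoch logs train
    and validation MSE; the parameters of the best validation epoch are
    restored at the end.  The learning rate is multiplied by ``lr_decay``
    after ``lr_patience`` epochs without validation improvement.
    """
    rng = np.random.default_rng(tcfg.seed)
    train_idx, val_idx = _record_split(len(dataset), tcfg.split, rng)
    train_records = [dataset[i] for i in train_idx]
    val_records = [dataset[i] for i in val_idx] or train_records
    x_train, y_train, _ = assemble_windows(train_records, tcfg.mask, mcfg.fusion)
    x_val, y_val, _ = assemble_windows(val_records, tcfg.mask, mcfg.fusion)
    if x_train.shape[0] < 1:
        raise InputError("training set is empty after the record-level split")

    network = EcgRegressor(mcfg, np.random.default_rng(tcfg.seed + 1))
    optimizer = Adam(network.parameters(), lr=tcfg.lr)
    history: list[dict] = []
    best_val = np.inf
    best_params: list[np.ndarray] | None = None
    stagnant = 0

    n = x_train.shape[0]
    for epoch in range(tcfg.epochs):
        network.set_training(True)
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, tcfg.batch_size):
            batch = order[start:start + tcfg.batch_size]
            fused = Tensor(x_train[batch])
            target = Tensor(y_train[batch])
            pred = network(fused)
            loss = ((pred - target) ** 2).mean()
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(float(loss.data))
        network.set_training(False)
        with no_grad():
            val_pred = np.concatenate(
                [network(Tensor(x_val[i:i + tcfg.batch_size])).data
                 for i in range(0, x_val.shape[0], tcfg.batch_size)], axis=0)
        val_mse = _mse(val_pred, y_val)
        train_mse = float(np.mean(epoch_losses))
        history.append({"epoch": epoch, "train_mse": train_mse,
                        "val_mse": val_mse, "lr": optimizer.lr})
        if verbose:
            print(f"epoch {epoch:3d}  train {train_mse:.5f}  val {val_mse:.5f}"
                  f"  lr {optimizer.lr:.2e}")
        if val_mse < best_val:
            best_val = val_mse
            best_params = [p.data.copy() for p in network.parameters()]
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= tcfg.lr_patience:
                optimizer.lr *= tcfg.lr_decay
                stagnant = 0

    if best_params is not None:
        for p, best in zip(network.parameters(), best_params):
            p.data[...] = best

    provenance = {
        "seed": tcfg.seed,
        "n_records": len(dataset),
        "train_records": [dataset[i].subject_id for i in train_idx],
        "val_records": [dataset[i].subject_id for i in val_idx],
        "mask": tcfg.mask,
    }
    return TrainedModel(config=mcfg, train_config=tcfg, network=network,
                        history=history, provenance=provenance)


def reconstruct(model: TrainedModel, scg: UniformSeries, pcg: UniformSeries,
                expected_fs: float = 250.0) -> UniformSeries:
    """Reconstruct an ECG estimate from preprocessed, aligned SCG and PCG.

    Inputs are windowed at the model's window length, standardized per
    window, passed through the network, and the window outputs are
    concatenated.  The result is a standardized-amplitude (a.u.) estimate;
    its length is the input length truncated to whole windows.
    """
    for name, series in (("scg", scg), ("pcg", pcg)):
        if abs(series.fs - expected_fs) > 1e-9:
            raise InputError(
                f"{name} is sampled at {series.fs} Hz; reconstruct expects "
                f"preprocessed {expected_fs} Hz input")
    n = min(len(scg), len(pcg))
    w = model.config.window_len
    n_windows = n // w
    if n_windows == 0:
        raise InputError(f"inputs shorter than one window ({w} samples)")
    scg_w = _standardize_windows(scg.samples[:n_windows * w].reshape(n_windows, w))
    pcg_w = _standardize_windows(pcg.samples[:n_windows * w].reshape(n_windows, w))
    fused = fuse_inputs(scg_w, pcg_w, mask=model.train_config.mask)
    out = model.forward(fused)
    return UniformSeries(samples=out.reshape(-1), fs=expected_fs, t0=scg.t0,
                        units="a.u.")


def saliency_map(model: TrainedModel, fused: np.ndarray,
                 output_indices: Optional[np.ndarray] = None) -> np.ndarray:
    """Gradient-magnitude attribution of outputs to input samples.

    Returns |d(sum of selected outputs)/d(input)| with the input's (T, 2)
    shape.  ``output_indices`` selects the output samples of interest
    (default: samples where the prediction exceeds 60% of its max — a
    QRS-region proxy).  Works on untrained networks too (with a warning
    upstream); gradients are always available.
    """
    if fused.ndim != 2:
        raise InputError("saliency_map expects a single (T, 2) window")
    model.network.set_training(False)
    x = Tensor(fused[None, :, :], requires_grad=True)
    pred = model.network(x)
    if output_indices is None:
        p = pred.data[0]
        output_indices = np.nonzero(p >= 0.6 * p.max())[0]
        if output_indices.size == 0:
            output_indices = np.array([int(np.argmax(p))])
    mask = np.zeros_like(pred.data)
    mask[0, np.asarray(output_indices, dtype=int)] = 1.0
    pred.backward(mask)
    assert x.grad is not None
    return np.abs(x.grad[0])


def save_checkpoint(model: TrainedModel, path) -> None:
    """Single-file .npz archive: weights + configs + history + provenance."""
    path = Path(path)
    meta = json.dumps({
        "model_config": asdict(model.config),
        "train_config": asdict(model.train_config),
        "history": model.history,
        "provenance": model.provenance,
    })
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.network.parameters())}
    np.savez(path, meta=np.array(meta), **arrays)


def load_checkpoint(path) -> TrainedModel:
    path = Path(path)
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        mcfg = ModelConfig(**meta["model_config"])
        tcfg = TrainConfig(**meta["train_config"])
        network = EcgRegressor(mcfg, np.random.default_rng(tcfg.seed + 1))
        params = network.parameters()
        for i, p in enumerate(params):
            p.data[...] = archive[f"param_{i}"]
    return TrainedModel(config=mcfg, train_config=tcfg, network=network,
                        history=meta["history"], provenance=meta["provenance"])
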