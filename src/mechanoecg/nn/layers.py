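"""Neural-network building blocks for the BiLSTM-transformer regressor."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, layer_norm, lstm_sequence, softmax

__all__ = ["Module", "Linear", "BiLSTM", "LayerNorm", "Dropout",
           "MultiHeadSelfAttention", "TransformerEncoderLayer",
           "positional_encoding"]


class Module:
    """Base class: parameter collection and train/eval mode switching."""

    def __init__(self) -> None:
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for value in self.__dict__.values():
            if isinstance(value, Module):
                value.set_training(flag)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.set_training(flag)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        super().__init__()
        self.w = Tensor(_glorot(rng, n_in, n_out, (n_in, n_out)),
                        requires_grad=True, name="linear.w")
        self.b = Tensor(np.zeros(n_out), requires_grad=True, name="linear.b")

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    @property
    def n_params(self) -> int:
        return self.w.data.size + self.b.data.size


class _LSTMDirection(Module):
    def __init__(self, rng: np.random.Generator, n_in: int, hidden: int):
        super().__init__()
        self.hidden = hidden
        self.w = Tensor(_glorot(rng, n_in, 4 * hidden, (n_in, 4 * hidden)),
                        requires_grad=True, name="lstm.w")
        self.u = Tensor(_glorot(rng, hidden, 4 * hidden, (hidden, 4 * hidden)),
                        requires_grad=True, name="lstm.u")
        bias = np.zeros(4 * hidden)
        bias[hidden:2 * hidden] = 1.0  # forget-gate bias: remember by default
        self.b = Tensor(bias, requires_grad=True, name="lstm.b")

    def __call__(self, x: Tensor) -> Tensor:
        return lstm_sequence(x, self.w, self.u, self.b)


class BiLSTM(Module):
    """One bidirectional LSTM layer; output feature size is 2 * hidden."""

    def __init__(self, rng: np.random.Generator, n_in: int, hidden: int):
        super().__init__()
        self.fwd = _LSTMDirection(rng, n_in, hidden)
        self.bwd = _LSTMDirection(rng, n_in, hidden)

    def __call__(self, x: Tensor) -> Tensor:
        forward = self.fwd(x)
        backward = self.bwd(x.flip(axis=1)).flip(axis=1)
        return concat([forward, backward], axis=-1)


class LayerNorm(Module):
    def __init__(self, size: int):
        super().__init__()
        self.gamma = Tensor(np.ones(size), requires_grad=True, name="ln.gamma")
        self.beta = Tensor(np.zeros(size), requires_grad=True, name="ln.beta")

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


class Dropout(Module):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.data.shape) < keep) / keep
        return x * Tensor(mask)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention with ``n_heads`` parallel heads."""

    def __init__(self, rng: np.random.Generator, d_model: int, n_heads: int):
        super().__init__()
        if d_model % n_heads != 0:
            raise ValueError(f"d_model {d_model} not divisible by n_heads {n_heads}")
        self.d_model = d_model
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(rng, d_model, d_model)
        self.wk = Linear(rng, d_model, d_model)
        self.wv = Linear(rng, d_model, d_model)
        self.wo = Linear(rng, d_model, d_model)

    def _split(self, x: Tensor, batch: int, steps: int) -> Tensor:
        # (B, T, D) -> (B, h, T, d_head)
        return x.reshape(batch, steps, self.n_heads, self.d_head).swapaxes(1, 2)

    def __call__(self, x: Tensor) -> Tensor:
        batch, steps, _ = x.data.shape
        q = self._split(self.wq(x), batch, steps)
        k = self._split(self.wk(x), batch, steps)
        v = self._split(self.wv(x), batch, steps)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.d_head))
        attn = softmax(scores, axis=-1)
        context = attn @ v  # (B, h, T, d_head)
        merged = context.swapaxes(1, 2).reshape(batch, steps, self.d_model)
        return self.wo(merged)


class FeedForward(Module):
    """Position-wise feed-forward network: Linear -> ReLU -> Linear."""

    def __init__(self, rng: np.random.Generator, d_model: int, ffn_dim: int):
        super().__init__()
        self.lin1 = Linear(rng, d_model, ffn_dim)
        self.lin2 = Linear(rng, ffn_dim, d_model)

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin2(self.lin1(x).relu())


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer: residual + layer norm around both the
    self-attention and feed-forward sublayers, dropout after each."""

    def __init__(self, rng: np.random.Generator, d_model: int, n_heads: int,
                 ffn_dim: int, dropout: float):
        super().__init__()
        self.attn = MultiHeadSelfAttention(rng, d_model, n_heads)
        self.ffn = FeedForward(rng, d_model, ffn_dim)
        self.norm1 = LayerNorm(d_model)
        self.norm2 = LayerNorm(d_model)
        self.drop1 = Dropout(dropout, rng)
        self.drop2 = Dropout(dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.drop1(self.attn(x)))
        x = self.norm2(x + self.drop2(self.ffn(x)))
        return x


def positional_encoding(n_steps: int, d_model: int) -> np.ndarray:
    """Sinusoidal positional-encoding table of shape (n_steps, d_model).

    Even columns carry ``sin(t / 10000^(2k/d))``, odd columns the matching
    cosine, giving each position a unique phase pattern across a geometric
    progression of wavelengths.
    """
    if n_steps < 1 or d_model < 1:
        raise ValueError("n_steps and d_model must be positive")
    position = np.arange(n_steps)[:, None].astype(np.float64)
    k = np.arange(0, d_model, 2).astype(np.float64)
    rate = np.power(10000.0, -k / d_model)
    table = np.zeros((n_steps, d_model))
    table[:, 0::2] = np.sin(position * rate)
    table[:, 1::2] = np.cos(position * rate[: table[:, 1::2].shape[1]])
    return table
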