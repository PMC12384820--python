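"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float64 ndarray and records the operations
applied to it; :meth:`Tensor.backward` walks the tape in reverse
topological order accumulating gradients.  Only the primitives the
BiLSTM-transformer regressor needs are implemented, plus fused nodes
(LSTM sequence, layer norm, softmax) whose hand-written backward passes
keep the tape short and the recurrent backprop-through-time loop in
numpy rather than in graph nodes.

Shapes follow the (batch, time, feature) convention used by the model.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "concat", "softmax", "layer_norm", "lstm_sequence",
           "no_grad"]

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable tape recording (evaluation-mode forward passes).

    Inside the context no operation stores a backward closure or parent
    references, so eval forwards allocate nothing beyond their outputs.
    """
    global _GRAD_ENABLED
    previous = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = previous


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A node in the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False,
                 _prev: tuple = (), name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._backward: Callable[[], None] | None = None
        self._prev = _prev if self.requires_grad else ()
        self.name = name

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._prev:
                if id(parent) not in seen:
                    stack.append((parent, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
        # Release the tape: the backward closures close over their output
        # tensors, forming reference cycles that would otherwise wait for
        # the garbage collector while holding large activation arrays.
        for node in topo:
            node._backward = None
            node._prev = ()
            if not node.requires_grad:
                node.grad = None

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     _prev=(self, other))

        def _backward():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad, other.data.shape))

        if out.requires_grad:
            out._backward = _backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accumulate(-out.grad)

        if out.requires_grad:
            out._backward = _backward
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     _prev=(self, other))

        def _backward():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad * self.data, other.data.shape))

        if out.requires_grad:
            out._backward = _backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar: float):
        return self * (1.0 / scalar)

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accumulate(out.grad * p * self.data ** (p - 1))

        if out.requires_grad:
            out._backward = _backward
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(np.matmul(self.data, other.data),
                     self.requires_grad or other.requires_grad,
                     _prev=(self, other))

        def _backward():
            if self.requires_grad:
                grad = np.matmul(out.grad, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(grad, self.data.shape))
            if other.requires_grad:
                grad = np.matmul(np.swapaxes(self.data, -1, -2), out.grad)
                other._accumulate(_unbroadcast(grad, other.data.shape))

        if out.requires_grad:
            out._backward = _backward
        return out

    # -- nonlinearities ---------------------------------------------------
    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, self.requires_grad, _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accumulate(out.grad * (1.0 - y * y))

        if out.requires_grad:
            out._backward = _backward
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, self.requires_grad, _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accumulate(out.grad * y * (1.0 - y))

        if out.requires_grad:
            out._backward = _backward
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accumulate(out.grad * mask)

        if out.requires_grad:
            out._backward = _backward
        return out

    # -- reductions / shape -----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, _prev=(self,))

        def _backward():
            if self.requires_grad:
                grad = out.grad
                if axis is not None and not keepdims:
                    grad = np.expand_dims(grad, axis)
                self._accumulate(np.broadcast_to(grad, self.data.shape).copy())

        if out.requires_grad:
            out._backward = _backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accumulate(out.grad.reshape(self.data.shape))

        if out.requires_grad:
            out._backward = _backward
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), self.requires_grad, _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accumulate(np.swapaxes(out.grad, a, b))

        if out.requires_grad:
            out._backward = _backward
        return out

    def flip(self, axis: int):
        out = Tensor(np.flip(self.data, axis=axis), self.requires_grad, _prev=(self,))

        def _backward():
            if self.requires_grad:
                self._accumulate(np.flip(out.grad, axis=axis))

        if out.requires_grad:
            out._backward = _backward
        return out

    def __getitem__(self, index):
        out = Tensor(self.data[index], self.requires_grad, _prev=(self,))

        def _backward():
            if self.requires_grad:
                grad = np.zeros_like(self.data)
                np.add.at(grad, index, out.grad)
                self._accumulate(grad)

        if out.requires_grad:
            out._backward = _backward
        return out

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis``."""
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _backward():
        grad = np.moveaxis(out.grad, axis, 0)
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t._accumulate(np.moveaxis(grad[lo:hi], 0, axis))

    if out.requires_grad:
        out._backward = _backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax with a fused backward pass."""
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, x.requires_grad, _prev=(x,))

    def _backward():
        if x.requires_grad:
            g = out.grad
            x._accumulate(y * (g - (g * y).sum(axis=axis, keepdims=True)))

    if out.requires_grad:
        out._backward = _backward
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with affine parameters."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(xhat * gamma.data + beta.data,
                 x.requires_grad or gamma.requires_grad or beta.requires_grad,
                 _prev=(x, gamma, beta))

    def _backward():
        g = out.grad
        if gamma.requires_grad:
            gamma._accumulate(_unbroadcast(g * xhat, gamma.data.shape))
        if beta.requires_grad:
            beta._accumulate(_unbroadcast(g, beta.data.shape))
        if x.requires_grad:
            gx = g * gamma.data
            x._accumulate(inv * (gx - gx.mean(axis=-1, keepdims=True)
                                 - xhat * (gx * xhat).mean(axis=-1, keepdims=True)))

    if out.requires_grad:
        out._backward = _backward
    return out


def lstm_sequence(x: Tensor, w: Tensor, u: Tensor, b: Tensor) -> Tensor:
    """Run a unidirectional LSTM over a (B, T, I) input; returns (B, T, H).

    ``w``: (I, 4H) input weights, ``u``: (H, 4H) recurrent weights, ``b``:
    (4H,) bias, gates ordered (input, forget, cell, output).  The whole
    sequence is one tape node with a hand-written backprop-through-time
    pass, so the recurrence runs as a numpy loop instead of thousands of
    graph nodes.
    """
    xb, wb, ub, bb = x.data, w.data, u.data, b.data
    batch, steps, _ = xb.shape
    hidden = ub.shape[0]
    h = np.zeros((batch, hidden))
    c = np.zeros((batch, hidden))
    hs = np.empty((batch, steps, hidden))
    cache = []
    x_proj = xb @ wb + bb  # (B, T, 4H), hoisted out of the loop
    for t in range(steps):
        z = x_proj[:, t, :] + h @ ub
        i = 1.0 / (1.0 + np.exp(-z[:, :hidden]))
        f = 1.0 / (1.0 + np.exp(-z[:, hidden:2 * hidden]))
        g = np.tanh(z[:, 2 * hidden:3 * hidden])
        o = 1.0 / (1.0 + np.exp(-z[:, 3 * hidden:]))
        c_prev, h_prev = c, h
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h = o * tc
        hs[:, t, :] = h
        cache.append((i, f, g, o, c_prev, h_prev, tc))

    out = Tensor(hs, x.requires_grad or w.requires_grad or u.requires_grad
                 or b.requires_grad, _prev=(x, w, u, b))

    def _backward():
        dh_seq = out.grad
        dw = np.zeros_like(wb)
        du = np.zeros_like(ub)
        db = np.zeros_like(bb)
        dx = np.zeros_like(xb)
        dh_next = np.zeros((batch, hidden))
        dc_next = np.zeros((batch, hidden))
        for t in range(steps - 1, -1, -1):
            i, f, g, o, c_prev, h_prev, tc = cache[t]
            dh = dh_seq[:, t, :] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([di * i * (1.0 - i),
                                 df * f * (1.0 - f),
                                 dg * (1.0 - g * g),
                                 do * o * (1.0 - o)], axis=1)
            dx[:, t, :] = dz @ wb.T
            dw += xb[:, t, :].T @ dz
            du += h_prev.T @ dz
            db += dz.sum(axis=0)
            dh_next = dz @ ub.T
            dc_next = dc * f
        if x.requires_grad:
            x._accumulate(dx)
        if w.requires_grad:
            w._accumulate(dw)
        if u.requires_grad:
            u._accumulate(du)
        if b.requires_grad:
            b._accumulate(db)

    if out.requires_grad:
        out._backward = _backward
    return out
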