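"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small, dependency-free tape autograd providing exactly the primitives the
graph attention network needs: dense matmul, broadcast add/mul/div,
(leaky-)ReLU, exp, row gather, segment sum/max scatter ops, concatenation
and reductions.  Everything is float64.  Gradient correctness is pinned by
finite-difference checks in the test suite.

Conventions: ``segment_sum(x, seg, n)`` adds row i of x into output row
seg[i]; ``segment_max`` routes its gradient to the first maximising row of
each segment (deterministic tie-break).  The softmax max-shift used for
numerical stability is treated as a constant, which leaves gradients exact.
"""

from __future__ import annotations

import contextlib
import math
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording (inference): no closures, no cycles."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    g = grad
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward: Optional[Callable[[], None]] = None
        self._prev: tuple[Tensor, ...] = ()

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            # copy: g may be a view into a consumer's gradient
            self.grad = np.array(g, dtype=float)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += g

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [t]
            while stack:
                node = stack[-1]
                if id(node) in seen:
                    stack.pop()
                    continue
                unvisited = [p for p in node._prev if id(p) not in seen]
                if unvisited:
                    stack.extend(unvisited)
                else:
                    seen.add(id(node))
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()
        # sever the graph: closures reference their own output tensor, so
        # every op node is a reference cycle; breaking it here lets plain
        # refcounting reclaim intermediate arrays immediately
        for node in topo:
            node._backward = None
            node._prev = ()

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        out = _node(self.data + other.data, (self, other))

        def back():
            if self.requires_grad or self._prev:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad or other._prev:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        _set_backward(out, back)
        return out

    def __sub__(self, other: "Tensor") -> "Tensor":
        return self + (other * -1.0)

    def __mul__(self, other) -> "Tensor":
        other = _as_tensor(other)
        out = _node(self.data * other.data, (self, other))

        def back():
            if self.requires_grad or self._prev:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad or other._prev:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        _set_backward(out, back)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = _as_tensor(other)
        out = _node(self.data / other.data, (self, other))

        def back():
            if self.requires_grad or self._prev:
                self._accum(_unbroadcast(out.grad / other.data, self.data.shape))
            if other.requires_grad or other._prev:
                other._accum(
                    _unbroadcast(
                        -out.grad * self.data / other.data**2, other.data.shape
                    )
                )

        _set_backward(out, back)
        return out

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        out = _node(self.data @ other.data, (self, other))

        def back():
            if self.requires_grad or self._prev:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad or other._prev:
                other._accum(self.data.T @ out.grad)

        _set_backward(out, back)
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, prev: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    if _grad_enabled:
        out._prev = tuple(p for p in prev if isinstance(p, Tensor))
    return out


def _set_backward(out: Tensor, back: Callable[[], None]) -> None:
    # under no_grad the closure is never stored, so no cycle is created
    if _grad_enabled:
        out._backward = back


# -- nonlinearities ---------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    out = _node(np.maximum(x.data, 0.0), (x,))

    def back():
        x._accum(out.grad * (x.data > 0))

    _set_backward(out, back)
    return out


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    out = _node(np.where(x.data > 0, x.data, slope * x.data), (x,))

    def back():
        x._accum(out.grad * np.where(x.data > 0, 1.0, slope))

    _set_backward(out, back)
    return out


def exp(x: Tensor) -> Tensor:
    out = _node(np.exp(x.data), (x,))

    def back():
        x._accum(out.grad * out.data)

    _set_backward(out, back)
    return out


# -- gather / scatter -------------------------------------------------------

def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx, dtype=int)
    out = _node(x.data[idx], (x,))

    def back():
        g = np.zeros_like(x.data)
        np.add.at(g, idx, out.grad)
        x._accum(g)

    _set_backward(out, back)
    return out


def segment_sum(x: Tensor, seg: np.ndarray, n_segments: int) -> Tensor:
    seg = np.asarray(seg, dtype=int)
    data = np.zeros((n_segments,) + x.data.shape[1:])
    np.add.at(data, seg, x.data)
    out = _node(data, (x,))

    def back():
        x._accum(out.grad[seg])

    _set_backward(out, back)
    return out


def segment_max(x: Tensor, seg: np.ndarray, n_segments: int) -> Tensor:
    """Per-segment elementwise max; gradient flows to the first argmax row."""
    seg = np.asarray(seg, dtype=int)
    data = np.full((n_segments,) + x.data.shape[1:], -np.inf)
    np.maximum.at(data, seg, x.data)
    n_rows = x.data.shape[0]
    # first row index attaining the segment max, per (segment, column)
    winner = np.full(data.shape, n_rows, dtype=int)
    rows = np.broadcast_to(
        np.arange(n_rows).reshape((-1,) + (1,) * (x.data.ndim - 1)), x.data.shape
    )
    candidate = np.where(x.data == data[seg], rows, n_rows)
    np.minimum.at(winner, seg, candidate)
    out = _node(data, (x,))

    def back():
        g = np.zeros_like(x.data)
        valid = winner < n_rows
        cols = np.nonzero(valid)
        np.add.at(
            g,
            (winner[valid],) + cols[1:],
            out.grad[cols],
        )
        x._accum(g)

    _set_backward(out, back)
    return out


# -- shaping / reductions ---------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * out.grad.ndim
            sl[axis] = slice(lo, hi)
            t._accum(out.grad[tuple(sl)])

    _set_backward(out, back)
    return out


def mean_all(x: Tensor) -> Tensor:
    out = _node(np.array(x.data.mean()), (x,))

    def back():
        x._accum(np.full_like(x.data, float(out.grad) / x.data.size))

    _set_backward(out, back)
    return out


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - Tensor(np.asarray(target, dtype=float).reshape(pred.shape))
    return mean_all(diff * diff)


# -- parameters and optimiser -----------------------------------------------

def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: Optional[tuple] = None) -> Tensor:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    shape = shape or (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Adam:
    """Adam optimiser over a flat dict of parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
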