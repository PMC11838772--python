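"""Minimal reverse-mode automatic differentiation on numpy arrays.

The models in this package are small (a gated recurrent encoder, a couple of
affine maps) and are trained on CPU, so a compact tape-based engine over
float64 numpy arrays is sufficient and keeps every training run bit-exactly
reproducible.  Only the operations the models actually use are provided.

Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`,
which topologically sorts the tape rooted at the output scalar.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf, expit

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "gelu",
    "sigmoid",
    "tanh",
    "exp",
    "log",
    "concat",
    "stack",
    "embedding",
    "snap_to_grid",
    "grad_reverse",
    "softmax_cross_entropy",
    "huber",
]

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
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
    """A node in the autodiff tape wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- introspection -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- graph construction helpers ---------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = backward
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        out._backward = backward
        return out

    # -- reductions / reshapes ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.full_like(self.data, 1.0) * g)
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = backward
        return out

    def transpose(self, *axes):
        axes = axes or None
        out = Tensor(self.data.transpose(axes), parents=(self,))

        def backward(g):
            if self.requires_grad:
                inv = np.argsort(axes) if axes else None
                self._accumulate(g.transpose(inv))

        out._backward = backward
        return out

    # -- backprop ----------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def parameter(data) -> Tensor:
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


# -- elementwise nonlinearities ---------------------------------------------


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit.

    ``gelu(v) = v * Phi(v)``; its global minimum is about -0.16997, which
    bounds every temporal concept entry from below.
    """
    v = x.data
    cdf = 0.5 * (1.0 + erf(v * _INV_SQRT2))
    out = Tensor(v * cdf, parents=(x,))

    def backward(g):
        if x.requires_grad:
            pdf = np.exp(-0.5 * v * v) * _INV_SQRT2PI
            x._accumulate(g * (cdf + v * pdf))

    out._backward = backward
    return out


GELU_FLOOR = -0.17  # slightly below the true infimum of gelu (~ -0.16997)


def sigmoid(x: Tensor) -> Tensor:
    s = expit(x.data)
    out = Tensor(s, parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    out._backward = backward
    return out


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    out = Tensor(t, parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * (1.0 - t * t))

    out._backward = backward
    return out


def exp(x: Tensor) -> Tensor:
    e = np.exp(x.data)
    out = Tensor(e, parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * e)

    out._backward = backward
    return out


def log(x: Tensor) -> Tensor:
    out = Tensor(np.log(x.data), parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g / x.data)

    out._backward = backward
    return out


# -- structural ops ----------------------------------------------------------


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    out._backward = backward
    return out


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), parents=tensors)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    out._backward = backward
    return out


def embedding(table: Tensor, idx: np.ndarray) -> Tensor:
    """Row lookup ``table[idx]`` with scatter-add gradient."""
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(table.data[idx], parents=(table,))

    def backward(g):
        if table.requires_grad:
            full = np.zeros_like(table.data)
            np.add.at(full, idx, g)
            table._accumulate(full)

    out._backward = backward
    return out


def snap_to_grid(x: Tensor, step: float = 2.0**-26) -> Tensor:
    """Round values to exact multiples of ``step`` (straight-through gradient).

    Used by the time encoder so that sums and differences of a handful of
    embeddings incur no floating-point rounding, making time-delta algebra
    (antisymmetry, additivity) hold bit-exactly.
    """
    out = Tensor(np.round(x.data / step) * step, parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g)

    out._backward = backward
    return out


def grad_reverse(x: Tensor, lam: float) -> Tensor:
    """Identity on the forward pass; multiplies the gradient by ``-lam``."""
    out = Tensor(x.data.copy(), parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(-lam * g)

    out._backward = backward
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross entropy of integer ``labels`` under row-softmax of logits."""
    labels = np.asarray(labels, dtype=np.intp)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=-1, keepdims=True)
    n = labels.shape[0]
    nll = -np.log(p[np.arange(n), labels] + 1e-300).mean()
    out = Tensor(nll, parents=(logits,))

    def backward(g):
        if logits.requires_grad:
            grad = p.copy()
            grad[np.arange(n), labels] -= 1.0
            logits._accumulate(g * grad / n)

    out._backward = backward
    return out


def huber(residual: Tensor, delta: float = 1.0, weights: np.ndarray | None = None) -> Tensor:
    """Mean Huber loss of a residual tensor.

    Quadratic ``0.5 a^2`` for ``|a| <= delta``, linear ``delta(|a|-0.5 delta)``
    beyond.  ``weights`` (0/1 observation mask) selects which entries count;
    the mean is over counted entries only.
    """
    a = residual.data
    absa = np.abs(a)
    quad = absa <= delta
    vals = np.where(quad, 0.5 * a * a, delta * (absa - 0.5 * delta))
    if weights is None:
        w = np.ones_like(a)
    else:
        w = np.asarray(weights, dtype=np.float64)
    denom = w.sum()
    if denom <= 0:
        raise ValueError("huber loss needs at least one observed target")
    out = Tensor((vals * w).sum() / denom, parents=(residual,))

    def backward(g):
        if residual.requires_grad:
            d = np.where(quad, a, delta * np.sign(a))
            residual._accumulate(g * d * w / denom)

    out._backward = backward
    return out
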