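"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps a float64 ndarray and records the operations that
produced it; calling :meth:`Tensor.backward` on a scalar accumulates
gradients into every upstream tensor created with ``requires_grad=True``.
Only the operations needed by the synergy model are implemented; all of
them support numpy broadcasting, with gradients summed back over the
broadcast axes.

Graph recording can be suspended with :func:`no_grad` for inference.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables graph construction."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size 1 in the original
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make numpy defer binary ops to Tensor.__r*__ instead of broadcasting
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _result(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
            out.requires_grad = True
        return out

    # -- basic properties -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            _accum(self, _unbroadcast(g, self.shape))
            _accum(other, _unbroadcast(g, other.shape))

        return self._result(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            _accum(self, -g)

        return self._result(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            _accum(self, _unbroadcast(g * other.data, self.shape))
            _accum(other, _unbroadcast(g * self.data, other.shape))

        return self._result(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g):
            _accum(self, _unbroadcast(g / other.data, self.shape))
            _accum(other, _unbroadcast(-g * self.data / other.data**2, other.shape))

        return self._result(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        def backward(g):
            _accum(self, g * exponent * self.data ** (exponent - 1))

        return self._result(self.data**exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:
                _accum(self, g * b)
                _accum(other, g * a)
                return
            ga = np.matmul(g, np.swapaxes(b, -1, -2)) if b.ndim > 1 else np.outer(g, b)
            gb = np.matmul(np.swapaxes(a, -1, -2), g) if a.ndim > 1 else np.outer(a, g)
            _accum(self, _unbroadcast(ga, a.shape))
            _accum(other, _unbroadcast(gb, b.shape))

        return self._result(np.matmul(self.data, other.data), (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            _accum(self, g * out_data)

        return self._result(out_data, (self,), backward)

    def log(self):
        def backward(g):
            _accum(self, g / self.data)

        return self._result(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            _accum(self, g * (1.0 - out_data**2))

        return self._result(out_data, (self,), backward)

    def sigmoid(self):
        out_data = _sigmoid(self.data)

        def backward(g):
            _accum(self, g * out_data * (1.0 - out_data))

        return self._result(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            _accum(self, g * mask)

        return self._result(self.data * mask, (self,), backward)

    def gelu(self):
        # tanh approximation of the Gaussian error linear unit
        x = self.data
        c = np.sqrt(2.0 / np.pi)
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        out_data = 0.5 * x * (1.0 + t)

        def backward(g):
            dinner = c * (1.0 + 3 * 0.044715 * x**2)
            local = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * dinner
            _accum(self, g * local)

        return self._result(out_data, (self,), backward)

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)

        def backward(g):
            _accum(self, g * mask)

        return self._result(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                _accum(self, np.broadcast_to(g, self.shape).copy())
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            _accum(self, np.broadcast_to(gg, self.shape).copy())

        return self._result(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation ---------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            _accum(self, g.reshape(old))

        return self._result(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            _accum(self, g.transpose(inv))

        return self._result(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            _accum(self, full)

        return self._result(self.data[idx], (self,), backward)

    # -- composite primitives -------------------------------------------------

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            _accum(self, out_data * (g - dot))

        return self._result(out_data, (self,), backward)

    def masked_fill(self, mask: np.ndarray, value: float):
        """Replace entries where ``mask`` is True by ``value`` (no gradient there)."""
        out_data = np.where(mask, value, self.data)

        def backward(g):
            _accum(self, np.where(mask, 0.0, g))

        return self._result(out_data, (self,), backward)

    # -- backward pass --------------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not (t.requires_grad or t._parents):
        return
    if t.grad is None:
        t.grad = np.array(g, dtype=np.float64)
    else:
        t.grad = t.grad + g


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    return Tensor._result(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]

    def backward(g):
        for i, t in enumerate(tensors):
            _accum(t, np.take(g, i, axis=axis))

    return Tensor._result(
        np.stack([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def take_rows(weight: Tensor, indices: np.ndarray) -> Tensor:
    """Embedding lookup: gather rows of a 2-D weight by an integer index array."""
    indices = np.asarray(indices)

    def backward(g):
        full = np.zeros_like(weight.data)
        np.add.at(full, indices.ravel(), g.reshape(-1, weight.data.shape[1]))
        _accum(weight, full)

    return Tensor._result(weight.data[indices], (weight,), backward)
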