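"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tape-based engine: :class:`Tensor` wraps an
``ndarray``, records the operations applied to it, and
:meth:`Tensor.backward` accumulates gradients by walking the tape in
reverse topological order.  The operation set is exactly what the
message-passing encoder, attention readout, projection head and
feed-forward classifier need — dense linear algebra, elementwise
nonlinearities, reductions, concatenation, row gathering and segment
sums — each with a hand-written vector-Jacobian product that is
verified against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "gather_rows",
    "segment_sum",
    "relu",
    "sigmoid",
    "softmax",
    "log_softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over broadcast axes so it matches ``shape``."""
    if grad.shape == shape:
        return grad
    # collapse leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray with a gradient tape.

    Parameters
    ----------
    data:
        Array (or scalar) value.  Always stored as ``float64``.
    requires_grad:
        Whether gradients should be accumulated into ``.grad`` on
        :meth:`backward`.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = self._lift(other)

        def backward(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g):
            self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)

        def backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)

        def backward(g):
            self._accumulate(_unbroadcast(g / other.data, self.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / other.data ** 2, other.shape))

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) / self

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)

        def backward(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    def __pow__(self, p: float) -> "Tensor":
        def backward(g):
            self._accumulate(g * p * self.data ** (p - 1))

        return self._make(self.data ** p, (self,), backward)

    # -- elementwise ----------------------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g):
            self._accumulate(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self) -> "Tensor":
        return self ** 0.5

    # -- reductions / reshaping ----------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g):
            if axis is None:
                self._accumulate(np.full_like(self.data, 1.0) * g)
            else:
                g_ = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g_, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def reshape(self, *shape) -> "Tensor":
        old = self.shape

        def backward(g):
            self._accumulate(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    @property
    def T(self) -> "Tensor":
        def backward(g):
            self._accumulate(g.T)

        return self._make(self.data.T, (self,), backward)

    # ------------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of this (scalar) tensor w.r.t. the tape."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a "
                                 "scalar output")
            grad = np.ones_like(self.data)

        # topological order over the tape
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


# ----------------------------------------------------------------------
# free functions
# ----------------------------------------------------------------------

def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, backward)


def gather_rows(x: Tensor, index: np.ndarray) -> Tensor:
    """``x[index]`` along axis 0, with scatter-add backward."""
    index = np.asarray(index, dtype=np.intp)

    def backward(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, index, g)
        x._accumulate(gx)

    return Tensor._make(x.data[index], (x,), backward)


def segment_sum(x: Tensor, segment_ids: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``n_segments`` buckets given per-row ids.

    Rows whose id is negative are dropped.  Empty segments yield zero
    rows (the empty-neighbourhood convention of the encoder).
    """
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    keep = segment_ids >= 0
    out = np.zeros((n_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(out, segment_ids[keep], x.data[keep])

    def backward(g):
        gx = np.zeros_like(x.data)
        gx[keep] = g[segment_ids[keep]]
        x._accumulate(gx)

    return Tensor._make(out, (x,), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        x._accumulate(g * mask)

    return Tensor._make(np.where(mask, x.data, 0.0), (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        x._accumulate(g * out_data * (1.0 - out_data))

    return Tensor._make(out_data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis`` (max-shift is constant)."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()
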