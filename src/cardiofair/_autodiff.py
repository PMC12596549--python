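"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the recurrent classifier needs: broadcast
arithmetic, matrix products, sigmoid/tanh/log/exp, concatenation, slicing and
reductions.  Gradients are accumulated in float64 and checked against central
finite differences in the test suite.

The same forward code can run gradient-free on plain ndarrays: every helper in
:mod:`cardiofair.network` dispatches on the input type, so inference and
Shapley evaluation skip graph construction entirely.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "sigmoid", "tanh", "concat", "log", "clip"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # keep numpy from hijacking mixed ndarray/Tensor arithmetic
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # ------------------------------------------------------------------ basics
    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        rg = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=rg, parents=parents if rg else (),
                      backward=backward if rg else None)

    # -------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other)

        def backward(grad, out):
            if self.requires_grad:
                self._accum(_unbroadcast(grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(grad, other.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)

        def backward(grad, out):
            if self.requires_grad:
                self._accum(_unbroadcast(grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(grad * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        def backward(grad, out):
            if self.requires_grad:
                self._accum(-grad)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("division only supported by constants")
        return self * (1.0 / other)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(grad, out):
            if self.requires_grad:
                self._accum(grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ grad)

        return self._make(self.data @ other.data, (self, other), backward)

    def __rmatmul__(self, other):
        return self._lift(other) @ self

    def __getitem__(self, idx):
        def backward(grad, out):
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, grad)
                self._accum(g)

        return self._make(self.data[idx], (self,), backward)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        def backward(grad, out):
            if not self.requires_grad:
                return
            g = np.asarray(grad)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # ------------------------------------------------------------ nonlinearity
    def sigmoid(self):
        out_data = _np_sigmoid(self.data)

        def backward(grad, out):
            if self.requires_grad:
                self._accum(grad * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(grad, out):
            if self.requires_grad:
                self._accum(grad * (1.0 - out_data ** 2))

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(grad, out):
            if self.requires_grad:
                self._accum(grad / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(grad, out):
            if self.requires_grad:
                self._accum(grad * out_data)

        return self._make(out_data, (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp; gradient passes only where the value was not clipped."""
        mask = (self.data > lo) & (self.data < hi)

        def backward(grad, out):
            if self.requires_grad:
                self._accum(grad * mask)

        return self._make(np.clip(self.data, lo, hi), (self,), backward)

    def reshape(self, *shape):
        def backward(grad, out):
            if self.requires_grad:
                self._accum(grad.reshape(self.data.shape))

        return self._make(self.data.reshape(*shape), (self,), backward)

    # ---------------------------------------------------------------- backward
    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs from long sequences overflow recursion
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
            if node._backward is not None:
                node._backward(node.grad, node)


def _np_sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------- dispatchers
# These let one forward implementation serve both the training graph (Tensor)
# and fast gradient-free inference (ndarray).

def sigmoid(x):
    return x.sigmoid() if isinstance(x, Tensor) else _np_sigmoid(np.asarray(x, dtype=np.float64))


def tanh(x):
    return x.tanh() if isinstance(x, Tensor) else np.tanh(x)


def log(x):
    return x.log() if isinstance(x, Tensor) else np.log(x)


def clip(x, lo, hi):
    return x.clip(lo, hi) if isinstance(x, Tensor) else np.clip(x, lo, hi)


def concat(parts, axis: int = -1):
    if any(isinstance(p, Tensor) for p in parts):
        parts = [Tensor._lift(p) for p in parts]
        datas = [p.data for p in parts]
        out_data = np.concatenate(datas, axis=axis)
        sizes = [d.shape[axis] for d in datas]
        offsets = np.cumsum([0] + sizes)

        def backward(grad, out):
            gs = np.split(grad, offsets[1:-1], axis=axis)
            for p, g in zip(parts, gs):
                if p.requires_grad:
                    p._accum(g)

        rg = any(p.requires_grad for p in parts)
        return Tensor(out_data, requires_grad=rg, parents=tuple(parts) if rg else (),
                      backward=backward if rg else None)
    return np.concatenate(parts, axis=axis)
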