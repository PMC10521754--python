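"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the MMIL network needs: broadcasting
arithmetic, 2-D matrix products, elementwise nonlinearities, reductions,
reshape/transpose, concatenation, indexing and a lower clamp. Gradients are
accumulated by reverse topological traversal from a scalar output.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def _accum(t: "Tensor", g: np.ndarray) -> None:
        if t.requires_grad:
            t.grad = g if t.grad is None else t.grad + g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        for node in topo:
            node.grad = None
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- helpers -----------------------------------------------------------

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def back(g):
            Tensor._accum(a, _unbroadcast(g, a.data.shape))
            Tensor._accum(b, _unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), back)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def back(g):
            Tensor._accum(a, -g)

        return Tensor._make(-a.data, (a,), back)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def back(g):
            Tensor._accum(a, _unbroadcast(g * b.data, a.data.shape))
            Tensor._accum(b, _unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def back(g):
            Tensor._accum(a, _unbroadcast(g / b.data, a.data.shape))
            Tensor._accum(b, _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return Tensor._make(a.data / b.data, (a, b), back)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self, other
        if a.data.ndim != 2 or b.data.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")

        def back(g):
            Tensor._accum(a, g @ b.data.T)
            Tensor._accum(b, a.data.T @ g)

        return Tensor._make(a.data @ b.data, (a, b), back)

    # -- elementwise nonlinearities ---------------------------------------

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def back(g):
            Tensor._accum(a, g * out_data)

        return Tensor._make(out_data, (a,), back)

    def log(self):
        a = self

        def back(g):
            Tensor._accum(a, g / a.data)

        return Tensor._make(np.log(a.data), (a,), back)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def back(g):
            Tensor._accum(a, g * (1.0 - out_data ** 2))

        return Tensor._make(out_data, (a,), back)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def back(g):
            Tensor._accum(a, g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), back)

    def relu(self):
        a = self
        mask = a.data > 0

        def back(g):
            Tensor._accum(a, g * mask)

        return Tensor._make(a.data * mask, (a,), back)

    def clip_min(self, floor: float):
        """Lower clamp; gradient passes only through unclamped entries."""
        a = self
        mask = a.data > floor

        def back(g):
            Tensor._accum(a, g * mask)

        return Tensor._make(np.maximum(a.data, floor), (a,), back)

    # -- reductions & reshaping -------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def back(g):
            if axis is None:
                Tensor._accum(a, np.broadcast_to(g, a.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                Tensor._accum(a, np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), back)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def back(g):
            Tensor._accum(a, g.reshape(a.data.shape))

        return Tensor._make(a.data.reshape(shape), (a,), back)

    @property
    def T(self):
        a = self

        def back(g):
            Tensor._accum(a, g.T)

        return Tensor._make(a.data.T, (a,), back)

    def __getitem__(self, key):
        a = self

        def back(g):
            full = np.zeros_like(a.data)
            np.add.at(full, key, g)
            Tensor._accum(a, full)

        return Tensor._make(a.data[key], (a,), back)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            Tensor._accum(t, g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, back
    )


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax; the max-shift is treated as a constant."""
    shift = x.data.max(axis=axis, keepdims=True)
    e = (x - Tensor(shift)).exp()
    return e / e.sum(axis=axis, keepdims=True)
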