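"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A tape-based scalar-graph engine sized for the compact temporal fusion
transformer in :mod:`breakcast.forecasters.tft`: tensors wrap ``ndarray``s of
any rank, ops record their parents, and ``backward()`` runs the reverse
topological sweep.  Broadcasting follows NumPy semantics, with gradients
summed back over broadcast axes.  Only the ops the network needs exist —
this is not a general deep-learning framework.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "cat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=True):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad

    # ---- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() needs a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # ---- elementwise arithmetic -------------------------------------------

    @staticmethod
    def _wrap(x):
        return x if isinstance(x, Tensor) else Tensor(x, requires_grad=False)

    def __add__(self, other):
        o = self._wrap(other)
        out = Tensor(self.data + o.data, (self, o))

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g, o.shape))
        out._backward = back
        return out

    __radd__ = __add__

    def __mul__(self, other):
        o = self._wrap(other)
        out = Tensor(self.data * o.data, (self, o))

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * o.data, self.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g * self.data, o.shape))
        out._backward = back
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        o = self._wrap(other)
        out = Tensor(self.data / o.data, (self, o))

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / o.data, self.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(-g * self.data / (o.data ** 2), o.shape))
        out._backward = back
        return out

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, k: float):
        out = Tensor(self.data ** k, (self,))

        def back(g):
            if self.requires_grad:
                self._accum(g * k * self.data ** (k - 1))
        out._backward = back
        return out

    # ---- matmul ------------------------------------------------------------

    def __matmul__(self, other):
        o = self._wrap(other)
        out = Tensor(np.matmul(self.data, o.data), (self, o))

        def back(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(o.data, -1, -2))
                self._accum(_unbroadcast(ga, self.shape))
            if o.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                o._accum(_unbroadcast(gb, o.shape))
        out._backward = back
        return out

    # ---- nonlinearities ----------------------------------------------------

    def exp(self):
        out = Tensor(np.exp(self.data), (self,))

        def back(g):
            if self.requires_grad:
                self._accum(g * out.data)
        out._backward = back
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), (self,))

        def back(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out.data ** 2))
        out._backward = back
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), (self,))

        def back(g):
            if self.requires_grad:
                self._accum(g * out.data * (1.0 - out.data))
        out._backward = back
        return out

    def elu(self):
        pos = self.data > 0
        out = Tensor(np.where(pos, self.data, np.expm1(self.data)), (self,))

        def back(g):
            if self.requires_grad:
                self._accum(g * np.where(pos, 1.0, out.data + 1.0))
        out._backward = back
        return out

    def abs(self):
        sign = np.sign(self.data)
        out = Tensor(np.abs(self.data), (self,))

        def back(g):
            if self.requires_grad:
                self._accum(g * sign)
        out._backward = back
        return out

    # ---- reductions & shape ------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def back(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())
        out._backward = back
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))

        def back(g):
            if self.requires_grad:
                self._accum(g.reshape(self.shape))
        out._backward = back
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))

        def back(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
        out._backward = back
        return out

    def swap_last(self):
        """Transpose the last two axes (for attention score computation)."""
        out = Tensor(np.swapaxes(self.data, -1, -2), (self,))

        def back(g):
            if self.requires_grad:
                self._accum(np.swapaxes(g, -1, -2))
        out._backward = back
        return out

    def softmax(self, axis=-1, mask: np.ndarray | None = None):
        """Numerically stable softmax; ``mask`` adds -inf-like offsets (constant)."""
        z = self.data
        if mask is not None:
            z = z + mask
        z = z - z.max(axis=axis, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(p, (self,))

        def back(g):
            if self.requires_grad:
                dot = (g * p).sum(axis=axis, keepdims=True)
                self._accum(p * (g - dot))
        out._backward = back
        return out

    def dropout(self, rate: float, rng: np.random.Generator | None):
        """Inverted dropout; ``rng=None`` means evaluation mode (identity)."""
        if rng is None or rate <= 0.0:
            return self
        keep = (rng.random(self.shape) >= rate) / (1.0 - rate)
        return self * Tensor(keep, requires_grad=False)


def cat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)
    out._backward = back
    return out


def stack(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Stack equal-shape tensors along a new axis (used for LSTM outputs)."""
    expanded = []
    for t in tensors:
        shape = list(t.shape)
        shape.insert(axis if axis >= 0 else len(shape) + 1 + axis, 1)
        expanded.append(t.reshape(*shape))
    return cat(expanded, axis=axis)
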