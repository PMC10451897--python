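"""Reverse-mode automatic differentiation over numpy arrays.

A small define-by-run tape: every :class:`Tensor` records the operation
that produced it and a closure that maps the output gradient to parent
gradients.  Calling :meth:`Tensor.backward` on a scalar walks the graph
in reverse topological order and accumulates ``.grad`` on every node,
including intermediates (which is what gradient-weighted class
activation mapping needs).

All data is float64.  Shapes follow numpy broadcasting; gradients of
broadcast operands are summed back to the operand's shape.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "concat"]


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
    return grad.reshape(shape)


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = parents
        self._backward = backward

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape})"

    # -- graph construction helpers ------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)

        def bwd(g, out):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, (self,), lambda g, out: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)

        def bwd(g, out):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)

        def bwd(g, out):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")

        def bwd(g, out):
            return (g * p * self.data ** (p - 1),)

        return Tensor(self.data**p, (self,), bwd)

    def __matmul__(self, other):
        other = Tensor._lift(other)

        def bwd(g, out):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        return Tensor(self.data @ other.data, (self, other), bwd)

    # -- elementwise nonlinearities ------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor(out_data, (self,), lambda g, out: (g * out.data,))

    def log(self):
        return Tensor(np.log(self.data), (self,), lambda g, out: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor(out_data, (self,), lambda g, out: (g / (2.0 * out.data),))

    def relu(self):
        mask = self.data > 0

        def bwd(g, out):
            return (g * mask,)

        return Tensor(self.data * mask, (self,), bwd)

    def gelu(self):
        """Exact Gaussian-error-linear unit: x * Phi(x)."""
        x = self.data
        phi = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)

        def bwd(g, out):
            return (g * (phi + x * pdf),)

        return Tensor(x * phi, (self,), bwd)

    def softmax(self, axis: int = -1):
        """Numerically stable softmax along ``axis`` (fused backward)."""
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bwd(g, out):
            dot = (g * s).sum(axis=axis, keepdims=True)
            return (s * (g - dot),)

        return Tensor(s, (self,), bwd)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bwd(g, out):
            g = np.asarray(g)
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                for a in sorted(a % self.ndim for a in ax):
                    g = np.expand_dims(g, a)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape manipulation --------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bwd(g, out):
            return (g.reshape(old),)

        return Tensor(self.data.reshape(shape), (self,), bwd)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bwd(g, out):
            return (g.transpose(inv),)

        return Tensor(self.data.transpose(axes), (self,), bwd)

    def swapaxes(self, a: int, b: int):
        def bwd(g, out):
            return (np.swapaxes(g, a, b),)

        return Tensor(np.swapaxes(self.data, a, b), (self,), bwd)

    def __getitem__(self, idx):
        def bwd(g, out):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor(self.data[idx], (self,), bwd)

    # -- backward pass --------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative topo sort; graphs can be deep
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        for node in order:
            node.grad = None
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.shape)
        for node in reversed(order):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad, node)):
                if g is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient splitting."""
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g, out):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd
    )
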