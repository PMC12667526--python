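"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operator set the network needs: broadcasting
arithmetic, matmul (including batched), relu/exp/scalar-power, axis
reductions, reshape/transpose, softmax and concatenation. Gradients are
accumulated by topological traversal of the recorded operation graph.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing broadcast axes."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus the closure needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # ---- graph plumbing -------------------------------------------------

    @classmethod
    def _op(cls, data, parents, backward):
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    def _accum(self, grad):
        grad = _unbroadcast(grad, self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # ---- shape info -----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # ---- arithmetic -----------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor._op(self.data + other.data, (self, other), None)
        if out.requires_grad:
            def backward(g):
                if self.requires_grad:
                    self._accum(g)
                if other.requires_grad:
                    other._accum(g)
            out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._op(-self.data, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor._op(self.data * other.data, (self, other), None)
        if out.requires_grad:
            def backward(g):
                if self.requires_grad:
                    self._accum(g * other.data)
                if other.requires_grad:
                    other._accum(g * self.data)
            out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * (as_tensor(other) ** -1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * (self ** -1.0)

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = Tensor._op(self.data ** exponent, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(
                g * exponent * self.data ** (exponent - 1.0)
            )
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor._op(self.data @ other.data, (self, other), None)
        if out.requires_grad:
            a, b = self.data, other.data
            def backward(g):
                if self.requires_grad:
                    if b.ndim == 1:
                        self._accum(np.outer(g, b) if g.ndim else g * b)
                    else:
                        self._accum(_unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape))
                if other.requires_grad:
                    if a.ndim == 1:
                        other._accum(np.outer(a, g))
                    else:
                        other._accum(_unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape))
            out._backward = backward
        return out

    # ---- elementwise nonlinearities -------------------------------------

    def relu(self):
        out = Tensor._op(np.maximum(self.data, 0), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def exp(self):
        val = np.exp(self.data)
        out = Tensor._op(val, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * val)
        return out

    def log(self):
        out = Tensor._op(np.log(self.data), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g / self.data)
        return out

    # ---- reductions ------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor._op(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)
        if out.requires_grad:
            def backward(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---- shape ops -------------------------------------------------------

    def reshape(self, *shape):
        orig = self.data.shape
        out = Tensor._op(self.data.reshape(*shape), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(orig))
        return out

    def transpose(self, *axes):
        inverse = np.argsort(axes)
        out = Tensor._op(self.data.transpose(axes), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.transpose(inverse))
        return out

    # ---- softmax ---------------------------------------------------------

    def softmax(self, axis=-1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor._op(s, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(
                s * (g - (g * s).sum(axis=axis, keepdims=True))
            )
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def concat(tensors, axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis``; backward splits the gradient."""
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor._op(data, tuple(tensors), None)
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def backward(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)
        out._backward = backward
    return out
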