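"""Minimal reverse-mode automatic differentiation on numpy arrays.

The harmonizer's networks are small fully-connected MLPs, so a compact
tape-based autodiff is sufficient: each :class:`Tensor` records the operation
that produced it and a closure that maps the output gradient to parent
gradients.  Broadcasting follows numpy semantics; gradients of broadcast
operands are summed back to the operand's shape.

Every op is checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "logsumexp"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _make(cls, value, parents, backward) -> "Tensor":
        out = cls(value, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.value.shape

    def item(self) -> float:
        return float(self.value)

    def detach(self) -> "Tensor":
        return Tensor(self.value)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(self.value + other.value, (self, other), backward)

    __radd__ = __add__

    def __sub__(self, other):
        other = self._wrap(other)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(-g, other.shape))

        return self._make(self.value - other.value, (self, other), backward)

    def __rsub__(self, other):
        return self._wrap(other).__sub__(self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            return (
                _unbroadcast(g * other.value, self.shape),
                _unbroadcast(g * self.value, other.shape),
            )

        return self._make(self.value * other.value, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(g):
            return (
                _unbroadcast(g / other.value, self.shape),
                _unbroadcast(-g * self.value / other.value**2, other.shape),
            )

        return self._make(self.value / other.value, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other).__truediv__(self)

    def __neg__(self):
        def backward(g):
            return (-g,)

        return self._make(-self.value, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g):
            ga = g @ other.value.T if other.value.ndim == 2 else np.outer(g, other.value)
            gb = self.value.T @ g
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        return self._make(self.value @ other.value, (self, other), backward)

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.value)
            np.add.at(full, idx, g)
            return (full,)

        return self._make(self.value[idx], (self,), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def tanh(self):
        y = np.tanh(self.value)

        def backward(g):
            return (g * (1.0 - y**2),)

        return self._make(y, (self,), backward)

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.value))

        def backward(g):
            return (g * y * (1.0 - y),)

        return self._make(y, (self,), backward)

    def exp(self):
        y = np.exp(self.value)

        def backward(g):
            return (g * y,)

        return self._make(y, (self,), backward)

    def log(self):
        def backward(g):
            return (g / self.value,)

        return self._make(np.log(self.value), (self,), backward)

    def sqrt(self):
        y = np.sqrt(self.value)

        def backward(g):
            return (g / (2.0 * y),)

        return self._make(y, (self,), backward)

    def square(self):
        def backward(g):
            return (2.0 * g * self.value,)

        return self._make(self.value**2, (self,), backward)

    # -- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return self._make(self.value.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        def backward(g):
            return (g.reshape(self.shape),)

        return self._make(self.value.reshape(*shape), (self,), backward)

    def expand_dims(self, axis: int):
        def backward(g):
            return (np.squeeze(g, axis=axis),)

        return self._make(np.expand_dims(self.value, axis), (self,), backward)

    @property
    def T(self):
        def backward(g):
            return (g.T,)

        return self._make(self.value.T, (self,), backward)

    # -- backpropagation ------------------------------------------------------
    def backward(self, grad=None):
        """Accumulate gradients of `self` into every reachable requires_grad leaf."""
        if grad is None:
            grad = np.ones_like(self.value)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            t.grad = g if t.grad is None else t.grad + g
            if t._backward is None:
                continue
            for p, pg in zip(t._parents, t._backward(g)):
                if not p.requires_grad:
                    continue
                acc = grads.get(id(p))
                grads[id(p)] = pg if acc is None else acc + pg

    def zero_grad(self):
        self.grad = None


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along `axis`, splitting the gradient back."""
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.value.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(
        np.concatenate([t.value for t in tensors], axis=axis), tensors, backward
    )


def logsumexp(t: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable log-sum-exp; the max shift is treated as a constant."""
    c = np.max(t.value, axis=axis, keepdims=True)
    shifted = t - Tensor(c)
    out = shifted.exp().sum(axis=axis).log() + Tensor(np.squeeze(c, axis=axis))
    return out
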