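"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine is deliberately small: a :class:`Tensor` wraps a float64
``numpy.ndarray`` and records the operations applied to it on a tape, so
that :meth:`Tensor.backward` can accumulate gradients for every tensor
created with ``requires_grad=True``.  Only the operations needed by the
neural-process models in this package are implemented (elementwise
arithmetic with broadcasting, 2-D matrix multiplication, reshape, slicing,
reductions and a handful of nonlinearities).  All computation is
vectorized; Python-level overhead is paid per operation, not per element.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "stack", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were introduced or expanded by broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum axes that were size-1 in the original shape
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ basic
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def backward(g):
            return (_unbroadcast(g, self.data.shape),
                    _unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def backward(g):
            return (_unbroadcast(g * other.data, self.data.shape),
                    _unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) * self ** -1.0

    def __pow__(self, p: float) -> "Tensor":
        out = Tensor(self.data ** p, self.requires_grad, (self,))
        out._backward = lambda g: (g * p * self.data ** (p - 1.0),)
        return out

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        if self.data.ndim != 2 or other.data.ndim != 2:
            raise ValueError("matmul supports 2-D operands; reshape first")
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)

        out._backward = backward
        return out

    # ------------------------------------------------------------ shape ops
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        out._backward = lambda g: (g.reshape(self.data.shape),)
        return out

    def transpose(self, *axes) -> "Tensor":
        axes = axes or None
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        inv = np.argsort(axes) if axes else None
        out._backward = lambda g: (g.transpose(inv),)
        return out

    @property
    def T(self) -> "Tensor":
        return self.transpose()

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        out._backward = backward
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -------------------------------------------------------- nonlinearities
    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))
        out._backward = lambda g: (g * (self.data > 0.0),)
        return out

    def leaky_relu(self, alpha: float = 0.01) -> "Tensor":
        out = Tensor(np.where(self.data > 0.0, self.data, alpha * self.data),
                     self.requires_grad, (self,))
        out._backward = lambda g: (g * np.where(self.data > 0.0, 1.0, alpha),)
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        out = Tensor(t, self.requires_grad, (self,))
        out._backward = lambda g: (g * (1.0 - t * t),)
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, self.requires_grad, (self,))
        out._backward = lambda g: (g * e,)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda g: (g / self.data,)
        return out

    def softplus(self) -> "Tensor":
        # numerically stable log(1 + e^x)
        out = Tensor(np.logaddexp(0.0, self.data), self.requires_grad, (self,))
        sig = 1.0 / (1.0 + np.exp(-self.data))
        out._backward = lambda g: (g * sig,)
        return out

    # --------------------------------------------------------------- engine
    def backward(self) -> None:
        """Accumulate gradients of this (scalar) tensor w.r.t. the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        while stack_:
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack_.extend(unvisited)
            else:
                seen.add(id(node))
                order.append(stack_.pop())
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None or node._backward is None:
                if g is not None and node.requires_grad:
                    node.grad = g if node.grad is None else node.grad + g
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg
        # leaves whose gradient never propagated further
        for key, g in grads.items():
            for node in order:
                if id(node) == key and node.requires_grad:
                    node.grad = g if node.grad is None else node.grad + g
                    break


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out._backward = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))

    def backward(g):
        return tuple(np.take(g, i, axis=axis) for i in range(len(tensors)))

    out._backward = backward
    return out
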