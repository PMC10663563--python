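"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the deconvolution and domain models need:
broadcasting arithmetic, matmul, exp/log/sqrt/power, relu/tanh, reductions,
softmax/log-softmax, and an epsilon clip whose gradient is passed through
only on the unclipped region. Graphs are built eagerly and freed after
``backward``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "absolute",
    "exp",
    "log",
    "sqrt",
    "relu",
    "tanh",
    "softmax",
    "log_softmax",
    "clip_min",
    "concatenate",
    "sum_sq",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, k):
        if not np.isscalar(k):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data**k

        def backward(g):
            return (g * k * self.data ** (k - 1),)

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            return g @ other.data.T, self.data.T @ g

        return Tensor._make(out_data, (self, other), backward)

    def __rmatmul__(self, other):
        return as_tensor(other) @ self

    # -- shape ops ------------------------------------------------------------
    @property
    def T(self):
        return Tensor._make(self.data.T, (self,), lambda g: (g.T,))

    def reshape(self, *shape):
        old = self.shape
        return Tensor._make(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),)
        )

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._make(self.data[idx], (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- autograd driver ------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        order_stack: list[tuple[Tensor, bool]] = [(self, False)]
        while order_stack:
            node, processed = order_stack.pop()
            if not node.requires_grad:
                continue
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            order_stack.append((node, True))
            for p in node._parents:
                order_stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.array(g, dtype=np.float64, copy=True)
                else:
                    parent.grad += g
            node._parents = ()
            node._backward = None


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- elementwise functions ----------------------------------------------------

def exp(t: Tensor) -> Tensor:
    t = as_tensor(t)
    out_data = np.exp(t.data)
    return Tensor._make(out_data, (t,), lambda g: (g * out_data,))


def log(t: Tensor) -> Tensor:
    t = as_tensor(t)
    return Tensor._make(np.log(t.data), (t,), lambda g: (g / t.data,))


def sqrt(t: Tensor) -> Tensor:
    return as_tensor(t) ** 0.5


def relu(t: Tensor) -> Tensor:
    t = as_tensor(t)
    mask = t.data > 0
    return Tensor._make(t.data * mask, (t,), lambda g: (g * mask,))


def tanh(t: Tensor) -> Tensor:
    t = as_tensor(t)
    out_data = np.tanh(t.data)
    return Tensor._make(out_data, (t,), lambda g: (g * (1 - out_data**2),))


def absolute(t: Tensor) -> Tensor:
    """|t| with subgradient sign(t) (zero at t = 0)."""
    t = as_tensor(t)
    return Tensor._make(np.abs(t.data), (t,), lambda g: (g * np.sign(t.data),))


def clip_min(t: Tensor, lo: float) -> Tensor:
    """max(t, lo) with gradient passed only where t > lo."""
    t = as_tensor(t)
    mask = t.data > lo
    return Tensor._make(np.maximum(t.data, lo), (t,), lambda g: (g * mask,))


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    # shift by a detached max; softmax is shift-invariant so the gradient
    # of the constant shift vanishes exactly
    shift = Tensor(t.data.max(axis=axis, keepdims=True))
    e = exp(t - shift)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(t: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(t.data.max(axis=axis, keepdims=True))
    s = t - shift
    return s - log(exp(s).sum(axis=axis, keepdims=True))


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)


def sum_sq(t: Tensor, axis=None, keepdims=False) -> Tensor:
    return (as_tensor(t) ** 2).sum(axis=axis, keepdims=keepdims)
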