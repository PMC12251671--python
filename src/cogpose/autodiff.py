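"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ndarray and records, per operation, a closure
that accumulates the upstream gradient into its parents. Calling
:meth:`Tensor.backward` on a scalar output walks the tape in reverse
topological order. The op set is exactly what the lifting network and the
physics loss functions need: broadcasting arithmetic, matmul, reductions,
elementwise transcendentals, softmax, indexing and shape manipulation.

Gradients follow the dtype of the data, so float64 inputs give gradients
that can be validated against central finite differences at ~1e-7
accuracy, while the network trains in float32 for speed.
"""
from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gelu", "relu", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a gradient over the axes that broadcasting expanded."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents
        )
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor (must be scalar if grad omitted)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        g = _unbroadcast(grad, self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        def bw(g):
            self._accum(g)
            other._accum(g)
        out._backward = bw if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = (lambda g: self._accum(-g)) if out.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)
        out._backward = bw if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))
        def bw(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / (other.data * other.data))
        out._backward = bw if out.requires_grad else None
        return out

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        def bw(g):
            a, b = self.data, other.data
            if b.ndim >= 2:
                ga = g @ b.swapaxes(-1, -2)
            else:
                ga = np.multiply.outer(g, b)
            if a.ndim >= 2:
                gb = a.swapaxes(-1, -2) @ g
            else:
                gb = np.multiply.outer(a, g)
            self._accum(ga)
            other._accum(gb)
        out._backward = bw if out.requires_grad else None
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     parents=(self,))
        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))
        out._backward = bw if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise ------------------------------------------------------
    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor(y, parents=(self,))
        def bw(g):
            # subgradient 0 at exactly zero (e.g. coincident keypoints)
            denom = np.where(y > 0, 2.0 * y, np.inf)
            self._accum(g / denom)
        out._backward = bw if out.requires_grad else None
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = (lambda g: self._accum(g / self.data)) \
            if out.requires_grad else None
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = (lambda g: self._accum(g * y)) \
            if out.requires_grad else None
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = (lambda g: self._accum(g * (1.0 - y * y))) \
            if out.requires_grad else None
        return out

    def maximum(self, other: float):
        mask = self.data > other
        out = Tensor(np.where(mask, self.data, other), parents=(self,))
        out._backward = (lambda g: self._accum(g * mask)) \
            if out.requires_grad else None
        return out

    # -- shape ------------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = (lambda g: self._accum(g.reshape(self.data.shape))) \
            if out.requires_grad else None
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(*axes), parents=(self,))
        out._backward = (lambda g: self._accum(g.transpose(*inv))) \
            if out.requires_grad else None
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)
        out._backward = bw if out.requires_grad else None
        return out


def concat(tensors, axis=-1) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)
    out._backward = bw if out.requires_grad else None
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, parents=(x,))
    def bw(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accum(y * (g - dot))
    out._backward = bw if out.requires_grad else None
    return out


def relu(x: Tensor) -> Tensor:
    return x.maximum(0.0)


def layernorm(x: Tensor, gamma: Tensor, beta: Tensor,
              eps: float = 1e-5) -> Tensor:
    """Fused layer normalization over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(xhat * gamma.data + beta.data, parents=(x, gamma, beta))

    def bw(g):
        axes = tuple(range(g.ndim - 1))
        beta._accum(g.sum(axis=axes))
        gamma._accum((g * xhat).sum(axis=axes))
        gh = g * gamma.data
        n = x.data.shape[-1]
        dx = inv * (gh - gh.mean(axis=-1, keepdims=True)
                    - xhat * (gh * xhat).mean(axis=-1, keepdims=True))
        x._accum(dx)

    out._backward = bw if out.requires_grad else None
    return out


def gelu(x: Tensor) -> Tensor:
    """Gaussian error linear unit (tanh approximation)."""
    c = float(np.sqrt(2.0 / np.pi))
    inner = (x + x * x * x * 0.044715) * c
    return x * 0.5 * (inner.tanh() + 1.0)
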