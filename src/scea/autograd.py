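"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the training core for the package's neural components (the MLP
autoencoder, the graph attention autoencoder and the self-optimizing
clustering head). It implements exactly the operations those models need —
dense linear algebra, elementwise nonlinearities, reductions, broadcasting,
and a support-masked softmax for attention — as a tape of `Tensor` nodes
with a topological-order backward pass.

Everything is deterministic: no dropout, no stochastic ops; randomness
enters only through parameter initialisation, which callers drive from a
seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "masked_softmax", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_children")

    def __init__(self, data, requires_grad: bool = False, _children=(), _backward=None):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._children = _children
        self._backward = _backward

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    @property
    def shape(self):
        return self.data.shape

    @property
    def T(self) -> "Tensor":
        out = Tensor(self.data.T, self.requires_grad, (self,))

        def bw():
            self._accum(out.grad.T)

        out._backward = bw
        return out

    def _accum(self, g: np.ndarray):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bw():
            self._accum(_unbroadcast(out.grad, self.data.shape))
            other._accum(_unbroadcast(out.grad, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda: self._accum(-out.grad)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bw():
            self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, self.requires_grad, (self,))

        def bw():
            self._accum(out.grad * exponent * self.data ** (exponent - 1.0))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bw():
            self._accum(out.grad @ other.data.T)
            other._accum(self.data.T @ out.grad)

        out._backward = bw
        return out

    # -- elementwise nonlinearities --------------------------------------------

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, self.requires_grad, (self,))
        out._backward = lambda: self._accum(out.grad * (1.0 - y * y))
        return out

    def leaky_relu(self, slope: float = 0.2):
        y = np.where(self.data > 0, self.data, slope * self.data)
        out = Tensor(y, self.requires_grad, (self,))

        def bw():
            self._accum(out.grad * np.where(self.data > 0, 1.0, slope))

        out._backward = bw
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, self.requires_grad, (self,))
        out._backward = lambda: self._accum(out.grad * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda: self._accum(out.grad / self.data)
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), self.requires_grad, (self,))
        out._backward = lambda: self._accum(out.grad * np.sign(self.data))
        return out

    # -- reductions and reshaping ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bw():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))
        out._backward = lambda: self._accum(out.grad.reshape(self.data.shape))
        return out

    # -- graph traversal --------------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for c in t._children:
                visit(c)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()
        # break the closure reference cycles so large intermediates free
        # immediately instead of waiting for the cyclic garbage collector
        for t in topo:
            if t._children:  # keep leaf parameters intact
                t._backward = None
                t._children = ()

    def item(self) -> float:
        return float(self.data)


def Parameter(data) -> Tensor:
    return Tensor(np.asarray(data), requires_grad=True)


def concat(tensors, axis: int = 1) -> Tensor:
    """Concatenate tensors along `axis` (used for multi-head merging)."""
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * data.ndim
            idx[axis] = slice(int(lo), int(hi))
            t._accum(out.grad[tuple(idx)])

    out._backward = bw
    return out


def masked_softmax(logits: Tensor, support: np.ndarray) -> Tensor:
    """Row softmax of `logits` restricted to the boolean `support` mask.

    Entries off the support are exactly zero in the output and receive no
    gradient; each row must have at least one supported entry.
    """
    support = np.asarray(support, dtype=bool)
    if not support.any(axis=1).all():
        raise ValueError("masked_softmax: a row has empty support")
    neg = np.where(support, logits.data, -np.inf)
    neg = neg - neg.max(axis=1, keepdims=True)
    e = np.exp(neg) * support
    a = e / e.sum(axis=1, keepdims=True)
    out = Tensor(a, logits.requires_grad, (logits,))

    def bw():
        g = out.grad
        dot = (g * a).sum(axis=1, keepdims=True)
        logits._accum(a * (g - dot))

    out._backward = bw
    return out


class Adam:
    """Adam optimizer over a list of Parameters."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            m, v = self.m[i], self.v[i]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * (g * g)
            denom = np.sqrt(v / bc2)
            denom += self.eps
            p.data -= (self.lr / bc1) * m / denom
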