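"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the sequence models in this package need:
broadcasting arithmetic, matmul, the usual pointwise nonlinearities,
reductions (sum/mean/max/logsumexp), concatenation, stacking and static
slicing.  Gradients are accumulated into ``Tensor.grad`` by ``backward()``
on a scalar loss.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "concat", "stack", "relu", "sigmoid", "tanh",
           "exp", "log", "logsumexp", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def detach(self):
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autodiff core -------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.data.shape)

        return Tensor(self.data + other.data, _parents=(self, other), _backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self.grad += -g
        return Tensor(-self.data, _parents=(self,), _backward=bw)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.data.shape)

        return Tensor(self.data * other.data, _parents=(self, other), _backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g / other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(
                    -g * self.data / other.data ** 2, other.data.shape)

        return Tensor(self.data / other.data, _parents=(self, other), _backward=bw)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p):
        assert np.isscalar(p)

        def bw(g):
            if self.requires_grad:
                self.grad += g * p * self.data ** (p - 1)

        return Tensor(self.data ** p, _parents=(self,), _backward=bw)

    def __matmul__(self, other):
        other = _as_tensor(other)

        def bw(g):
            a, b = self.data, other.data
            if self.requires_grad:
                if a.ndim == 1 and b.ndim == 1:
                    self.grad += g * b
                elif a.ndim == 1:
                    self.grad += b @ g
                elif b.ndim == 1:
                    self.grad += g[..., None] * b
                else:
                    self.grad += g @ b.T
            if other.requires_grad:
                if a.ndim == 1 and b.ndim == 1:
                    other.grad += g * a
                elif a.ndim == 1:
                    other.grad += np.outer(a, g)
                elif b.ndim == 1:
                    other.grad += (a.reshape(-1, a.shape[-1]).T
                                   @ g.reshape(-1))
                elif a.ndim == 2 and b.ndim == 2:
                    other.grad += a.T @ g
                else:
                    # stacked (..., n, k) @ (k, m): pool the leading axes
                    other.grad += (a.reshape(-1, a.shape[-1]).T
                                   @ g.reshape(-1, g.shape[-1]))

        return Tensor(self.data @ other.data, _parents=(self, other), _backward=bw)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self.grad += np.broadcast_to(g, self.data.shape)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self.grad += np.broadcast_to(gg, self.data.shape)

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                      _parents=(self,), _backward=bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis):
        """Max along an axis; gradient flows to the (first) argmax."""
        idx = np.argmax(self.data, axis=axis)
        out = np.max(self.data, axis=axis)

        def bw(g):
            if not self.requires_grad:
                return
            grad = np.zeros_like(self.data)
            it = np.indices(out.shape)
            sl = list(it)
            sl.insert(axis % self.data.ndim, idx)
            grad[tuple(sl)] = g
            self.grad += grad

        return Tensor(out, _parents=(self,), _backward=bw)

    # -- shaping -------------------------------------------------------------
    def __getitem__(self, key):
        def bw(g):
            if self.requires_grad:
                grad = np.zeros_like(self.data)
                np.add.at(grad, key, g)
                self.grad += grad

        return Tensor(self.data[key], _parents=(self,), _backward=bw)

    def reshape(self, *shape):
        def bw(g):
            if self.requires_grad:
                self.grad += g.reshape(self.data.shape)
        return Tensor(self.data.reshape(*shape), _parents=(self,), _backward=bw)

    @property
    def T(self):
        def bw(g):
            if self.requires_grad:
                self.grad += g.T
        return Tensor(self.data.T, _parents=(self,), _backward=bw)


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def tensor(data, requires_grad=False):
    return Tensor(data, requires_grad=requires_grad)


# -- pointwise nonlinearities ------------------------------------------------
def tanh(x: Tensor) -> Tensor:
    out = np.tanh(x.data)

    def bw(g):
        if x.requires_grad:
            x.grad += g * (1.0 - out ** 2)

    return Tensor(out, _parents=(x,), _backward=bw)


def sigmoid(x: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))

    def bw(g):
        if x.requires_grad:
            x.grad += g * out * (1.0 - out)

    return Tensor(out, _parents=(x,), _backward=bw)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bw(g):
        if x.requires_grad:
            x.grad += g * mask

    return Tensor(x.data * mask, _parents=(x,), _backward=bw)


def exp(x: Tensor) -> Tensor:
    out = np.exp(x.data)

    def bw(g):
        if x.requires_grad:
            x.grad += g * out

    return Tensor(out, _parents=(x,), _backward=bw)


def log(x: Tensor) -> Tensor:
    def bw(g):
        if x.requires_grad:
            x.grad += g / x.data

    return Tensor(np.log(x.data), _parents=(x,), _backward=bw)


def logsumexp(x: Tensor, axis=None, keepdims=False) -> Tensor:
    m = np.max(x.data, axis=axis, keepdims=True)
    out = np.log(np.sum(np.exp(x.data - m), axis=axis, keepdims=True)) + m
    softmax_cache = np.exp(x.data - out)
    if not keepdims and axis is not None:
        out = np.squeeze(out, axis=axis)
    elif not keepdims:
        out = out.reshape(())

    def bw(g):
        if not x.requires_grad:
            return
        gg = g
        if not keepdims and axis is not None:
            gg = np.expand_dims(g, axis)
        x.grad += gg * softmax_cache

    return Tensor(out, _parents=(x,), _backward=bw)


def softmax(x: Tensor, axis=-1) -> Tensor:
    return exp(x - logsumexp(x, axis=axis, keepdims=True))


def concat(tensors, axis=0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.grad += g[tuple(sl)]

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  _parents=tuple(tensors), _backward=bw)


def stack(tensors, axis=0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t.grad += np.take(g, i, axis=axis)

    return Tensor(np.stack([t.data for t in tensors], axis=axis),
                  _parents=tuple(tensors), _backward=bw)
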