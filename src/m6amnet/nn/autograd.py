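"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Covers exactly the tensor operations the window classifier needs: dense,
1-D convolution (via ``unfold1d``), recurrent cells, multi-head attention,
softmax and cross-entropy.  Tensors record their parents as the graph is
built; ``Tensor.backward`` replays it in reverse creation order (creation
order is a valid topological order since parents always exist before
children).

No operation mutates a gradient buffer in place, so gradient arrays may be
shared between nodes without copying.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

_IDS = itertools.count()


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "_id")

    def __init__(self, data, requires_grad: bool = False):
        if not isinstance(data, np.ndarray):
            data = np.asarray(data, dtype=np.float32)
        self.data = data
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = ()
        self._backward = None
        self._id = next(_IDS)

    # -- graph plumbing ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _acc(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g
        else:
            self.grad = self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = grad
        nodes: dict[int, Tensor] = {}
        stack = [self]
        while stack:
            n = stack.pop()
            if id(n) in nodes:
                continue
            nodes[id(n)] = n
            stack.extend(p for p in n._parents if p.requires_grad)
        for n in sorted(nodes.values(), key=lambda t: t._id, reverse=True):
            if n._backward is not None and n.grad is not None:
                n._backward(n.grad)

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other, self.data.dtype)
        out = _node(self.data + other.data, (self, other))

        def bw(g):
            self._acc(_unbroadcast(g, self.data.shape))
            other._acc(_unbroadcast(g, other.data.shape))

        out._backward = bw if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        out._backward = (lambda g: self._acc(-g)) if out.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other, self.data.dtype))

    def __rsub__(self, other):
        return _as_tensor(other, self.data.dtype) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other, self.data.dtype)
        out = _node(self.data * other.data, (self, other))

        def bw(g):
            self._acc(_unbroadcast(g * other.data, self.data.shape))
            other._acc(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other, self.data.dtype)
        out = _node(self.data / other.data, (self, other))

        def bw(g):
            self._acc(_unbroadcast(g / other.data, self.data.shape))
            other._acc(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        out._backward = bw if out.requires_grad else None
        return out

    def __pow__(self, exponent: float):
        out = _node(self.data**exponent, (self,))

        def bw(g):
            self._acc(g * exponent * self.data ** (exponent - 1))

        out._backward = bw if out.requires_grad else None
        return out

    def __matmul__(self, other):
        out = _node(self.data @ other.data, (self, other))

        def bw(g):
            self._acc(_unbroadcast(g @ other.data.swapaxes(-1, -2), self.data.shape))
            other._acc(_unbroadcast(self.data.swapaxes(-1, -2) @ g, other.data.shape))

        out._backward = bw if out.requires_grad else None
        return out

    # -- nonlinearities ---------------------------------------------------

    def tanh(self):
        y = np.tanh(self.data)
        out = _node(y, (self,))
        out._backward = (lambda g: self._acc(g * (1.0 - y * y))) if out.requires_grad else None
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = _node(y, (self,))
        out._backward = (lambda g: self._acc(g * y * (1.0 - y))) if out.requires_grad else None
        return out

    def relu(self):
        mask = self.data > 0
        out = _node(np.where(mask, self.data, 0.0), (self,))
        out._backward = (lambda g: self._acc(g * mask)) if out.requires_grad else None
        return out

    def exp(self):
        y = np.exp(self.data)
        out = _node(y, (self,))
        out._backward = (lambda g: self._acc(g * y)) if out.requires_grad else None
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))
        out._backward = (lambda g: self._acc(g / self.data)) if out.requires_grad else None
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = _node(s, (self,))

        def bw(g):
            self._acc(s * (g - (g * s).sum(axis=axis, keepdims=True)))

        out._backward = bw if out.requires_grad else None
        return out

    # -- reductions & shaping ---------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._acc(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int):
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis).squeeze(axis)
        out = _node(out_data, (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis)
            self._acc(full)

        out._backward = bw if out.requires_grad else None
        return out

    def reshape(self, *shape):
        out = _node(self.data.reshape(*shape), (self,))
        out._backward = (lambda g: self._acc(g.reshape(self.data.shape))) if out.requires_grad else None
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = _node(self.data.transpose(*axes), (self,))
        out._backward = (lambda g: self._acc(g.transpose(*inv))) if out.requires_grad else None
        return out

    def __getitem__(self, idx):
        out = _node(self.data[idx], (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            full[idx] = g  # basic slicing only: no duplicate indices
            self._acc(full)

        out._backward = bw if out.requires_grad else None
        return out


def _node(data: np.ndarray, parents: tuple) -> Tensor:
    t = Tensor.__new__(Tensor)
    t.data = data
    t.grad = None
    t.requires_grad = any(p.requires_grad for p in parents)
    t._parents = parents if t.requires_grad else ()
    t._backward = None
    t._id = next(_IDS)
    return t


def _as_tensor(x, dtype) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


def cat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._acc(piece)

    out._backward = bw if out.requires_grad else None
    return out


def unfold1d(x: Tensor, k: int) -> Tensor:
    """Sliding windows along axis 1: (B, L, C) -> (B, L-k+1, k*C)."""
    b, length, c = x.data.shape
    lout = length - k + 1
    view = np.lib.stride_tricks.sliding_window_view(x.data, k, axis=1)  # (B, Lout, C, k)
    out = _node(np.ascontiguousarray(view.transpose(0, 1, 3, 2)).reshape(b, lout, k * c), (x,))

    def bw(g):
        g = g.reshape(b, lout, k, c)
        gx = np.zeros_like(x.data)
        for j in range(k):
            gx[:, j : j + lout, :] += g[:, :, j, :]
        x._acc(gx)

    out._backward = bw if out.requires_grad else None
    return out


def maxpool1d(x: Tensor, size: int) -> Tensor:
    """Non-overlapping max pooling along axis 1; trailing remainder dropped."""
    b, length, c = x.data.shape
    lout = length // size
    if lout < 1:
        raise ValueError(f"pool size {size} exceeds sequence length {length}")
    return x[:, : lout * size, :].reshape(b, lout, size, c).max(axis=2)


def dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; call only in training mode."""
    if p <= 0:
        return x
    mask = (rng.random(x.data.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    return x * Tensor(mask)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; labels are integer class indices."""
    z = logits.data
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = z.shape[0]
    nll = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None))
    out = _node(np.asarray(nll.mean(), dtype=z.dtype), (logits,))

    def bw(g):
        gz = p.copy()
        gz[np.arange(n), labels] -= 1.0
        logits._acc(gz * (g / n))

    out._backward = bw if out.requires_grad else None
    return out


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    """Plain-NumPy stable softmax for inference paths (no graph)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def glorot(rng: np.random.Generator, shape: tuple, dtype=np.float32) -> Tensor:
    fan_in, fan_out = shape[0], shape[-1]
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape).astype(dtype), requires_grad=True)


def zeros(shape, dtype=np.float32, requires_grad: bool = False) -> Tensor:
    return Tensor(np.zeros(shape, dtype=dtype), requires_grad=requires_grad)
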