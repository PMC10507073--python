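"""Compact reverse-mode automatic differentiation over numpy arrays.

A tape-based engine sized for the small recurrent and attention networks in
this package: tensors wrap ndarrays, elementary ops record closures that
propagate gradients, and ``backward`` walks the tape in reverse topological
order. Broadcasting follows numpy semantics, with gradients summed back
over broadcast axes.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient over axes that were broadcast to produce ``grad``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- graph -------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        # iterative post-order walk: recurrent graphs are deeper than the
        # interpreter's recursion limit
        topo, seen = [], set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            t, expanded = stack.pop()
            if not (t.requires_grad or t._parents):
                continue
            if expanded:
                topo.append(t)
                continue
            if id(t) in seen:
                continue
            seen.add(id(t))
            stack.append((t, True))
            for p in t._parents:
                stack.append((p, False))
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic --------------------------------------------------------
    def _binary(self, other, fwd, bwd_a, bwd_b):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(fwd(self.data, other.data), parents=(self, other))

        def backward(g):
            if self.grad is not None:
                self.grad += _unbroadcast(bwd_a(g, self.data, other.data), self.shape)
            if other.grad is not None:
                other.grad += _unbroadcast(bwd_b(g, self.data, other.data), other.shape)

        out._backward = backward
        return out

    def __add__(self, other):
        return self._binary(other, lambda a, b: a + b,
                            lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda a, b: a - b,
                            lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        return self._binary(other, lambda a, b: a * b,
                            lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(other, lambda a, b: a / b,
                            lambda g, a, b: g / b,
                            lambda g, a, b: -g * a / (b * b))

    def __neg__(self):
        return self * -1.0

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(np.matmul(self.data, other.data), parents=(self, other))

        def backward(g):
            if self.grad is not None:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self.grad += _unbroadcast(ga, self.shape)
            if other.grad is not None:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other.grad += _unbroadcast(gb, other.shape)

        out._backward = backward
        return out

    # -- elementwise -------------------------------------------------------
    def _unary(self, fwd, bwd):
        y = fwd(self.data)
        out = Tensor(y, parents=(self,))

        def backward(g):
            if self.grad is not None:
                self.grad += bwd(g, self.data, y)

        out._backward = backward
        return out

    def tanh(self):
        return self._unary(np.tanh, lambda g, x, y: g * (1.0 - y * y))

    def sigmoid(self):
        def fwd(x):
            out = np.empty_like(x)
            pos = x >= 0
            out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
            e = np.exp(x[~pos])
            out[~pos] = e / (1.0 + e)
            return out
        return self._unary(fwd, lambda g, x, y: g * y * (1.0 - y))

    def exp(self):
        return self._unary(np.exp, lambda g, x, y: g * y)

    def log(self):
        return self._unary(np.log, lambda g, x, y: g / x)

    def sqrt(self):
        return self._unary(np.sqrt, lambda g, x, y: g / (2.0 * y))

    # -- shape -------------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            if self.grad is None:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self.grad += np.broadcast_to(g, self.shape)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def backward(g):
            if self.grad is not None:
                self.grad += g.reshape(self.shape)

        out._backward = backward
        return out

    def swap_last(self):
        """Transpose the last two axes."""
        out = Tensor(np.swapaxes(self.data, -1, -2), parents=(self,))

        def backward(g):
            if self.grad is not None:
                self.grad += np.swapaxes(g, -1, -2)

        out._backward = backward
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))

        def backward(g):
            if self.grad is not None:
                np.add.at(self.grad, key, g)

        out._backward = backward
        return out


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.grad is not None:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t.grad += g[tuple(idx)]

    out._backward = backward
    return out


def stack(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))

    def backward(g):
        parts = np.moveaxis(g, axis, 0)
        for t, part in zip(tensors, parts):
            if t.grad is not None:
                t.grad += part

    out._backward = backward
    return out


def embedding(weight: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup ``weight[indices]`` with scatter-add backward."""
    idx = np.asarray(indices)
    out = Tensor(weight.data[idx], parents=(weight,))

    def backward(g):
        if weight.grad is not None:
            np.add.at(weight.grad, idx, g)

    out._backward = backward
    return out


def masked_softmax(scores: Tensor, mask: np.ndarray, axis: int = -1) -> Tensor:
    """Softmax over ``axis`` restricted to mask==1 positions.

    Rows with an all-zero mask fall back to uniform weights over all
    positions (keeps attention defined for all-padding samples).
    """
    m = np.asarray(mask, dtype=np.float64)
    m = np.broadcast_to(m, scores.shape)
    shifted = scores - np.max(scores.data, axis=axis, keepdims=True)
    e = shifted.exp() * Tensor(m)
    total = e.sum(axis=axis, keepdims=True)
    dead = (total.data == 0.0)
    safe = e / (total + Tensor(dead.astype(np.float64)))
    n = scores.shape[axis]
    fallback = np.broadcast_to(dead, scores.shape).astype(np.float64) / n
    return safe + Tensor(fallback)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw scores, numerically stable."""
    y = np.asarray(targets, dtype=np.float64)
    z = logits.data
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(loss.mean(), parents=(logits,))

    def backward(g):
        if logits.grad is not None:
            sig = 1.0 / (1.0 + np.exp(-z))
            logits.grad += g * (sig - y) / y.size

    out._backward = backward
    return out


class Adam:
    """Adaptive-moment gradient descent with an external LR multiplier."""

    def __init__(self, params: dict[str, Tensor], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
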