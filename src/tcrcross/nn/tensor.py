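"""Reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine sufficient for transformer training on CPU:
broadcasting binary ops, batched matmul, reductions, softmax, layer norm,
embedding lookup and the cross-entropy losses. Gradients accumulate in
``Tensor.grad``; intermediate tensors keep their gradients, which the
explanation code exploits to read d(loss)/d(attention probabilities).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "concat",
    "softmax",
    "layer_norm",
    "embedding",
    "relu",
    "gelu",
    "cross_entropy_with_logits",
    "bce_with_logits",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "parents", "backward_fn", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward_fn=None):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        if self.data.dtype == np.float16:
            self.data = self.data.astype(np.float32)
        self.grad = None
        self.parents = parents
        self.backward_fn = backward_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # -- graph ------------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        # accumulation always rebinds (never mutates), so sharing g is safe
        self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor (seeded with ones by default)."""
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self._accum(np.ones_like(self.data) if grad is None else np.asarray(grad))
        for node in reversed(topo):
            if node.backward_fn is not None and node.grad is not None:
                node.backward_fn(node.grad)

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        if np.isscalar(other):
            # float32 scalars avoid NEP-50 promotion of float32 graphs
            return Tensor(np.float32(other))
        return Tensor(np.asarray(other))

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out.backward_fn = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out.backward_fn = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out.backward_fn = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other.reciprocal()
        return self * (1.0 / other)

    def reciprocal(self):
        out = Tensor(1.0 / self.data, parents=(self,))
        out.backward_fn = lambda g: self._accum(-g / (self.data * self.data))
        return out

    def __pow__(self, p: float):
        y = self.data * self.data if p == 2 else self.data**p
        out = Tensor(y, parents=(self,))
        grad_base = self.data if p == 2 else self.data ** (p - 1)
        out.backward_fn = lambda g: self._accum(g * p * grad_base)
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            a, b = self.data, other.data
            if a.ndim == 1 or b.ndim == 1:
                raise NotImplementedError("1-D matmul operands are not supported")
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape))

        out.backward_fn = bwd
        return out

    # -- shape -------------------------------------------------------------

    def reshape(self, *shape):
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out.backward_fn = lambda g: self._accum(g.reshape(orig))
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(*axes), parents=(self,))
        out.backward_fn = lambda g: self._accum(g.transpose(*inv))
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), parents=(self,))
        out.backward_fn = lambda g: self._accum(np.swapaxes(g, a, b))
        return out

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out.backward_fn = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities -----------------------------------------

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, parents=(self,))
        out.backward_fn = lambda g: self._accum(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out.backward_fn = lambda g: self._accum(g / self.data)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        out.backward_fn = lambda g: self._accum(g * (1.0 - y * y))
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, parents=(self,))
        out.backward_fn = lambda g: self._accum(g * y * (1.0 - y))
        return out

    def detach(self) -> np.ndarray:
        return self.data


class Parameter(Tensor):
    """A trainable leaf tensor; the only kind collected by Module.parameters()."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, parents=(x,))
    out.backward_fn = lambda g: x._accum(g * mask)
    return out


_GELU_C = float(np.sqrt(2.0 / np.pi))


def gelu(x: Tensor) -> Tensor:
    """tanh-approximated GELU with an exact derivative of the approximation."""
    v = x.data
    inner = _GELU_C * (v + 0.044715 * (v * v * v))
    t = np.tanh(inner)
    y = 0.5 * v * (1.0 + t)
    out = Tensor(y, parents=(x,))

    def bwd(g):
        dinner = _GELU_C * (1.0 + 3 * 0.044715 * v * v)
        dy = 0.5 * (1.0 + t) + 0.5 * v * (1.0 - t * t) * dinner
        x._accum(g * dy)

    out.backward_fn = bwd
    return out


def concat(tensors: list, axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out.backward_fn = bwd
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    ez = np.exp(z, out=z)
    y = ez / ez.sum(axis=axis, keepdims=True)
    out = Tensor(y, parents=(x,))

    def bwd(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accum(y * (g - dot))

    out.backward_fn = bwd
    return out


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(gain.data * xhat + bias.data, parents=(x, gain, bias))

    def bwd(g):
        reduce_axes = tuple(range(g.ndim - 1))
        gain._accum((g * xhat).sum(axis=reduce_axes))
        bias._accum(g.sum(axis=reduce_axes))
        gx = g * gain.data
        m1 = gx.mean(axis=-1, keepdims=True)
        m2 = (gx * xhat).mean(axis=-1, keepdims=True)
        x._accum(inv * (gx - m1 - xhat * m2))

    out.backward_fn = bwd
    return out


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    ids = np.asarray(ids)
    out = Tensor(weight.data[ids], parents=(weight,))

    def bwd(g):
        gw = np.zeros_like(weight.data)
        np.add.at(gw, ids, g)
        weight._accum(gw)

    out.backward_fn = bwd
    return out


def cross_entropy_with_logits(logits: Tensor, targets: np.ndarray, position_mask: np.ndarray) -> Tensor:
    """Mean token-level cross entropy over positions where ``position_mask`` is true.

    logits: (..., V); targets: integer array matching logits[..., 0] shape.
    Returns a scalar Tensor; 0 when no position is selected.
    """
    targets = np.asarray(targets)
    mask = np.asarray(position_mask, dtype=bool)
    n = int(mask.sum())
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - lse
    if n == 0:
        out = Tensor(np.zeros((), dtype=logits.data.dtype), parents=(logits,))
        out.backward_fn = lambda g: logits._accum(np.zeros_like(logits.data))
        return out
    picked = np.take_along_axis(logp, targets[..., None], axis=-1)[..., 0]
    loss = -(picked * mask).sum() / n
    out = Tensor(np.asarray(loss, dtype=logits.data.dtype), parents=(logits,))

    def bwd(g):
        probs = np.exp(logp)
        onehot = np.zeros_like(probs)
        np.put_along_axis(onehot, targets[..., None], 1.0, axis=-1)
        grad = (probs - onehot) * mask[..., None] * (g / n)
        logits._accum(grad.astype(logits.data.dtype))

    out.backward_fn = bwd
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray, sample_mask: np.ndarray | None = None) -> Tensor:
    """Mean binary cross entropy with a sigmoid link, numerically stable.

    ``sample_mask`` (optional, bool) drops elements, e.g. samples with a
    missing label; the mean runs over kept elements only.
    """
    y = np.asarray(targets, dtype=logits.data.dtype)
    x = logits.data
    mask = np.ones_like(x, dtype=bool) if sample_mask is None else np.asarray(sample_mask, bool)
    n = int(mask.sum())
    if n == 0:
        out = Tensor(np.zeros((), dtype=x.dtype), parents=(logits,))
        out.backward_fn = lambda g: logits._accum(np.zeros_like(x))
        return out
    # softplus(x) - x*y, stable for large |x|
    per = np.maximum(x, 0) - x * y + np.log1p(np.exp(-np.abs(x)))
    out = Tensor(np.asarray((per * mask).sum() / n, dtype=x.dtype), parents=(logits,))

    def bwd(g):
        p = 1.0 / (1.0 + np.exp(-x))
        logits._accum(((p - y) * mask) * (g / n))

    out.backward_fn = bwd
    return out
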