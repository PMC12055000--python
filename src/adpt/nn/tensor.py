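"""Reverse-mode autodiff over numpy arrays.

A ``Tensor`` wraps an ndarray and records the closure that propagates its
gradient to its parents; ``backward()`` runs the tape in reverse
topological order. Structured ops that dominate runtime (convolution,
pooling, softmax, layer norm, cross-entropy) are fused single nodes with
hand-written backward passes; everything else composes from elementwise
primitives. Gradients accumulate in ``.grad`` as plain ndarrays.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "maxpool2d",
    "softmax",
    "layer_norm",
    "sparse_cross_entropy",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum grad over axes that were broadcast to reach ``grad.shape``."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    # -- helpers ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.float64 if self.data.dtype == np.float64 else np.float32)
        self.grad += g

    @staticmethod
    def _wrap(x):
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- elementwise -----------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = _back
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = _back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self**-1.0

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _prev=(self,))

        def _back(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        out._backward = _back
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0), _prev=(self,))

        def _back(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        out._backward = _back
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))

        def _back(g):
            if self.requires_grad:
                self._accum(g * out.data)

        out._backward = _back
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def _back(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = _back
        return out

    def sqrt(self):
        return self**0.5

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _back(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, axes)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = _back
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))

        def _back(g):
            if self.requires_grad:
                self._accum(g.reshape(self.shape))

        out._backward = _back
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        inv = np.argsort(axes)

        def _back(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        out._backward = _back
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def _back(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = _back
        return out

    # -- matmul ----------------------------------------------------------
    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def _back(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        out._backward = _back
        return out

    # -- autodiff driver -------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: "Tensor"):
            stack = [(t, iter(t._prev))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._prev)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self._accum(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={'set' if self.grad is not None else 'none'})"


class Parameter(Tensor):
    """A trainable tensor; ``decay`` marks it for weight decay."""

    __slots__ = ("decay", "name")

    def __init__(self, data, decay: bool = True, name: str = ""):
        super().__init__(np.asarray(data), requires_grad=True)
        self.decay = decay
        self.name = name


# ---------------------------------------------------------------------------
# fused structured ops
# ---------------------------------------------------------------------------

def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = _back
    return out


def _patches(xp: np.ndarray, kh, kw, sh, sw, oh, ow) -> np.ndarray:
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + sh * oh : sh, j : j + sw * ow : sw]
    return cols


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, padding: int | None = None) -> Tensor:
    """2-D convolution, NCHW layout, square kernel, symmetric zero padding."""
    kh, kw = w.shape[2], w.shape[3]
    if padding is None:
        padding = kh // 2
    s = stride
    n, c, h, wd = x.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    oh = (h + 2 * padding - kh) // s + 1
    ow = (wd + 2 * padding - kw) // s + 1
    cols = _patches(xp, kh, kw, s, s, oh, ow)
    y = np.tensordot(w.data, cols, axes=([1, 2, 3], [1, 2, 3]))  # (O, N, oh, ow)
    y = np.ascontiguousarray(y.transpose(1, 0, 2, 3))
    if b is not None:
        y = y + b.data.reshape(1, -1, 1, 1)
    prev = (x, w) + ((b,) if b is not None else ())
    out = Tensor(y, _prev=prev)

    def _back(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.tensordot(g, cols, axes=([0, 2, 3], [0, 4, 5]))  # (O, C, kh, kw)
            w._accum(gw.astype(w.data.dtype, copy=False))
        if x.requires_grad:
            tmp = np.tensordot(g, w.data, axes=([1], [0]))  # (N, oh, ow, C, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += tmp[..., i, j].transpose(0, 3, 1, 2)
            if padding:
                dxp = dxp[:, :, padding : padding + h, padding : padding + wd]
            x._accum(dxp)

    out._backward = _back
    return out


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 2) -> Tensor:
    """Transposed convolution with kernel == stride (exact upsampling).

    x: (N, C, H, W); w: (C, O, k, k); output (N, O, H*k, W*k).
    """
    k = stride
    if w.shape[2] != k or w.shape[3] != k:
        raise ValueError("conv_transpose2d requires kernel size == stride")
    n, c, h, wd = x.shape
    o = w.shape[1]
    y = np.zeros((n, o, h * k, wd * k), dtype=x.data.dtype)
    for i in range(k):
        for j in range(k):
            y[:, :, i::k, j::k] = np.tensordot(x.data, w.data[:, :, i, j], axes=([1], [0])).transpose(0, 3, 1, 2)
    if b is not None:
        y = y + b.data.reshape(1, -1, 1, 1)
    prev = (x, w) + ((b,) if b is not None else ())
    out = Tensor(y, _prev=prev)

    def _back(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.zeros_like(w.data)
            for i in range(k):
                for j in range(k):
                    gw[:, :, i, j] = np.tensordot(
                        x.data, g[:, :, i::k, j::k], axes=([0, 2, 3], [0, 2, 3])
                    )
            w._accum(gw)
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            for i in range(k):
                for j in range(k):
                    gx += np.tensordot(g[:, :, i::k, j::k], w.data[:, :, i, j], axes=([1], [1])).transpose(0, 3, 1, 2)
            x._accum(gx)

    out._backward = _back
    return out


def maxpool2d(x: Tensor, kernel: int = 2, stride: int | None = None, padding: int = 0) -> Tensor:
    s = stride or kernel
    k = kernel
    n, c, h, w = x.shape
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)), constant_values=-np.inf)
    oh = (h + 2 * padding - k) // s + 1
    ow = (w + 2 * padding - k) // s + 1
    cols = _patches(xp, k, k, s, s, oh, ow).reshape(n, c, k * k, oh, ow)
    arg = cols.argmax(axis=2)
    y = np.take_along_axis(cols, arg[:, :, None], axis=2)[:, :, 0]
    out = Tensor(y, _prev=(x,))

    def _back(g):
        if not x.requires_grad:
            return
        dxp = np.zeros(
            (n, c, h + 2 * padding, w + 2 * padding), dtype=x.data.dtype
        )
        for idx in range(k * k):
            i, j = divmod(idx, k)
            m = (arg == idx) * g
            dxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += m
        if padding:
            dxp = dxp[:, :, padding : padding + h, padding : padding + w]
        x._accum(dxp)

    out._backward = _back
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, _prev=(x,))

    def _back(g):
        if x.requires_grad:
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accum(y * (g - dot))

    out._backward = _back
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(gamma.data * xhat + beta.data, _prev=(x, gamma, beta))
    d = x.shape[-1]

    def _back(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).reshape(-1, d).sum(axis=0))
        if beta.requires_grad:
            beta._accum(g.reshape(-1, d).sum(axis=0))
        if x.requires_grad:
            gh = g * gamma.data
            term = gh - gh.mean(axis=-1, keepdims=True) - xhat * (gh * xhat).mean(axis=-1, keepdims=True)
            x._accum(term * inv)

    out._backward = _back
    return out


def sparse_cross_entropy(logits: Tensor, labels: np.ndarray, axis: int = 1) -> Tensor:
    """Mean cross-entropy of integer labels against softmax(logits, axis)."""
    labels = np.asarray(labels, dtype=np.int64)
    z = logits.data - logits.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)
    logp = z - np.log(e.sum(axis=axis, keepdims=True))
    picked = np.take_along_axis(logp, np.expand_dims(labels, axis), axis=axis)
    count = labels.size
    out = Tensor(np.asarray(-picked.sum() / count, dtype=logits.data.dtype), _prev=(logits,))

    def _back(g):
        if not logits.requires_grad:
            return
        onehot = np.zeros_like(p)
        np.put_along_axis(onehot, np.expand_dims(labels, axis), 1.0, axis=axis)
        logits._accum((p - onehot) * (float(g) / count))

    out._backward = _back
    return out
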