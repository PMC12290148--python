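"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float32 ndarray plus an optional gradient. Ops build
a DAG of parents and backward closures; :meth:`Tensor.backward` runs a
topological sweep. The op set is exactly what the segmentation networks need:
2-D convolution (stride / padding / dilation), batch normalization, average
pooling, bilinear resize, channel concatenation, pointwise nonlinearities and
scalar reductions. Everything is single-threaded numpy, so results are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add", "sub", "mul", "div", "neg", "log", "abs_", "clamp",
    "relu", "leaky_relu", "sigmoid",
    "sum_", "mean",
    "reshape", "concat",
    "conv2d", "avg_pool2d", "bilinear_resize", "batch_norm",
]


def _as_f32(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype != np.float32:
        a = a.astype(np.float32)
    return a


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction of graph nodes -------------------------------------
    @staticmethod
    def _result(data, parents, backward):
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        else:
            out._parents = ()
            out._backward = None
        return out

    # -- basic protocol ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # operators
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def sum(self):
        return sum_(self)

    def mean(self):
        return mean(self)

    # -- backward pass ----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep graphs would blow the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate grads/graph as we go; leaves keep theirs
                if node is not self:
                    node.grad = None
                node._backward = None
                node._parents = ()


def _t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _acc(t: Tensor, g: np.ndarray) -> None:
    # accumulation never mutates in place, so sharing g between parents is safe
    if t.requires_grad:
        t.grad = g if t.grad is None else t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _t(a), _t(b)
    out_data = a.data + b.data

    def backward(g):
        _acc(a, _unbroadcast(g, a.data.shape))
        _acc(b, _unbroadcast(g, b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def sub(a, b) -> Tensor:
    a, b = _t(a), _t(b)
    out_data = a.data - b.data

    def backward(g):
        _acc(a, _unbroadcast(g, a.data.shape))
        _acc(b, _unbroadcast(-g, b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def neg(a) -> Tensor:
    a = _t(a)
    return Tensor._result(-a.data, (a,), lambda g: _acc(a, -g))


def mul(a, b) -> Tensor:
    a, b = _t(a), _t(b)
    out_data = a.data * b.data

    def backward(g):
        _acc(a, _unbroadcast(g * b.data, a.data.shape))
        _acc(b, _unbroadcast(g * a.data, b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = _t(a), _t(b)
    out_data = a.data / b.data

    def backward(g):
        _acc(a, _unbroadcast(g / b.data, a.data.shape))
        _acc(b, _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def log(a) -> Tensor:
    a = _t(a)
    return Tensor._result(np.log(a.data), (a,), lambda g: _acc(a, g / a.data))


def abs_(a) -> Tensor:
    a = _t(a)
    sign = np.sign(a.data)
    return Tensor._result(np.abs(a.data), (a,), lambda g: _acc(a, g * sign))


def clamp(a, lo: float, hi: float) -> Tensor:
    a = _t(a)
    out_data = np.clip(a.data, lo, hi)
    inside = ((a.data >= lo) & (a.data <= hi)).astype(np.float32)
    return Tensor._result(out_data, (a,), lambda g: _acc(a, g * inside))


# ---------------------------------------------------------------------------
# nonlinearities
# ---------------------------------------------------------------------------

def relu(a) -> Tensor:
    a = _t(a)
    mask = a.data > 0
    return Tensor._result(np.where(mask, a.data, 0.0), (a,),
                          lambda g: _acc(a, g * mask))


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = _t(a)
    mask = a.data > 0
    scale = np.where(mask, np.float32(1.0), np.float32(slope))
    return Tensor._result(a.data * scale, (a,), lambda g: _acc(a, g * scale))


def sigmoid(a) -> Tensor:
    a = _t(a)
    # numerically stable logistic
    y = np.empty_like(a.data)
    pos = a.data >= 0
    y[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    e = np.exp(a.data[~pos])
    y[~pos] = e / (1.0 + e)
    return Tensor._result(y, (a,), lambda g: _acc(a, g * y * (1.0 - y)))


# ---------------------------------------------------------------------------
# reductions / shape
# ---------------------------------------------------------------------------

def sum_(a) -> Tensor:
    a = _t(a)
    out_data = np.asarray(a.data.sum(), dtype=np.float32)
    return Tensor._result(out_data, (a,),
                          lambda g: _acc(a, np.broadcast_to(g, a.data.shape).astype(np.float32)))


def mean(a) -> Tensor:
    a = _t(a)
    n = a.data.size
    out_data = np.asarray(a.data.mean(), dtype=np.float32)
    return Tensor._result(out_data, (a,),
                          lambda g: _acc(a, np.broadcast_to(g / n, a.data.shape).astype(np.float32)))


def reshape(a, shape) -> Tensor:
    a = _t(a)
    old = a.data.shape
    return Tensor._result(a.data.reshape(shape), (a,),
                          lambda g: _acc(a, g.reshape(old)))


def concat(tensors, axis: int = 1) -> Tensor:
    ts = [_t(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(ts, np.split(g, splits, axis=axis)):
            _acc(t, piece)

    return Tensor._result(out_data, tuple(ts), backward)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, s: int, d: int,
            ho: int, wo: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> (N*ho*wo, C*kh*kw) patch matrix (copies once)."""
    win = np.lib.stride_tricks.sliding_window_view(
        xp, (d * (kh - 1) + 1, d * (kw - 1) + 1), axis=(2, 3))
    # dilated taps, then strided output positions
    win = win[:, :, ::s, ::s, ::d, ::d][:, :, :ho, :wo]
    n, c = xp.shape[:2]
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)


def conv2d(x, w, b=None, stride: int = 1, padding: int = 0,
           dilation: int = 1) -> Tensor:
    """2-D cross-correlation over NCHW input with OIHW weights."""
    x, w = _t(x), _t(w)
    if b is not None:
        b = _t(b)
    n, c, h, wi = x.data.shape
    o, ci, kh, kw = w.data.shape
    if ci != c:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {ci}")
    s, p, d = stride, padding, dilation
    ho = (h + 2 * p - d * (kh - 1) - 1) // s + 1
    wo = (wi + 2 * p - d * (kw - 1) - 1) // s + 1
    if ho < 1 or wo < 1:
        raise ValueError(
            f"conv2d: input {h}x{wi} too small for kernel {kh} dilation {d} stride {s}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    pat = _im2col(xp, kh, kw, s, d, ho, wo)
    wmat = w.data.reshape(o, c * kh * kw)
    out = (pat @ wmat.T).reshape(n, ho, wo, o).transpose(0, 3, 1, 2)
    if b is not None:
        out = out + b.data.reshape(1, o, 1, 1)
    out = np.ascontiguousarray(out)

    parents = (x, w) if b is None else (x, w, b)
    if not any(t.requires_grad for t in parents):
        return Tensor._result(out, parents, None)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, o)
        if w.requires_grad:
            _acc(w, (gmat.T @ pat).reshape(o, c, kh, kw))
        if b is not None and b.requires_grad:
            _acc(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gpat = (gmat @ wmat).reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
            gxp = np.zeros_like(xp)
            for ki in range(kh):
                for kj in range(kw):
                    gxp[:, :, ki * d: ki * d + s * ho: s,
                        kj * d: kj * d + s * wo: s] += gpat[:, :, :, :, ki, kj]
            _acc(x, gxp[:, :, p:p + h, p:p + wi] if p else gxp)

    return Tensor._result(out, parents, backward)


# ---------------------------------------------------------------------------
# pooling / resampling
# ---------------------------------------------------------------------------

def avg_pool2d(x, k: int = 2) -> Tensor:
    x = _t(x)
    n, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"avg_pool2d: spatial dims ({h},{w}) not divisible by {k}")
    out_data = x.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(g):
        gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        _acc(x, gx.astype(np.float32))

    return Tensor._result(out_data, (x,), backward)


_RESIZE_CACHE: dict[tuple[int, int], tuple] = {}


def _resize_coeffs(n_in: int, n_out: int):
    """Bilinear interpolation taps (align_corners=False) along one axis."""
    key = (n_in, n_out)
    hit = _RESIZE_CACHE.get(key)
    if hit is not None:
        return hit
    src = (np.arange(n_out, dtype=np.float64) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(np.int64)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = (src - i0).astype(np.float32)
    w0 = 1.0 - w1
    # dense transpose operator for the backward scatter
    a_t = np.zeros((n_in, n_out), dtype=np.float32)
    a_t[i0, np.arange(n_out)] += w0
    a_t[i1, np.arange(n_out)] += w1
    hit = (i0, i1, w0, w1, a_t)
    _RESIZE_CACHE[key] = hit
    return hit


def bilinear_resize(x, size: tuple[int, int]) -> Tensor:
    """Resize an NCHW tensor to (ho, wo) with bilinear interpolation."""
    x = _t(x)
    n, c, h, w = x.data.shape
    ho, wo = size
    i0h, i1h, w0h, w1h, ath = _resize_coeffs(h, ho)
    i0w, i1w, w0w, w1w, atw = _resize_coeffs(w, wo)
    tmp = x.data[:, :, i0h, :] * w0h[:, None] + x.data[:, :, i1h, :] * w1h[:, None]
    out_data = tmp[:, :, :, i0w] * w0w + tmp[:, :, :, i1w] * w1w

    def backward(g):
        # exact transpose of the forward linear map, one axis at a time
        gtmp = np.einsum("nchw,vw->nchv", g, atw, optimize=True)
        gx = np.einsum("uh,nchv->ncuv", ath, gtmp, optimize=True)
        _acc(x, gx.astype(np.float32))

    return Tensor._result(out_data.astype(np.float32), (x,), backward)


# ---------------------------------------------------------------------------
# batch normalization
# ---------------------------------------------------------------------------

def batch_norm(x, gamma, beta, running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch norm over (N,H,W). Updates running stats in place."""
    x, gamma, beta = _t(x), _t(gamma), _t(beta)
    axes = (0, 2, 3)
    c = x.data.shape[1]
    gsh = (1, c, 1, 1)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        m = x.data.size // c
        running_mean *= (1 - momentum)
        running_mean += momentum * mu
        running_var *= (1 - momentum)
        running_var += momentum * (var * m / max(m - 1, 1))  # unbiased for stats
    else:
        mu = running_mean
        var = running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(gsh)) * inv.reshape(gsh)
    out_data = (xhat * gamma.data.reshape(gsh) + beta.data.reshape(gsh)).astype(np.float32)

    def backward(g):
        if gamma.requires_grad:
            _acc(gamma, (g * xhat).sum(axis=axes))
        if beta.requires_grad:
            _acc(beta, g.sum(axis=axes))
        if x.requires_grad:
            gs = gamma.data.reshape(gsh) * inv.reshape(gsh)
            if training:
                m = x.data.size // c
                gmean = g.mean(axis=axes).reshape(gsh)
                gxhat_mean = (g * xhat).mean(axis=axes).reshape(gsh)
                _acc(x, (gs * (g - gmean - xhat * gxhat_mean)).astype(np.float32))
            else:
                _acc(x, (gs * g).astype(np.float32))

    return Tensor._result(out_data, (x, gamma, beta), backward)
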