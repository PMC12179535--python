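"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the multiple-instance network needs:
broadcast arithmetic, matmul, relu/tanh/sigmoid, reductions, softmax,
softmax cross-entropy, 2-D convolution (im2col), average/max pooling and
global average pooling.  Arrays are float32 by default (see ``DTYPE``).
Gradients of every op are verified against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: float32 for speed; tests switch to float64 for finite-difference checks
DTYPE = np.float32

__all__ = [
    "Tensor",
    "add", "sub", "mul", "matmul", "relu", "tanh", "sigmoid",
    "tsum", "tmean", "softmax", "softmax_cross_entropy",
    "conv2d", "avg_pool2d", "max_pool2d", "global_avg_pool", "bag_max",
]


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    # convenience operators
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def relu(self):
        return relu(self)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    if out.requires_grad:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray):
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.astype(t.data.dtype, copy=True)
    else:
        t.grad = t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient `g` down to `shape` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def sub(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data - b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(-g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def matmul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    return _make(out_data, (a, b), backward)


def relu(a):
    a = _as_tensor(a)
    mask = a.data > 0
    out_data = a.data * mask

    def backward(g):
        _accum(a, g * mask)

    return _make(out_data, (a,), backward)


def tanh(a):
    a = _as_tensor(a)
    out_data = np.tanh(a.data)

    def backward(g):
        _accum(a, g * (1.0 - out_data * out_data))

    return _make(out_data, (a,), backward)


def sigmoid(a):
    a = _as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        _accum(a, g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def tsum(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        gg = np.asarray(g)
        if axis is not None and not keepdims:
            gg = np.expand_dims(gg, axis)
        _accum(a, np.broadcast_to(gg, a.data.shape).astype(a.data.dtype))

    return _make(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    out_data = a.data.mean(axis=axis, keepdims=keepdims)
    count = a.data.size / out_data.size

    def backward(g):
        gg = np.asarray(g)
        if axis is not None and not keepdims:
            gg = np.expand_dims(gg, axis)
        _accum(a, (np.broadcast_to(gg, a.data.shape) / count).astype(a.data.dtype))

    return _make(out_data, (a,), backward)


def softmax(a, axis=-1):
    a = _as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        inner = (g * p).sum(axis=axis, keepdims=True)
        _accum(a, p * (g - inner))

    return _make(p, (a,), backward)


def softmax_cross_entropy(logits, target: int):
    """Scalar −log softmax(logits)[target]; logits is a (C,) or (1, C) tensor."""
    logits = _as_tensor(logits)
    z = logits.data.reshape(-1)
    z = z - z.max()
    e = np.exp(z)
    p = e / e.sum()
    loss = -np.log(max(p[target], 1e-12))

    def backward(g):
        dz = p.copy()
        dz[target] -= 1.0
        _accum(logits, (g * dz).reshape(logits.data.shape))

    return _make(np.asarray(loss, dtype=logits.data.dtype), (logits,), backward)


# ---------------------------------------------------------------------------
# convolution and pooling (NHWC layout)
# ---------------------------------------------------------------------------

def _unpad_edge_grad(g: np.ndarray, pad: int) -> np.ndarray:
    """Adjoint of np.pad(..., mode='edge') for symmetric spatial padding."""
    if pad == 0:
        return g
    core = g[:, pad:-pad].copy()
    core[:, 0] += g[:, :pad].sum(axis=1)
    core[:, -1] += g[:, -pad:].sum(axis=1)
    g = core
    core = g[:, :, pad:-pad].copy()
    core[:, :, 0] += g[:, :, :pad].sum(axis=2)
    core[:, :, -1] += g[:, :, -pad:].sum(axis=2)
    return core


def conv2d(x, w, b, stride: int = 1, pad: int = 1, pad_mode: str = "edge"):
    """2-D convolution, NHWC input, (kh, kw, Cin, Cout) weights.

    Edge padding keeps spatially constant inputs constant through the layer,
    which matters for sane class-activation maps on uniform tiles.
    """
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    kh, kw, cin, cout = w.data.shape
    if pad:
        mode = "edge" if pad_mode == "edge" else "constant"
        xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad), (0, 0)), mode=mode)
    else:
        xp = x.data
    n, hp, wp, _ = xp.shape
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # (n, hp-kh+1, wp-kw+1, c, kh, kw)
    win = win[:, ::stride, ::stride]
    col = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
        n * oh * ow, kh * kw * cin
    )
    wmat = w.data.reshape(kh * kw * cin, cout)
    out_data = (col @ wmat + b.data).reshape(n, oh, ow, cout)

    def backward(g):
        gflat = g.reshape(n * oh * ow, cout)
        _accum(w, (col.T @ gflat).reshape(w.data.shape))
        _accum(b, gflat.sum(axis=0))
        if x.requires_grad:
            dcol = (gflat @ wmat.T).reshape(n, oh, ow, kh, kw, cin)
            dxp = np.zeros_like(xp)
            for p in range(kh):
                for q in range(kw):
                    dxp[:, p:p + oh * stride:stride, q:q + ow * stride:stride, :] += \
                        dcol[:, :, :, p, q, :]
            if pad:
                if pad_mode == "edge":
                    dx = _unpad_edge_grad(dxp, pad)
                else:
                    dx = dxp[:, pad:-pad, pad:-pad, :]
            else:
                dx = dxp
            _accum(x, dx)

    return _make(out_data, (x, w, b), backward)


def avg_pool2d(x, k: int):
    """Non-overlapping k×k average pooling; H and W must be divisible by k."""
    x = _as_tensor(x)
    n, h, w, c = x.data.shape
    if h % k or w % k:
        raise ValueError(f"spatial dims ({h},{w}) not divisible by pool size {k}")
    r = x.data.reshape(n, h // k, k, w // k, k, c)
    out_data = r.mean(axis=(2, 4))

    def backward(g):
        gg = g[:, :, None, :, None, :] / (k * k)
        _accum(x, np.broadcast_to(gg, r.shape).reshape(n, h, w, c)
               .astype(x.data.dtype))

    return _make(out_data, (x,), backward)


def max_pool2d(x, k: int):
    """Non-overlapping k×k max pooling (ties split the gradient evenly)."""
    x = _as_tensor(x)
    n, h, w, c = x.data.shape
    if h % k or w % k:
        raise ValueError(f"spatial dims ({h},{w}) not divisible by pool size {k}")
    r = x.data.reshape(n, h // k, k, w // k, k, c)
    out_data = r.max(axis=(2, 4))

    def backward(g):
        mask = (r == out_data[:, :, None, :, None, :]).astype(x.data.dtype)
        mask /= mask.sum(axis=(2, 4), keepdims=True)
        gg = g[:, :, None, :, None, :] * mask
        _accum(x, gg.reshape(n, h, w, c).astype(x.data.dtype))

    return _make(out_data, (x,), backward)


def global_avg_pool(x):
    """GAP: (N, H, W, C) → (N, C)."""
    return tmean(x, axis=(1, 2))


def bag_max(x):
    """Element-wise maximum over the bag axis: (N, D) → (1, D).

    The gradient routes to the first arg-max tile per feature, the standard
    sub-gradient choice for MIL max pooling.
    """
    x = _as_tensor(x)
    idx = x.data.argmax(axis=0)
    d = x.data.shape[1]
    out_data = x.data[idx, np.arange(d)].reshape(1, d)

    def backward(g):
        dx = np.zeros_like(x.data)
        dx[idx, np.arange(d)] = g.reshape(d)
        _accum(x, dx)

    return _make(out_data, (x,), backward)
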