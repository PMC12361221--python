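"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the primitive set the segmentation network needs:
elementwise arithmetic, reductions, matmul, reshaping, 2-D convolution with
groups/stride/padding, batch normalisation, pooling, bilinear resampling and
point (bilinear) sampling.  Gradients flow through a tape of closures; a
global switch (:func:`no_grad`) disables tape construction for inference and
profiling.

Arrays keep the dtype they are given (float32 in the network, float64 in
numerical gradient checks).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True

# Multiply-accumulate bookkeeping for profiling (conv/linear convention).
_MAC_COUNTER: dict | None = None


@contextlib.contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


@contextlib.contextmanager
def count_macs(counter: dict):
    """Accumulate conv/linear multiply-accumulates into ``counter['macs']``."""
    global _MAC_COUNTER
    counter.setdefault("macs", 0)
    prev = _MAC_COUNTER
    _MAC_COUNTER = counter
    try:
        yield counter
    finally:
        _MAC_COUNTER = prev


def _add_macs(n: int) -> None:
    if _MAC_COUNTER is not None:
        _MAC_COUNTER["macs"] += int(n)


class Tensor:
    """A numpy array plus an optional gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._prev: tuple[Tensor, ...] = ()

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, dtype={self.dtype}, grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            # copy: g may alias another node's gradient buffer
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
            # free the tape eagerly: breaks closure reference cycles so large
            # intermediate buffers are reclaimed by refcounting, and drops
            # gradients of non-leaf nodes once they have been propagated
            if node._prev:
                node._backward = None
                node._prev = ()
                node.grad = None

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return add(-self, other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / np.asarray(other))

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 or isinstance(shape[0], int) else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return reduce_sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return reduce_mean(self, axis, keepdims)

    def relu(self):
        return relu(self)

    def sigmoid(self):
        return sigmoid(self)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: Sequence[Tensor], backward: Callable[[Tensor], Callable]) -> Tensor:
    """Build an output node; skip tape construction when grads are off."""
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._prev = tuple(parents)
        out._backward = backward(out)
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise & reductions
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def bw(out):
        def run():
            if a.requires_grad:
                a._accumulate(_unbroadcast(out.grad, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(out.grad, b.shape))
        return run

    return _node(data, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def bw(out):
        def run():
            if a.requires_grad:
                a._accumulate(_unbroadcast(out.grad * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(out.grad * a.data, b.shape))
        return run

    return _node(data, (a, b), bw)


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    data = a.data ** p

    def bw(out):
        def run():
            if a.requires_grad:
                a._accumulate(out.grad * p * a.data ** (p - 1.0))
        return run

    return _node(data, (a,), bw)


def exp(a) -> Tensor:
    a = as_tensor(a)
    data = np.exp(a.data)

    def bw(out):
        def run():
            if a.requires_grad:
                a._accumulate(out.grad * out.data)
        return run

    return _node(data, (a,), bw)


def log(a) -> Tensor:
    a = as_tensor(a)
    data = np.log(a.data)

    def bw(out):
        def run():
            if a.requires_grad:
                a._accumulate(out.grad / a.data)
        return run

    return _node(data, (a,), bw)


def reduce_sum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(out):
        def run():
            if not a.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.shape).copy())
        return run

    return _node(data, (a,), bw)


def reduce_mean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.size if axis is None else np.prod([a.shape[i] for i in np.atleast_1d(axis)])
    return mul(reduce_sum(a, axis, keepdims), 1.0 / float(n))


def relu(a) -> Tensor:
    a = as_tensor(a)
    data = np.maximum(a.data, 0)

    def bw(out):
        def run():
            if a.requires_grad:
                a._accumulate(out.grad * (a.data > 0))
        return run

    return _node(data, (a,), bw)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    data = 1.0 / (1.0 + np.exp(-a.data))

    def bw(out):
        def run():
            if a.requires_grad:
                a._accumulate(out.grad * out.data * (1.0 - out.data))
        return run

    return _node(data, (a,), bw)


def softmax(a, axis: int = 1) -> Tensor:
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    data = e / e.sum(axis=axis, keepdims=True)

    def bw(out):
        def run():
            if a.requires_grad:
                s = out.data
                g = out.grad
                a._accumulate(s * (g - (g * s).sum(axis=axis, keepdims=True)))
        return run

    return _node(data, (a,), bw)


# ---------------------------------------------------------------------------
# shape ops
# ---------------------------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    data = a.data.reshape(shape)

    def bw(out):
        def run():
            if a.requires_grad:
                a._accumulate(out.grad.reshape(a.shape))
        return run

    return _node(data, (a,), bw)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    axes = tuple(axes)
    data = a.data.transpose(axes)
    inv = tuple(np.argsort(axes))

    def bw(out):
        def run():
            if a.requires_grad:
                a._accumulate(out.grad.transpose(inv))
        return run

    return _node(data, (a,), bw)


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)
    data = a.data[idx]

    def bw(out):
        def run():
            if a.requires_grad:
                g = np.zeros_like(a.data)
                np.add.at(g, idx, out.grad)
                a._accumulate(g)
        return run

    return _node(data, (a,), bw)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]

    def bw(out):
        def run():
            offs = np.cumsum([0] + sizes)
            for t, lo, hi in zip(ts, offs[:-1], offs[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * out.grad.ndim
                    sl[axis] = slice(lo, hi)
                    t._accumulate(out.grad[tuple(sl)])
        return run

    return _node(data, tuple(ts), bw)


def pad2d(a, pad: tuple[int, int, int, int]) -> Tensor:
    """Zero-pad the last two axes: pad = (top, bottom, left, right)."""
    a = as_tensor(a)
    t, b, l, r = pad
    width = [(0, 0)] * (a.ndim - 2) + [(t, b), (l, r)]
    data = np.pad(a.data, width)

    def bw(out):
        def run():
            if a.requires_grad:
                sl = [slice(None)] * (a.ndim - 2) + [
                    slice(t, t + a.shape[-2]), slice(l, l + a.shape[-1])]
                a._accumulate(out.grad[tuple(sl)])
        return run

    return _node(data, (a,), bw)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data @ b.data

    def bw(out):
        def run():
            if a.requires_grad:
                ga = out.grad @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ out.grad
                b._accumulate(_unbroadcast(gb, b.shape))
        return run

    return _node(data, (a, b), bw)


# ---------------------------------------------------------------------------
# neural-network primitives
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, s: int, ho: int, wo: int) -> np.ndarray:
    """(B,C,Hp,Wp) -> (B, C*kh*kw, ho*wo) with (c, i, j) inner ordering."""
    B, C = xp.shape[:2]
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::s, ::s][:, :, :ho, :wo]          # (B,C,ho,wo,kh,kw)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(B, C * kh * kw, ho * wo)
    return np.ascontiguousarray(cols)


def conv2d(x, w, b=None, stride: int = 1, padding=0, groups: int = 1) -> Tensor:
    """Grouped 2-D cross-correlation.

    x: (B, Ci, H, W); w: (Co, Ci//groups, kh, kw); b: (Co,) or None.
    ``padding`` may be an int or an (ph, pw) pair.
    """
    x, w = as_tensor(x), as_tensor(w)
    B, Ci, H, W = x.shape
    Co, Cig, kh, kw = w.shape
    if Ci != Cig * groups or Co % groups:
        raise ValueError(f"channel/group mismatch: x has {Ci}, w {w.shape}, groups {groups}")
    s = stride
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    ho = (H + 2 * ph - kh) // s + 1
    wo = (W + 2 * pw - kw) // s + 1
    xp = (np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
          if (ph or pw) else x.data)
    cols = _im2col(xp, kh, kw, s, ho, wo).reshape(B, groups, Cig * kh * kw, ho * wo)
    wg = w.data.reshape(groups, Co // groups, Cig * kh * kw)
    out = np.matmul(wg[None], cols)                    # (B, g, Co/g, L)
    out = out.reshape(B, Co, ho, wo)
    if b is not None:
        b = as_tensor(b)
        out = out + b.data.reshape(1, Co, 1, 1)
    _add_macs(B * Co * ho * wo * Cig * kh * kw)

    parents = (x, w) if b is None else (x, w, b)

    def bw(outT):
        def run():
            g = outT.grad.reshape(B, groups, Co // groups, ho * wo)
            if b is not None and b.requires_grad:
                b._accumulate(outT.grad.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                dw = np.matmul(g, cols.transpose(0, 1, 3, 2)).sum(axis=0)
                w._accumulate(dw.reshape(w.shape))
            if x.requires_grad:
                dcols = np.matmul(wg.transpose(0, 2, 1)[None], g)
                dcols = dcols.reshape(B, Ci, kh, kw, ho, wo)
                dxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i:i + ho * s:s, j:j + wo * s:s] += dcols[:, :, i, j]
                if ph or pw:
                    dxp = dxp[:, :, ph:ph + H, pw:pw + W]
                x._accumulate(dxp)
        return run

    return _node(out, parents, bw)


def linear(x, w, b=None) -> Tensor:
    """x: (..., Cin); w: (Cout, Cin); b: (Cout,)."""
    x, w = as_tensor(x), as_tensor(w)
    out = x.data @ w.data.T
    if b is not None:
        b = as_tensor(b)
        out = out + b.data
    _add_macs(out.size // w.shape[0] * w.shape[0] * w.shape[1])
    parents = (x, w) if b is None else (x, w, b)

    def bw(outT):
        def run():
            g = outT.grad
            if b is not None and b.requires_grad:
                b._accumulate(g.reshape(-1, g.shape[-1]).sum(axis=0))
            if w.requires_grad:
                gf = g.reshape(-1, g.shape[-1])
                xf = x.data.reshape(-1, x.shape[-1])
                w._accumulate(gf.T @ xf)
            if x.requires_grad:
                x._accumulate(g @ w.data)
        return run

    return _node(out, parents, bw)


def batch_norm(x, gamma, beta, running_mean, running_var, training: bool,
               momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalisation over (B, H, W) per channel for 4-D input.

    ``running_mean``/``running_var`` are plain numpy buffers updated in place
    during training (biased variance normalises, unbiased updates the buffer).
    """
    x = as_tensor(x)
    gamma, beta = as_tensor(gamma), as_tensor(beta)
    axes = (0, 2, 3) if x.ndim == 4 else (0,)
    shape = [1] * x.ndim
    shape[1 if x.ndim == 4 else -1] = -1
    n = x.size // gamma.size
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        if running_mean is not None:
            running_mean *= (1 - momentum)
            running_mean += momentum * mean
            running_var *= (1 - momentum)
            running_var += momentum * var * (n / max(n - 1, 1))
    else:
        mean, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(shape)) * inv.reshape(shape)
    out = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)

    def bw(outT):
        def run():
            g = outT.grad
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=axes))
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=axes))
            if x.requires_grad:
                gxhat = g * gamma.data.reshape(shape)
                if training:
                    m1 = gxhat.mean(axis=axes, keepdims=True)
                    m2 = (gxhat * xhat).mean(axis=axes, keepdims=True)
                    dx = (gxhat - m1 - xhat * m2) * inv.reshape(shape)
                else:
                    dx = gxhat * inv.reshape(shape)
                x._accumulate(dx)
        return run

    return _node(out, (x, gamma, beta), bw)


def avg_pool2d(x, kernel: int, stride: int | None = None, padding: int = 0) -> Tensor:
    x = as_tensor(x)
    s = stride or kernel
    B, C, H, W = x.shape
    ho = (H + 2 * padding - kernel) // s + 1
    wo = (W + 2 * padding - kernel) // s + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2)) if padding else x.data
    win = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    win = win[:, :, ::s, ::s][:, :, :ho, :wo]
    out = win.mean(axis=(4, 5))

    def bw(outT):
        def run():
            if not x.requires_grad:
                return
            g = outT.grad / (kernel * kernel)
            dxp = np.zeros_like(xp)
            for i in range(kernel):
                for j in range(kernel):
                    dxp[:, :, i:i + ho * s:s, j:j + wo * s:s] += g
            if padding:
                dxp = dxp[:, :, padding:padding + H, padding:padding + W]
            x._accumulate(dxp)
        return run

    return _node(out, (x,), bw)


def max_pool2d(x, kernel: int, stride: int, padding: int = 0) -> Tensor:
    x = as_tensor(x)
    B, C, H, W = x.shape
    s = stride
    ho = (H + 2 * padding - kernel) // s + 1
    wo = (W + 2 * padding - kernel) // s + 1
    fill = -np.inf
    xp = np.full((B, C, H + 2 * padding, W + 2 * padding), fill, dtype=x.dtype)
    xp[:, :, padding:padding + H, padding:padding + W] = x.data
    win = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    win = win[:, :, ::s, ::s][:, :, :ho, :wo].reshape(B, C, ho, wo, kernel * kernel)
    arg = win.argmax(axis=-1)
    out = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]

    def bw(outT):
        def run():
            if not x.requires_grad:
                return
            dxp = np.zeros((B, C, H + 2 * padding, W + 2 * padding), dtype=x.dtype)
            ki, kj = np.divmod(arg, kernel)
            bi, ci, oi, oj = np.indices((B, C, ho, wo), sparse=False)
            np.add.at(dxp, (bi, ci, oi * s + ki, oj * s + kj), outT.grad)
            x._accumulate(dxp[:, :, padding:padding + H, padding:padding + W])
        return run

    return _node(out, (x,), bw)


_RESIZE_CACHE: dict = {}


def _resize_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """Bilinear interpolation matrix (n_out x n_in), align_corners=False."""
    key = (n_in, n_out, np.dtype(dtype).name)
    if key in _RESIZE_CACHE:
        return _RESIZE_CACHE[key]
    m = np.zeros((n_out, n_in), dtype=dtype)
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    f = src - i0
    np.add.at(m, (np.arange(n_out), i0), 1 - f)
    np.add.at(m, (np.arange(n_out), i1), f)
    if len(_RESIZE_CACHE) < 64:
        _RESIZE_CACHE[key] = m
    return m


def interpolate_bilinear(x, size: tuple[int, int]) -> Tensor:
    """Resize (B,C,H,W) to ``size`` with bilinear weights, align_corners=False."""
    x = as_tensor(x)
    B, C, H, W = x.shape
    Ho, Wo = size
    My = _resize_matrix(H, Ho, x.dtype)
    Mx = _resize_matrix(W, Wo, x.dtype)
    flat = x.data.reshape(B * C, H, W)
    out = (My @ flat @ Mx.T).reshape(B, C, Ho, Wo)

    def bw(outT):
        def run():
            if x.requires_grad:
                g = outT.grad.reshape(B * C, Ho, Wo)
                x._accumulate((My.T @ g @ Mx).reshape(B, C, H, W))
        return run

    return _node(out, (x,), bw)


def point_sample(x, coords: np.ndarray) -> Tensor:
    """Bilinear sampling of (B,C,H,W) at normalised coords (B,N,2) = (x, y).

    Pixel centres sit at ((col + 0.5)/W, (row + 0.5)/H); borders clamp.
    Coordinates are constants (no gradient).
    """
    x = as_tensor(x)
    B, C, H, W = x.shape
    N = coords.shape[1]
    px = np.clip(coords[..., 0] * W - 0.5, 0, W - 1)
    py = np.clip(coords[..., 1] * H - 0.5, 0, H - 1)
    x0 = np.floor(px).astype(int)
    y0 = np.floor(py).astype(int)
    x1 = np.minimum(x0 + 1, W - 1)
    y1 = np.minimum(y0 + 1, H - 1)
    fx = (px - x0).astype(x.dtype)
    fy = (py - y0).astype(x.dtype)
    bi = np.arange(B)[:, None]
    w00 = ((1 - fx) * (1 - fy))[:, None]
    w01 = (fx * (1 - fy))[:, None]
    w10 = ((1 - fx) * fy)[:, None]
    w11 = (fx * fy)[:, None]
    xc = x.data.transpose(0, 2, 3, 1)                  # (B,H,W,C)
    g00 = xc[bi, y0, x0]
    g01 = xc[bi, y0, x1]
    g10 = xc[bi, y1, x0]
    g11 = xc[bi, y1, x1]
    out = (w00.transpose(0, 2, 1) * g00 + w01.transpose(0, 2, 1) * g01 +
           w10.transpose(0, 2, 1) * g10 + w11.transpose(0, 2, 1) * g11)   # (B,N,C)
    out = out.transpose(0, 2, 1)                                          # (B,C,N)

    def bw(outT):
        def run():
            if not x.requires_grad:
                return
            g = outT.grad.transpose(0, 2, 1)       # (B,N,C)
            dx = np.zeros_like(x.data).transpose(0, 2, 3, 1)  # (B,H,W,C) view-copy
            dx = np.ascontiguousarray(dx)
            np.add.at(dx, (bi, y0, x0), g * w00.transpose(0, 2, 1))
            np.add.at(dx, (bi, y0, x1), g * w01.transpose(0, 2, 1))
            np.add.at(dx, (bi, y1, x0), g * w10.transpose(0, 2, 1))
            np.add.at(dx, (bi, y1, x1), g * w11.transpose(0, 2, 1))
            x._accumulate(dx.transpose(0, 3, 1, 2))
        return run

    return _node(out, (x,), bw)


def cross_entropy(logits, target: np.ndarray) -> Tensor:
    """Mean cross-entropy.

    logits: (B, K) or (B, K, H, W); target: int array (B,) or (B, H, W).
    """
    logits = as_tensor(logits)
    ax = 1
    z = logits.data - logits.data.max(axis=ax, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=ax, keepdims=True))
    logp = z - lse
    t = np.asarray(target)
    if logits.ndim == 4:
        picked = np.take_along_axis(logp, t[:, None], axis=1)[:, 0]
    else:
        picked = np.take_along_axis(logp, t[:, None], axis=1)[:, 0]
    n = picked.size
    loss = -picked.sum() / n

    def bw(outT):
        def run():
            if not logits.requires_grad:
                return
            p = np.exp(logp)
            onehot = np.zeros_like(p)
            np.put_along_axis(onehot, t[:, None] if logits.ndim in (2, 4) else t, 1.0, axis=1)
            logits._accumulate(outT.grad * (p - onehot) / n)
        return run

    return _node(np.asarray(loss, dtype=logits.dtype), (logits,), bw)
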