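"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the detection stack needs: dense and
grouped 2-D convolution, deformable convolution with bilinear sampling and
trainable offsets, batch normalisation, average pooling, nearest-neighbour
upsampling, RoI align, linear layers and the detection losses.  Gradients are
hand-derived per operator and verified by finite differences in the test
suite.

Tensors wrap ``numpy.ndarray`` values.  Calling :meth:`Tensor.backward` on a
scalar loss walks the recorded graph in reverse topological order and
accumulates ``.grad`` arrays on every tensor with ``requires_grad=True``.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "no_grad",
    "add",
    "mul",
    "matmul",
    "relu",
    "reshape",
    "concat",
    "conv2d",
    "deform_conv2d",
    "avg_pool2d",
    "upsample_nearest2x",
    "batch_norm2d",
    "roi_align",
    "linear",
    "softmax_cross_entropy",
    "sigmoid_bce",
    "smooth_l1",
]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    """A numpy array plus an optional backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=g.dtype if self.data.dtype.kind != "f" else self.data.dtype)
        self.grad = self.grad + g

    # -- graph ----------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar tensor")
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- sugar ----------------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _make(data: np.ndarray, parents: Sequence[Tensor], backward: Callable[[np.ndarray], None]) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce gradient ``g`` to ``shape`` undoing numpy broadcasting."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# ---------------------------------------------------------------------------
# elementwise / linear algebra
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.data.shape))

    return _make(out, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(g @ b.data.T)
        if b.requires_grad:
            b.accumulate(a.data.T @ g)

    return _make(out, (a, b), backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """``x @ w.T + b`` with ``w`` of shape (out, in)."""
    out = x.data @ w.data.T
    if b is not None:
        out = out + b.data

    def backward(g):
        if x.requires_grad:
            x.accumulate(g @ w.data)
        if w.requires_grad:
            w.accumulate(g.T @ x.data)
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=0))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def backward(g):
        if x.requires_grad:
            x.accumulate(g * mask)

    return _make(out, (x,), backward)


def reshape(x: Tensor, shape) -> Tensor:
    out = x.data.reshape(shape)

    def backward(g):
        if x.requires_grad:
            x.accumulate(g.reshape(x.data.shape))

    return _make(out, (x,), backward)


def permute(x: Tensor, axes) -> Tensor:
    axes = tuple(axes)
    out = x.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        if x.requires_grad:
            x.accumulate(g.transpose(inv))

    return _make(out, (x,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]

    def backward(g):
        offset = 0
        for t, s in zip(tensors, sizes):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(offset, offset + s)
                t.accumulate(g[tuple(idx)])
            offset += s

    return _make(out, tensors, backward)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, groups: int = 1) -> Tensor:
    """Grouped 2-D convolution, NCHW layout, weight (Co, Ci/groups, kh, kw)."""
    xd, wd = x.data, w.data
    N, Ci, H, W = xd.shape
    Co, Cig, kh, kw = wd.shape
    g = groups
    if Ci != Cig * g or Co % g:
        raise ValueError(
            f"conv2d channel mismatch: input {Ci}, weight {wd.shape}, groups {g}")
    s = stride
    Ho = (H + 2 * padding - kh) // s + 1
    Wo = (W + 2 * padding - kw) // s + 1
    if Ho <= 0 or Wo <= 0:
        raise ValueError("conv2d: kernel larger than padded input")
    if kh == kw == 1 and padding == 0:
        return _conv1x1(x, w, b, stride, g)
    xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else xd
    Kf = Cig * kh * kw
    # im2col: (N, Ci, Hp-kh+1, Wp-kw+1, kh, kw) view, strided to the output grid
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::s, ::s]
    # (g, N*Ho*Wo, Cig*kh*kw) copy for batched matmul
    cols = np.ascontiguousarray(win.transpose(1, 0, 2, 3, 4, 5)).reshape(
        g, Cig, N * Ho * Wo, kh * kw).transpose(0, 2, 1, 3).reshape(g, N * Ho * Wo, Kf)
    wm = wd.reshape(g, Co // g, Kf)
    y = np.matmul(cols, wm.transpose(0, 2, 1))            # (g, NHW, Cog)
    y = y.reshape(g, N, Ho, Wo, Co // g).transpose(1, 0, 4, 2, 3).reshape(N, Co, Ho, Wo)
    if b is not None:
        y = y + b.data.reshape(1, Co, 1, 1)

    def backward(gy):
        gym = gy.reshape(N, g, Co // g, Ho, Wo).transpose(
            1, 0, 3, 4, 2).reshape(g, N * Ho * Wo, Co // g)
        if w.requires_grad:
            dw = np.matmul(gym.transpose(0, 2, 1), cols)  # (g, Cog, Kf)
            w.accumulate(dw.reshape(wd.shape))
        if x.requires_grad:
            dcols = np.matmul(gym, wm)                    # (g, NHW, Kf)
            dcols = dcols.reshape(g, N, Ho, Wo, Cig, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += (
                        dcols[:, :, :, :, :, i, j].transpose(1, 0, 4, 2, 3).reshape(N, Ci, Ho, Wo))
            if padding:
                dxp = dxp[:, :, padding:padding + H, padding:padding + W]
            x.accumulate(dxp)
        if b is not None and b.requires_grad:
            b.accumulate(gy.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return _make(y, parents, backward)


def _conv1x1(x: Tensor, w: Tensor, b: Tensor | None, stride: int, g: int) -> Tensor:
    """1×1 convolution as a pure channel matmul (no im2col copies)."""
    xd, wd = x.data, w.data
    N, Ci, H, W = xd.shape
    Co = wd.shape[0]
    Cig, Cog = Ci // g, Co // g
    xs = xd[:, :, ::stride, ::stride]
    Ho, Wo = xs.shape[2:]
    xm = xs.reshape(N, g, Cig, Ho * Wo)
    wm = wd.reshape(g, Cog, Cig)
    y = np.matmul(wm[None], xm).reshape(N, Co, Ho, Wo)
    if b is not None:
        y = y + b.data.reshape(1, Co, 1, 1)

    def backward(gy):
        gym = gy.reshape(N, g, Cog, Ho * Wo)
        if w.requires_grad:
            dw = np.matmul(gym, xm.transpose(0, 1, 3, 2)).sum(axis=0)
            w.accumulate(dw.reshape(wd.shape))
        if x.requires_grad:
            dxs = np.matmul(wm.transpose(0, 2, 1)[None], gym).reshape(N, Ci, Ho, Wo)
            if stride == 1:
                x.accumulate(dxs)
            else:
                dx = np.zeros_like(xd)
                dx[:, :, ::stride, ::stride] = dxs
                x.accumulate(dx)
        if b is not None and b.requires_grad:
            b.accumulate(gy.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return _make(y, parents, backward)


def _bilinear_gather(xd: np.ndarray, py: np.ndarray, px: np.ndarray):
    """Sample xd (N,C,H,W) at fractional (py, px) of shape (N, *S).

    Out-of-bounds positions contribute zero.  Returns the sampled values
    (N, *S, C) plus the pieces needed for gradients.
    """
    N, C, H, W = xd.shape
    y0 = np.floor(py)
    x0 = np.floor(px)
    ty = py - y0
    tx = px - x0
    y0 = y0.astype(np.int64)
    x0 = x0.astype(np.int64)
    nn = np.arange(N).reshape((N,) + (1,) * (py.ndim - 1))
    nn = np.broadcast_to(nn, py.shape)
    corners = []
    for dy_, dx_ in ((0, 0), (0, 1), (1, 0), (1, 1)):
        yy = y0 + dy_
        xx = x0 + dx_
        valid = (yy >= 0) & (yy < H) & (xx >= 0) & (xx < W)
        yc = np.clip(yy, 0, H - 1)
        xc = np.clip(xx, 0, W - 1)
        val = xd[nn, :, yc, xc] * valid[..., None]  # (N, *S, C)
        wy = (1.0 - ty) if dy_ == 0 else ty
        wx = (1.0 - tx) if dx_ == 0 else tx
        corners.append((val, wy * wx, wy, wx, dy_, dx_, yc, xc, valid))
    sampled = sum(val * wgt[..., None] for val, wgt, *_ in corners)
    return sampled, corners, (nn, ty, tx)


def deform_conv2d(x: Tensor, w: Tensor, offsets: Tensor, b: Tensor | None = None,
                  stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """Deformable 2-D convolution.

    Each kernel tap ``Pn`` samples the input at ``P0 + Pn + ΔPn`` where the
    per-location fractional displacements ``ΔPn`` come from ``offsets`` of
    shape (N, 2·K, Ho, Wo) — channel ``2k`` is the row (y) displacement of tap
    ``k``, channel ``2k+1`` the column (x) displacement, taps in row-major
    kernel order.  Fractional positions are bilinearly interpolated;
    out-of-bounds samples contribute zero.  Gradients flow to the input, the
    weights and the offsets.
    """
    xd, wd, od = x.data, w.data, offsets.data
    N, Ci, H, W = xd.shape
    Co, Cig, kh, kw = wd.shape
    K = kh * kw
    g = groups
    if Ci != Cig * g or Co % g:
        raise ValueError(f"deform_conv2d channel mismatch: input {Ci}, weight {wd.shape}, groups {g}")
    s = stride
    Ho = (H + 2 * padding - kh) // s + 1
    Wo = (W + 2 * padding - kw) // s + 1
    if od.shape != (N, 2 * K, Ho, Wo):
        raise ValueError(
            f"offset shape {od.shape} incompatible with kernel {kh}x{kw} and output {Ho}x{Wo}: "
            f"expected {(N, 2 * K, Ho, Wo)}")
    # sampling positions per tap, in input coordinates
    oy = (np.arange(Ho) * s - padding).astype(od.dtype)
    ox = (np.arange(Wo) * s - padding).astype(od.dtype)
    ki, kj = (a.astype(od.dtype) for a in np.divmod(np.arange(K), kw))
    py = od[:, 0::2] + oy[None, None, :, None] + ki[None, :, None, None]   # (N,K,Ho,Wo)
    px = od[:, 1::2] + ox[None, None, None, :] + kj[None, :, None, None]
    sampled, corners, (nn, ty, tx) = _bilinear_gather(xd, py, px)          # (N,K,Ho,Wo,Ci)
    smp = sampled.reshape(N, K, Ho, Wo, g, Cig)
    wg = wd.reshape(g, Co // g, Cig, kh, kw).reshape(g, Co // g, Cig, K)
    y = np.einsum("nkhwgc,gock->ngohw", smp, wg, optimize=True).reshape(N, Co, Ho, Wo)
    if b is not None:
        y = y + b.data.reshape(1, Co, 1, 1)

    def backward(gy):
        gyg = gy.reshape(N, g, Co // g, Ho, Wo)
        if w.requires_grad:
            dw = np.einsum("nkhwgc,ngohw->gock", smp, gyg, optimize=True)
            w.accumulate(dw.reshape(Co, Cig, kh, kw))
        need_x = x.requires_grad
        need_o = offsets.requires_grad
        if need_x or need_o:
            dsmp = np.einsum("ngohw,gock->nkhwgc", gyg, wg, optimize=True)
            dsmp = dsmp.reshape(N, K, Ho, Wo, Ci)
            if need_x:
                dx = np.zeros((N * H * W, Ci), dtype=xd.dtype)
            dpy = np.zeros_like(py) if need_o else None
            dpx = np.zeros_like(px) if need_o else None
            for val, wgt, wy, wx, dy_, dx_, yc, xc, valid in corners:
                if need_x:
                    contrib = dsmp * (wgt * valid)[..., None]
                    flat = ((nn * H + yc) * W + xc)[valid]
                    np.add.at(dx, flat, contrib[valid])
                if need_o:
                    # d(weight)/dpy: sign of the ty factor; likewise for px
                    per = (dsmp * val).sum(axis=-1)
                    sy = -1.0 if dy_ == 0 else 1.0
                    sx = -1.0 if dx_ == 0 else 1.0
                    dpy += per * sy * wx
                    dpx += per * sx * wy
            if need_x:
                x.accumulate(np.moveaxis(dx.reshape(N, H, W, Ci), 3, 1))
            if need_o:
                do = np.empty_like(od)
                do[:, 0::2] = dpy
                do[:, 1::2] = dpx
                offsets.accumulate(do)
        if b is not None and b.requires_grad:
            b.accumulate(gy.sum(axis=(0, 2, 3)))

    parents = [x, w, offsets] + ([b] if b is not None else [])
    return _make(y, parents, backward)


# ---------------------------------------------------------------------------
# pooling / resampling
# ---------------------------------------------------------------------------

def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """k×k average pooling with stride k; odd trailing rows/cols are
    replicate-padded so no position is dropped."""
    xd = x.data
    N, C, H, W = xd.shape
    ph = (-H) % k
    pw = (-W) % k
    xp = np.pad(xd, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="edge") if (ph or pw) else xd
    Hp, Wp = xp.shape[2:]
    Ho, Wo = Hp // k, Wp // k
    y = xp.reshape(N, C, Ho, k, Wo, k).mean(axis=(3, 5))

    def backward(g):
        if not x.requires_grad:
            return
        gp = np.broadcast_to(g[:, :, :, None, :, None] / (k * k), (N, C, Ho, k, Wo, k))
        gp = gp.reshape(N, C, Hp, Wp)
        if ph or pw:
            dx = gp[:, :, :H, :W].copy()
            if ph:
                dx[:, :, H - 1, :] += gp[:, :, H:, :W].sum(axis=2)
            if pw:
                dx[:, :, :, W - 1] += gp[:, :, :H, W:].sum(axis=3)
            if ph and pw:
                dx[:, :, H - 1, W - 1] += gp[:, :, H:, W:].sum(axis=(2, 3))
        else:
            dx = gp
        x.accumulate(dx)

    return _make(y, (x,), backward)


def upsample_nearest2x(x: Tensor, out_hw: tuple[int, int] | None = None) -> Tensor:
    """Nearest-neighbour 2× upsampling, optionally cropped to ``out_hw``."""
    xd = x.data
    N, C, H, W = xd.shape
    y = xd.repeat(2, axis=2).repeat(2, axis=3)
    th, tw = out_hw if out_hw is not None else (2 * H, 2 * W)
    if th > 2 * H or tw > 2 * W:
        raise ValueError(f"cannot crop {2*H}x{2*W} upsample to larger {th}x{tw}")
    y = y[:, :, :th, :tw]

    def backward(g):
        if not x.requires_grad:
            return
        gfull = np.zeros((N, C, 2 * H, 2 * W), dtype=g.dtype)
        gfull[:, :, :th, :tw] = g
        x.accumulate(gfull.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))

    return _make(y, (x,), backward)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
                 running_var: np.ndarray, training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """Batch normalisation over (N, H, W) per channel.

    ``running_mean``/``running_var`` are plain arrays updated in place during
    training and used verbatim in eval mode.
    """
    xd = x.data
    N, C, H, W = xd.shape
    if training:
        mu = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu = running_mean
        var = running_var
    mu = mu.astype(xd.dtype, copy=False)
    inv_std = (1.0 / np.sqrt(var + eps)).astype(xd.dtype)
    xhat = (xd - mu[None, :, None, None]) * inv_std[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if gamma.requires_grad:
            gamma.accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta.accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gs = g * gamma.data[None, :, None, None]
            if training:
                m = N * H * W
                term1 = gs
                term2 = gs.mean(axis=(0, 2, 3), keepdims=True)
                term3 = xhat * (gs * xhat).mean(axis=(0, 2, 3), keepdims=True)
                dx = inv_std[None, :, None, None] * (term1 - term2 - term3)
            else:
                dx = gs * inv_std[None, :, None, None]
            x.accumulate(dx)

    return _make(y, (x, gamma, beta), backward)


def roi_align(x: Tensor, rois: np.ndarray, out_size: int = 7,
              spatial_scale: float = 1.0, samples: int = 2) -> Tensor:
    """RoI align.  ``rois`` is (R, 5): (batch_index, x0, y0, x1, y1) in image
    coordinates (0-based half-open); each output bin averages ``samples²``
    bilinear samples."""
    xd = x.data
    N, C, H, W = xd.shape
    rois = np.asarray(rois, dtype=np.float64)
    R = rois.shape[0]
    P = out_size
    if R == 0:
        out = np.zeros((0, C, P, P), dtype=xd.dtype)
        return _make(out, (x,), lambda g: None)
    bi = rois[:, 0].astype(np.int64)
    x0 = rois[:, 1] * spatial_scale
    y0 = rois[:, 2] * spatial_scale
    x1 = rois[:, 3] * spatial_scale
    y1 = rois[:, 4] * spatial_scale
    bw = np.maximum(x1 - x0, 1e-3)
    bh = np.maximum(y1 - y0, 1e-3)
    # sample grid: per bin, `samples` points at regular offsets
    grid = (np.arange(P * samples) + 0.5) / samples  # in bin units over P bins
    py = y0[:, None] + bh[:, None] * grid[None, :] / P      # (R, P*samples)
    px = x0[:, None] + bw[:, None] * grid[None, :] / P
    py = np.broadcast_to(py[:, :, None], (R, P * samples, P * samples))
    px = np.broadcast_to(px[:, None, :], (R, P * samples, P * samples))
    yy0 = np.floor(py).astype(np.int64)
    xx0 = np.floor(px).astype(np.int64)
    ty = py - yy0
    tx = px - xx0
    out_flat = np.zeros((R, P * samples, P * samples, C), dtype=xd.dtype)
    corner_info = []
    for dy_, dx_ in ((0, 0), (0, 1), (1, 0), (1, 1)):
        yy = yy0 + dy_
        xx = xx0 + dx_
        valid = (yy >= 0) & (yy < H) & (xx >= 0) & (xx < W)
        yc = np.clip(yy, 0, H - 1)
        xc = np.clip(xx, 0, W - 1)
        wy = (1.0 - ty) if dy_ == 0 else ty
        wx = (1.0 - tx) if dx_ == 0 else tx
        wgt = wy * wx * valid
        bidx = np.broadcast_to(bi[:, None, None], yy.shape)
        out_flat += xd[bidx, :, yc, xc] * wgt[..., None]
        corner_info.append((bidx, yc, xc, wgt, valid))
    y = out_flat.reshape(R, P, samples, P, samples, C).mean(axis=(2, 4))
    y = np.moveaxis(y, 3, 1)  # (R, C, P, P)

    def backward(g):
        if not x.requires_grad:
            return
        gflat = np.moveaxis(g, 1, 3) / (samples * samples)          # (R,P,P,C)
        gfull = np.repeat(np.repeat(gflat, samples, axis=1), samples, axis=2)
        dx = np.zeros((N * H * W, C), dtype=xd.dtype)
        for bidx, yc, xc, wgt, valid in corner_info:
            contrib = gfull * wgt[..., None]
            flat = ((bidx * H + yc) * W + xc)[valid]
            np.add.at(dx, flat, contrib[valid])
        x.accumulate(np.moveaxis(dx.reshape(N, H, W, C), 3, 1))

    return _make(y, (x,), backward)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def softmax_cross_entropy(logits: Tensor, labels: np.ndarray, ignore_index: int = -1) -> Tensor:
    """Mean cross-entropy over rows whose label != ignore_index."""
    z = logits.data
    labels = np.asarray(labels)
    valid = labels != ignore_index
    nv = max(int(valid.sum()), 1)
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    p = ez / ez.sum(axis=1, keepdims=True)
    idx = np.where(valid)[0]
    ll = -np.log(np.maximum(p[idx, labels[idx]], 1e-12))
    out = np.asarray(ll.sum() / nv)

    def backward(g):
        if logits.requires_grad:
            dz = np.zeros_like(z)
            dz[idx] = p[idx]
            dz[idx, labels[idx]] -= 1.0
            logits.accumulate(dz * (g / nv))

    return _make(out, (logits,), backward)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Plain (non-differentiable) softmax on a numpy array."""
    zmax = z.max(axis=axis, keepdims=True)
    ez = np.exp(z - zmax)
    return ez / ez.sum(axis=axis, keepdims=True)


def sigmoid_bce(logits: Tensor, targets: np.ndarray, weights: np.ndarray) -> Tensor:
    """Weighted binary cross-entropy with logits; normalised by the number of
    positively weighted entries."""
    z = logits.data
    t = np.asarray(targets, dtype=z.dtype)
    wgt = np.asarray(weights, dtype=z.dtype)
    norm = max(float((wgt > 0).sum()), 1.0)
    # softplus(z) - t*z, numerically stable
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    out = np.asarray((loss * wgt).sum() / norm)

    def backward(g):
        if logits.requires_grad:
            sig = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
            logits.accumulate((sig - t) * wgt * (g / norm))

    return _make(out, (logits,), backward)


def smooth_l1(pred: Tensor, target: np.ndarray, weights: np.ndarray,
              beta: float = 1.0, normalizer: float | None = None) -> Tensor:
    """Huber loss; ``weights`` broadcasts against pred rows, sum normalised by
    ``normalizer`` (defaults to the number of positively weighted rows)."""
    d = pred.data - np.asarray(target, dtype=pred.data.dtype)
    wgt = np.asarray(weights, dtype=pred.data.dtype)
    if wgt.ndim == 1:
        wgt = wgt[:, None]
    if normalizer is None:
        normalizer = max(float((wgt.max(axis=tuple(range(1, wgt.ndim))) > 0).sum()), 1.0)
    ad = np.abs(d)
    h = np.where(ad < beta, 0.5 * d * d / beta, ad - 0.5 * beta)
    out = np.asarray((h * wgt).sum() / normalizer)

    def backward(g):
        if pred.requires_grad:
            dd = np.clip(d / beta, -1.0, 1.0)
            pred.accumulate(dd * wgt * (g / normalizer))

    return _make(out, (pred,), backward)


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

class SGD:
    """Stochastic gradient descent with momentum and weight decay."""

    def __init__(self, params: Iterable[Parameter], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def clip_grad_norm(self, max_norm: float) -> float:
        total = 0.0
        for p in self.params:
            if p.grad is not None:
                total += float((p.grad ** 2).sum())
        norm = float(np.sqrt(total))
        if norm > max_norm > 0:
            scale = max_norm / (norm + 1e-12)
            for p in self.params:
                if p.grad is not None:
                    p.grad = p.grad * scale
        return norm

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype, copy=False)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v
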