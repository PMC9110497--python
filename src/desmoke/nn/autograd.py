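"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine supports exactly the operations the translation networks and
their training objectives need: convolution (via im2col/GEMM), reflection
padding, nearest-neighbour upsampling, instance normalisation, pointwise
nonlinearities, channel/patch minima (for the dark-channel term), per-sample
trimmed means, and elementwise arithmetic with reductions.

All tensors are float32.  Gradients are accumulated on ``Tensor.grad`` by
``Tensor.backward()``, which walks the recorded graph in reverse topological
order.  Only tensors with ``requires_grad`` (parameters, or anything computed
from them) participate in the graph; pure-data subgraphs are pruned at
construction so inference allocates no tape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add", "sub", "mul", "neg", "abs_", "square", "affine",
    "relu", "leaky_relu", "tanh",
    "mean", "reflect_pad2d", "upsample_nearest2", "instance_norm",
    "conv2d", "channel_slice", "channel_min", "min_pool2d",
    "trimmed_mean_per_sample",
]

_F32 = np.float32


class Tensor:
    """An ndarray plus an optional gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_edges")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_F32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        # list of (parent Tensor, fn upstream-grad -> parent-grad)
        self._edges: list = []

    # -- conveniences -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- backward pass ------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._edges:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node.grad is None:
                continue
            for parent, fn in node._edges:
                g = fn(node.grad)
                if parent.grad is None:
                    parent.grad = g.astype(_F32, copy=False)
                else:
                    parent.grad = parent.grad + g


def _result(data, edges) -> Tensor:
    """Build an op result, pruning the tape when no input needs gradients."""
    live = [(p, fn) for p, fn in edges if p.requires_grad]
    out = Tensor(data, requires_grad=bool(live))
    out._edges = live
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


# ---------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data
    return _result(data, [
        (a, lambda g: _unbroadcast(g, a.data.shape)),
        (b, lambda g: _unbroadcast(g, b.data.shape)),
    ])


def sub(a: Tensor, b: Tensor) -> Tensor:
    data = a.data - b.data
    return _result(data, [
        (a, lambda g: _unbroadcast(g, a.data.shape)),
        (b, lambda g: _unbroadcast(-g, b.data.shape)),
    ])


def mul(a: Tensor, b) -> Tensor:
    """Elementwise product; ``b`` may be a Tensor or a python scalar."""
    if isinstance(b, Tensor):
        data = a.data * b.data
        return _result(data, [
            (a, lambda g: _unbroadcast(g * b.data, a.data.shape)),
            (b, lambda g: _unbroadcast(g * a.data, b.data.shape)),
        ])
    s = _F32(b)
    return _result(a.data * s, [(a, lambda g: g * s)])


def neg(a: Tensor) -> Tensor:
    return _result(-a.data, [(a, lambda g: -g)])


def affine(a: Tensor, scale: float, shift: float) -> Tensor:
    """scale * a + shift with scalar constants."""
    s = _F32(scale)
    return _result(a.data * s + _F32(shift), [(a, lambda g: g * s)])


def abs_(a: Tensor) -> Tensor:
    sign = np.sign(a.data)
    return _result(np.abs(a.data), [(a, lambda g: g * sign)])


def square(a: Tensor) -> Tensor:
    return _result(a.data * a.data, [(a, lambda g: g * (2.0 * a.data))])


# ---------------------------------------------------------------------
# nonlinearities
# ---------------------------------------------------------------------

def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    return _result(a.data * mask, [(a, lambda g: g * mask)])


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    factor = np.where(a.data > 0, _F32(1.0), _F32(slope))
    return _result(a.data * factor, [(a, lambda g: g * factor)])


def tanh(a: Tensor) -> Tensor:
    out = np.tanh(a.data)
    return _result(out, [(a, lambda g: g * (1.0 - out * out))])


# ---------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------

def mean(a: Tensor, axis=None) -> Tensor:
    data = a.data.mean(axis=axis)
    shape = a.data.shape
    if axis is None:
        count = a.data.size

        def bwd(g):
            return np.broadcast_to(g / count, shape).astype(_F32)
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        count = int(np.prod([shape[ax] for ax in axes]))

        def bwd(g):
            g_exp = np.expand_dims(g, axes)
            return np.broadcast_to(g_exp / count, shape).astype(_F32)

    return _result(data, [(a, bwd)])


# ---------------------------------------------------------------------
# spatial ops (NCHW layout)
# ---------------------------------------------------------------------

def _reflect_indices(n: int, pad: int) -> np.ndarray:
    idx = np.arange(-pad, n + pad)
    # reflect without repeating the border sample (numpy 'reflect' mode)
    idx = np.abs(idx)
    idx = np.where(idx >= n, 2 * (n - 1) - idx, idx)
    return idx


def reflect_pad2d(a: Tensor, pad: int) -> Tensor:
    if pad == 0:
        return a
    N, C, H, W = a.data.shape
    ih = _reflect_indices(H, pad)
    iw = _reflect_indices(W, pad)
    data = a.data[:, :, ih[:, None], iw[None, :]]

    def bwd(g):
        dx = np.zeros((N, C, H, W), dtype=_F32)
        np.add.at(dx, (slice(None), slice(None), ih[:, None], iw[None, :]), g)
        return dx

    return _result(data, [(a, bwd)])


def upsample_nearest2(a: Tensor) -> Tensor:
    N, C, H, W = a.data.shape
    data = a.data.repeat(2, axis=2).repeat(2, axis=3)

    def bwd(g):
        return g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)).astype(_F32)

    return _result(data, [(a, bwd)])


def instance_norm(a: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel standardisation over the spatial axes."""
    x = a.data
    mu = x.mean(axis=(2, 3), keepdims=True)
    var = x.var(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = (x - mu) * inv
    hw = x.shape[2] * x.shape[3]

    def bwd(g):
        g_mean = g.mean(axis=(2, 3), keepdims=True)
        gy_mean = (g * y).mean(axis=(2, 3), keepdims=True)
        return (inv * (g - g_mean - y * gy_mean)).astype(_F32)

    _ = hw
    return _result(y.astype(_F32), [(a, bwd)])


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           pad: int = 0) -> Tensor:
    """2-D cross-correlation with zero padding, via im2col + GEMM."""
    N, C, H, W = x.data.shape
    Co, Ci, k, _ = w.data.shape
    if Ci != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Ci}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho = (Hp - k) // stride + 1
    Wo = (Wp - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]                 # (N,C,Ho,Wo,k,k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, C * k * k)
    wmat = w.data.reshape(Co, C * k * k)
    out = cols @ wmat.T                                  # (N*Ho*Wo, Co)
    if b is not None:
        out = out + b.data[None, :]
    data = out.reshape(N, Ho, Wo, Co).transpose(0, 3, 1, 2)

    def bwd_x(g):
        gcols = g.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, Co) @ wmat
        gcols = gcols.reshape(N, Ho, Wo, C, k, k)
        dxp = np.zeros((N, C, Hp, Wp), dtype=_F32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + Ho * stride:stride, j:j + Wo * stride:stride] += \
                    gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if pad:
            dxp = dxp[:, :, pad:-pad, pad:-pad]
        return dxp

    def bwd_w(g):
        gflat = g.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, Co)
        return (gflat.T @ cols).reshape(Co, C, k, k).astype(_F32)

    edges = [(x, bwd_x), (w, bwd_w)]
    if b is not None:
        edges.append((b, lambda g: g.sum(axis=(0, 2, 3)).astype(_F32)))
    return _result(data.astype(_F32), edges)


# ---------------------------------------------------------------------
# minima (dark-channel machinery)
# ---------------------------------------------------------------------

def channel_slice(a: Tensor, c: int) -> Tensor:
    """Select one channel, keeping the axis: (N,C,H,W) -> (N,1,H,W)."""
    data = a.data[:, c:c + 1]
    idx = c

    def bwd(g):
        dx = np.zeros_like(a.data)
        dx[:, idx:idx + 1] = g
        return dx

    return _result(data, [(a, bwd)])


def channel_min(a: Tensor) -> Tensor:
    """Pixelwise minimum over channels: (N,C,H,W) -> (N,1,H,W)."""
    arg = a.data.argmin(axis=1, keepdims=True)
    data = np.take_along_axis(a.data, arg, axis=1)

    def bwd(g):
        dx = np.zeros_like(a.data)
        np.put_along_axis(dx, arg, g, axis=1)
        return dx

    return _result(data, [(a, bwd)])


def min_pool2d(a: Tensor, k: int) -> Tensor:
    """Sliding-window minimum, window k x k clamped at the image border.

    Equivalent to an erosion with edge-replicated padding; output keeps the
    input's spatial shape.  Gradient routes to each window's argmin pixel.
    """
    if k < 1 or k % 2 == 0:
        raise ValueError("min filter window must be odd and positive")
    N, C, H, W = a.data.shape
    p = k // 2
    xp = np.pad(a.data, ((0, 0), (0, 0), (p, p), (p, p)), mode="edge")
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    flat = win.reshape(N, C, H, W, k * k)
    arg = flat.argmin(axis=-1)
    data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    # argmin offsets relative to window origin, mapped back to (clamped)
    # source coordinates in the unpadded image
    di, dj = np.divmod(arg, k)
    ii = np.clip(np.arange(H)[None, None, :, None] + di - p, 0, H - 1)
    jj = np.clip(np.arange(W)[None, None, None, :] + dj - p, 0, W - 1)
    nn = np.arange(N)[:, None, None, None]
    cc = np.arange(C)[None, :, None, None]

    def bwd(g):
        dx = np.zeros_like(a.data)
        np.add.at(dx, (np.broadcast_to(nn, g.shape), np.broadcast_to(cc, g.shape), ii, jj), g)
        return dx

    return _result(data.astype(_F32), [(a, bwd)])


def trimmed_mean_per_sample(a: Tensor, trim_frac: float) -> Tensor:
    """Per-sample trimmed mean over all non-batch elements: (N,...) -> (N,).

    Discards the lowest and highest ``floor(trim_frac * m)`` values by rank
    for each sample; gradient spreads uniformly over the kept entries.
    """
    if not 0.0 <= trim_frac < 0.5:
        raise ValueError("trim_frac must lie in [0, 0.5)")
    N = a.data.shape[0]
    flat = a.data.reshape(N, -1)
    m = flat.shape[1]
    cut = int(m * trim_frac)
    order = np.argsort(flat, axis=1)
    kept = order[:, cut:m - cut]
    nkept = kept.shape[1]
    data = np.take_along_axis(flat, kept, axis=1).mean(axis=1)

    def bwd(g):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, kept, (g[:, None] / nkept).astype(_F32), axis=1)
        return dflat.reshape(a.data.shape)

    return _result(data, [(a, bwd)])
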