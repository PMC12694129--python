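"""Differentiable operations built on the Tensor tape.

Convolutions use an explicit im2col/col2im realization; the backward pass of
col2im is a short loop over the k*k kernel offsets, which keeps everything
vectorized without `np.add.at` on large arrays.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

from .tensor import Tensor, as_tensor

__all__ = [
    "exp", "log", "sqrt", "abs_", "relu", "silu", "sigmoid", "tanh",
    "softplus", "softmax", "clamp", "concatenate", "pad2d", "conv2d",
    "depthwise_persample_conv2d", "upsample_nearest2d", "upsample_bilinear2d",
    "log_softmax",
]


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = np.exp(x.data)

    def bwd(g):
        if x.requires_grad:
            x._accum(g * out_data)

    return Tensor._make(out_data, (x,), bwd)


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = np.log(x.data)

    def bwd(g):
        if x.requires_grad:
            x._accum(g / x.data)

    return Tensor._make(out_data, (x,), bwd)


def sqrt(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = np.sqrt(x.data)

    def bwd(g):
        if x.requires_grad:
            x._accum(g * 0.5 / np.maximum(out_data, 1e-12))

    return Tensor._make(out_data, (x,), bwd)


def abs_(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = np.abs(x.data)
    sign = np.sign(x.data)

    def bwd(g):
        if x.requires_grad:
            x._accum(g * sign)

    return Tensor._make(out_data, (x,), bwd)


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    out_data = x.data * mask

    def bwd(g):
        if x.requires_grad:
            x._accum(g * mask)

    return Tensor._make(out_data, (x,), bwd)


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = expit(x.data)

    def bwd(g):
        if x.requires_grad:
            x._accum(g * out_data * (1.0 - out_data))

    return Tensor._make(out_data, (x,), bwd)


def tanh(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = np.tanh(x.data)

    def bwd(g):
        if x.requires_grad:
            x._accum(g * (1.0 - out_data**2))

    return Tensor._make(out_data, (x,), bwd)


def silu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    s = expit(x.data)
    out_data = x.data * s

    def bwd(g):
        if x.requires_grad:
            x._accum(g * (s + x.data * s * (1.0 - s)))

    return Tensor._make(out_data, (x,), bwd)


def softplus(x: Tensor) -> Tensor:
    x = as_tensor(x)
    # numerically stable: log(1+exp(x)) = max(x,0) + log1p(exp(-|x|))
    out_data = np.maximum(x.data, 0) + np.log1p(np.exp(-np.abs(x.data)))
    s = expit(x.data)

    def bwd(g):
        if x.requires_grad:
            x._accum(g * s)

    return Tensor._make(out_data, (x,), bwd)


def clamp(x: Tensor, lo: float, hi: float) -> Tensor:
    """Hard clip; gradient is passed only inside the open interval."""
    x = as_tensor(x)
    out_data = np.clip(x.data, lo, hi)
    mask = (x.data > lo) & (x.data < hi)

    def bwd(g):
        if x.requires_grad:
            x._accum(g * mask)

    return Tensor._make(out_data, (x,), bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        if x.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            x._accum(out_data * (g - dot))

    return Tensor._make(out_data, (x,), bwd)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - lse
    soft = np.exp(out_data)

    def bwd(g):
        if x.requires_grad:
            x._accum(g - soft * g.sum(axis=axis, keepdims=True))

    return Tensor._make(out_data, (x,), bwd)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 mean: np.ndarray, var: np.ndarray, eps: float) -> Tensor:
    """Channel normalization of (B, C, H, W) with the given statistics
    (batch statistics during training, running statistics at eval).
    Fused forward/backward; gradients flow to x, gamma and beta.  The
    backward treats `mean`/`var` as functions of x (training semantics)."""
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    B, C, H, W = x.data.shape
    n = B * H * W
    mu = mean.reshape(1, C, 1, 1)
    inv_std = (1.0 / np.sqrt(var + eps)).reshape(1, C, 1, 1).astype(np.float32)
    xhat = (x.data - mu) * inv_std
    g = gamma.data.reshape(1, C, 1, 1)
    out_data = xhat * g + beta.data.reshape(1, C, 1, 1)

    def bwd(grad):
        if beta.requires_grad:
            beta._accum(grad.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma._accum((grad * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxhat = grad * g
            s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
            s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            x._accum(inv_std * (dxhat - (s1 + xhat * s2) / n))

    return Tensor._make(out_data, (x, gamma, beta), bwd)


def batch_norm2d_eval(x: Tensor, gamma: Tensor, beta: Tensor,
                      mean: np.ndarray, var: np.ndarray, eps: float) -> Tensor:
    """Normalization with fixed (running) statistics: affine in x."""
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    C = x.data.shape[1]
    inv_std = (1.0 / np.sqrt(var + eps)).reshape(1, C, 1, 1).astype(np.float32)
    g = gamma.data.reshape(1, C, 1, 1)
    scale = (g * inv_std).astype(np.float32)
    xhat = (x.data - mean.reshape(1, C, 1, 1)) * inv_std
    out_data = x.data * scale + (beta.data.reshape(1, C, 1, 1)
                                 - mean.reshape(1, C, 1, 1) * scale)

    def bwd(grad):
        if beta.requires_grad:
            beta._accum(grad.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma._accum((grad * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x._accum(grad * scale)

    return Tensor._make(out_data, (x, gamma, beta), bwd)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), bwd)


def pad2d(x: Tensor, ph: int, pw: int) -> Tensor:
    """Zero-pad the two trailing spatial axes of a (B, C, H, W) tensor."""
    x = as_tensor(x)
    if ph == 0 and pw == 0:
        return x
    out_data = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))

    def bwd(g):
        if x.requires_grad:
            h, w = x.data.shape[2], x.data.shape[3]
            x._accum(g[:, :, ph:ph + h, pw:pw + w])

    return Tensor._make(out_data, (x,), bwd)


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int):
    # xp: (B, C, Hp, Wp) -> windows (B, C, OH, OW, kh, kw), then cols
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    b, c, oh, ow = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * oh * ow, c * kh * kw)
    return np.ascontiguousarray(cols), oh, ow


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding=0) -> Tensor:
    """2-D cross-correlation. x (B,Cin,H,W), w (Cout,Cin,kh,kw)."""
    x, w = as_tensor(x), as_tensor(w)
    ph, pw = (padding, padding) if np.isscalar(padding) else padding
    cout, cin, kh, kw = w.data.shape
    B = x.data.shape[0]
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
    cols, oh, ow = _im2col(xp, kh, kw, stride)
    wmat = w.data.reshape(cout, -1)
    out = cols @ wmat.T  # (B*OH*OW, Cout)
    if b is not None:
        out = out + b.data
    out_data = out.reshape(B, oh, ow, cout).transpose(0, 3, 1, 2)
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(-1, cout)  # (B*OH*OW, Cout)
        if b is not None and b.requires_grad:
            b._accum(gmat.sum(axis=0))
        if w.requires_grad:
            w._accum((gmat.T @ cols).reshape(w.data.shape))
        if x.requires_grad:
            dcols = gmat @ wmat  # (B*OH*OW, Cin*kh*kw)
            dcols = dcols.reshape(B, oh, ow, cin, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + stride * oh:stride,
                        j:j + stride * ow:stride] += np.moveaxis(
                            dcols[:, :, :, :, i, j], 3, 1)
            if ph or pw:
                h, wd = x.data.shape[2], x.data.shape[3]
                dxp = dxp[:, :, ph:ph + h, pw:pw + wd]
            x._accum(dxp)

    return Tensor._make(out_data, parents, bwd)


def depthwise_persample_conv2d(x: Tensor, kernels: Tensor,
                               stride: int = 1, padding: int = 0) -> Tensor:
    """Apply one 2-D kernel per batch sample across all channels.

    x: (B, C, H, W); kernels: (B, kh, kw).  Used by the dynamic
    Fourier-synthesized downsampling, where each sample gets its own kernel.
    """
    x, kernels = as_tensor(x), as_tensor(kernels)
    B, C, H, W = x.data.shape
    kh, kw = kernels.data.shape[1:]
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2)) if padding else x.data
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    oh, ow = win.shape[2], win.shape[3]
    out_data = np.einsum("bchwij,bij->bchw", win, kernels.data, optimize=True)

    def bwd(g):
        if kernels.requires_grad:
            kernels._accum(np.einsum("bchwij,bchw->bij", win, g, optimize=True))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += (
                        g * kernels.data[:, i, j][:, None, None, None])
            if padding:
                dxp = dxp[:, :, padding:padding + H, padding:padding + W]
            x._accum(dxp)

    return Tensor._make(out_data, (x, kernels), bwd)


def upsample_nearest2d(x: Tensor, scale: int = 2) -> Tensor:
    x = as_tensor(x)
    out_data = x.data.repeat(scale, axis=2).repeat(scale, axis=3)

    def bwd(g):
        if x.requires_grad:
            b, c, h, w = x.data.shape
            gr = g.reshape(b, c, h, scale, w, scale).sum(axis=(3, 5))
            x._accum(gr)

    return Tensor._make(out_data, (x,), bwd)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic 1-D bilinear interpolation matrix (align_corners=False)."""
    m = np.zeros((n_out, n_in), dtype=np.float32)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    scale = n_in / n_out
    for o in range(n_out):
        src = (o + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        i0 = int(np.floor(src))
        i1 = min(i0 + 1, n_in - 1)
        t = src - i0
        m[o, i0] += 1.0 - t
        m[o, i1] += t
    return m


def upsample_bilinear2d(x: Tensor, out_h: int, out_w: int) -> Tensor:
    x = as_tensor(x)
    b, c, h, w = x.data.shape
    R = _interp_matrix(out_h, h)  # (out_h, h)
    Cm = _interp_matrix(out_w, w)  # (out_w, w)
    out_data = np.einsum("oh,bchw,pw->bcop", R, x.data, Cm, optimize=True)

    def bwd(g):
        if x.requires_grad:
            x._accum(np.einsum("oh,bcop,pw->bchw", R, g, Cm, optimize=True))

    return Tensor._make(out_data, (x,), bwd)
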