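"""Low-level convolution primitives (im2col based).

All arrays are NCHW float64/float32. These functions are the shared kernels
behind both ``Conv2d`` (forward = correlation) and ``ConvTranspose2d``
(forward = the adjoint of a strided correlation), so each op's gradient is
the other's forward pass.
"""

from __future__ import annotations

import numpy as np


def conv_out_size(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


def _im2col(xp: np.ndarray, k: int, stride: int, ho: int, wo: int) -> np.ndarray:
    n, c, _, _ = xp.shape
    cols = np.empty((n, c, k, k, ho, wo), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return cols.reshape(n, c * k * k, ho * wo)


def _col2im(cols: np.ndarray, xshape: tuple, k: int, stride: int, pad: int, ho: int, wo: int) -> np.ndarray:
    n, c, h, w = xshape
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols = cols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[:, :, i, j]
    if pad == 0:
        return xp
    return xp[:, :, pad : pad + h, pad : pad + w]


def conv2d_forward(x, weight, bias, stride, pad):
    """x: (N,C,H,W); weight: (O,C,k,k) -> (N,O,Ho,Wo) plus the im2col cache."""
    n, c, h, w = x.shape
    o, _, k, _ = weight.shape
    ho, wo = conv_out_size(h, k, stride, pad), conv_out_size(w, k, stride, pad)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    cols = _im2col(xp, k, stride, ho, wo)  # (N, C*k*k, Ho*Wo)
    out = np.einsum("op,npq->noq", weight.reshape(o, -1), cols, optimize=True)
    out = out.reshape(n, o, ho, wo)
    if bias is not None:
        out += bias[None, :, None, None]
    return out, cols


def conv2d_backward(dout, x_shape, cols, weight, stride, pad):
    """Gradients of conv2d_forward w.r.t. input, weight and bias."""
    n, o, ho, wo = dout.shape
    k = weight.shape[2]
    dflat = dout.reshape(n, o, ho * wo)
    dw = np.einsum("noq,npq->op", dflat, cols, optimize=True).reshape(weight.shape)
    db = dout.sum(axis=(0, 2, 3))
    dcols = np.einsum("op,noq->npq", weight.reshape(o, -1), dflat, optimize=True)
    dx = _col2im(dcols, x_shape, k, stride, pad, ho, wo)
    return dx, dw, db


def conv_transpose2d_forward(x, weight, bias, stride, pad):
    """x: (N,Ci,H,W); weight: (Ci,Co,k,k) -> (N,Co,Ho,Wo), Ho = stride*(H-1)+k-2*pad.

    Implemented as the adjoint (col2im) of a strided correlation mapping the
    output back to the input shape.
    """
    n, ci, h, w = x.shape
    _, co, k, _ = weight.shape
    ho = stride * (h - 1) + k - 2 * pad
    wo = stride * (w - 1) + k - 2 * pad
    w2 = weight.reshape(ci, co * k * k)
    cols = np.einsum("cm,ncq->nmq", w2, x.reshape(n, ci, h * w), optimize=True)
    out = _col2im(cols, (n, co, ho, wo), k, stride, pad, h, w)
    if bias is not None:
        out += bias[None, :, None, None]
    return out, None


def conv_transpose2d_backward(dout, x, weight, stride, pad):
    n, ci, h, w = x.shape
    _, co, k, _ = weight.shape
    doutp = np.pad(dout, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else dout
    cols = _im2col(doutp, k, stride, h, w)  # (N, Co*k*k, H*W)
    w2 = weight.reshape(ci, co * k * k)
    dx = np.einsum("cm,nmq->ncq", w2, cols, optimize=True).reshape(x.shape)
    dw = np.einsum("ncq,nmq->cm", x.reshape(n, ci, h * w), cols, optimize=True).reshape(weight.shape)
    db = dout.sum(axis=(0, 2, 3))
    return dx, dw, db


def sigmoid(x):
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def logit(p, eps=1e-6):
    p = np.clip(p, eps, 1.0 - eps)
    return np.log(p) - np.log1p(-p)


def softmax(x, axis=-1):
    x = x - x.max(axis=axis, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=axis, keepdims=True)
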