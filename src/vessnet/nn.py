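"""Low-level tensor operations: convolution, batch norm, ReLU, pooling.

All operations work on float32 arrays in (N, C, H, W) layout and come in
forward/backward pairs so the network can be trained by explicit reverse-mode
differentiation.  Convolution is implemented as im2col + matrix multiply;
max pooling is 2x2 stride 2 with floor division of odd sizes and stores the
argmax index of every window so the paired max-unpooling restores the exact
pre-pool shape (odd trailing rows/columns come back as zeros, matching their
zero gradient).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "PoolRecord",
    "conv2d_forward",
    "conv2d_backward",
    "batchnorm_forward",
    "batchnorm_backward",
    "relu_forward",
    "relu_backward",
    "maxpool_forward",
    "maxpool_backward",
    "maxunpool_forward",
    "maxunpool_backward",
    "softmax",
]


@dataclass
class PoolRecord:
    """Argmax locations and pre-pool shape of one 2x2 max-pooling stage."""

    indices: np.ndarray  # (N, C, Ho, Wo) in {0,1,2,3}: window-local argmax
    pre_pool_shape: tuple[int, int, int, int]


# --- convolution ---------------------------------------------------------

def conv2d_forward(x, W, b):
    """Stride-1 convolution with 'same' zero padding for 3x3, none for 1x1.

    W has shape (Cout, Cin, kh, kw); output spatial dims equal the input's.
    """
    n, c, h, w = x.shape
    cout, cin, kh, kw = W.shape
    if cin != c:
        raise ValueError(f"channel mismatch: input {c}, kernel {cin}")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if ph or pw else x
    view = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (N,C,H,W,kh,kw)
    cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * kh * kw)
    wmat = W.reshape(cout, c * kh * kw)
    y = cols @ wmat.T + b
    y = y.reshape(n, h, w, cout).transpose(0, 3, 1, 2)
    cache = (cols, wmat, x.shape, (kh, kw))
    return np.ascontiguousarray(y), cache


def conv2d_backward(dy, cache):
    cols, wmat, xshape, (kh, kw) = cache
    n, c, h, w = xshape
    cout = wmat.shape[0]
    dyt = dy.transpose(0, 2, 3, 1).reshape(n * h * w, cout)
    dW = (dyt.T @ cols).reshape(cout, c, kh, kw)
    db = dyt.sum(axis=0)
    dcols = (dyt @ wmat).reshape(n, h, w, c, kh, kw)
    ph, pw = kh // 2, kw // 2
    dxp = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=dy.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(
                0, 3, 1, 2
            )
    dx = dxp[:, :, ph : ph + h, pw : pw + w] if ph or pw else dxp
    return np.ascontiguousarray(dx), dW, db


# --- batch normalization --------------------------------------------------

def batchnorm_forward(x, gamma, beta, eps=1e-5, training=True, running=None,
                      momentum=0.1):
    """Per-channel batch normalization with learned scale/shift.

    ``running`` is an optional dict with 'mean' and 'var' arrays; in training
    mode it is updated in place (exponential moving average), in inference
    mode it supplies the statistics.
    """
    if training:
        mu = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))
        if running is not None:
            running["mean"] += momentum * (mu - running["mean"])
            running["var"] += momentum * (var - running["var"])
    else:
        if running is None:
            raise ValueError("inference-mode BN requires running statistics")
        mu, var = running["mean"], running["var"]
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu[None, :, None, None]) * inv_std[None, :, None, None]
    y = gamma[None, :, None, None] * xhat + beta[None, :, None, None]
    cache = (xhat, gamma, inv_std, training)
    return y.astype(x.dtype, copy=False), cache


def batchnorm_backward(dy, cache):
    xhat, gamma, inv_std, training = cache
    m = dy.shape[0] * dy.shape[2] * dy.shape[3]
    dgamma = (dy * xhat).sum(axis=(0, 2, 3))
    dbeta = dy.sum(axis=(0, 2, 3))
    g = (gamma * inv_std)[None, :, None, None]
    if training:
        dx = g * (
            dy
            - dbeta[None, :, None, None] / m
            - xhat * dgamma[None, :, None, None] / m
        )
    else:  # statistics are constants in inference mode
        dx = g * dy
    return dx.astype(dy.dtype, copy=False), dgamma, dbeta


# --- ReLU -----------------------------------------------------------------

def relu_forward(x):
    mask = x > 0
    return x * mask, mask


def relu_backward(dy, mask):
    return dy * mask


# --- max pooling / unpooling ---------------------------------------------

def maxpool_forward(x):
    """2x2, stride 2, floor division; returns pooled map and a PoolRecord."""
    n, c, h, w = x.shape
    ho, wo = h // 2, w // 2
    if ho == 0 or wo == 0:
        raise ValueError(f"input {h}x{w} too small to pool")
    r = (
        x[:, :, : 2 * ho, : 2 * wo]
        .reshape(n, c, ho, 2, wo, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, ho, wo, 4)
    )
    idx = r.argmax(axis=-1)
    y = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    return np.ascontiguousarray(y), PoolRecord(idx, (n, c, h, w))


def _scatter(values, rec: PoolRecord):
    """Place (N,C,Ho,Wo) values at the recorded argmax positions."""
    n, c, h, w = rec.pre_pool_shape
    ho, wo = rec.indices.shape[2], rec.indices.shape[3]
    r = np.zeros((n, c, ho, wo, 4), dtype=values.dtype)
    np.put_along_axis(r, rec.indices[..., None], values[..., None], axis=-1)
    full = np.zeros((n, c, h, w), dtype=values.dtype)
    full[:, :, : 2 * ho, : 2 * wo] = (
        r.reshape(n, c, ho, wo, 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, 2 * ho, 2 * wo)
    )
    return full


def _gather(full, rec: PoolRecord):
    """Read (N,C,Ho,Wo) values from the recorded argmax positions."""
    n, c, h, w = rec.pre_pool_shape
    ho, wo = rec.indices.shape[2], rec.indices.shape[3]
    r = (
        full[:, :, : 2 * ho, : 2 * wo]
        .reshape(n, c, ho, 2, wo, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, ho, wo, 4)
    )
    return np.take_along_axis(r, rec.indices[..., None], axis=-1)[..., 0]


def maxpool_backward(dy, rec: PoolRecord):
    return _scatter(dy, rec)


def maxunpool_forward(x, rec: PoolRecord):
    """Index-preserving upsampling: restores exactly ``rec.pre_pool_shape``."""
    n, c, h, w = rec.pre_pool_shape
    if x.shape != rec.indices.shape:
        raise ValueError(
            f"unpool input {x.shape} does not match record {rec.indices.shape}"
        )
    return _scatter(x, rec)


def maxunpool_backward(dy, rec: PoolRecord):
    return np.ascontiguousarray(_gather(dy, rec))


# --- softmax --------------------------------------------------------------

def softmax(logits, axis=1):
    """Numerically stable softmax along the class axis."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
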