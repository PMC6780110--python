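"""Shared fixtures and a naive reference implementation.

The reference ops below compute convolution, batch norm, pooling and
unpooling by direct per-pixel loops / formula transcription, independent of
the vectorized im2col engine, so they can serve as an oracle on tiny
tensors.
"""

import numpy as np
import pytest

from vessnet import TensorShape, plan_vessnet
from vessnet.network import VessNet


# --- naive reference ops --------------------------------------------------

def naive_conv2d(x, W, b):
    """Direct per-pixel convolution, 'same' zero padding, stride 1."""
    n, c, h, w = x.shape
    cout, cin, kh, kw = W.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    y = np.zeros((n, cout, h, w), dtype=np.float64)
    for ni in range(n):
        for o in range(cout):
            for i in range(h):
                for j in range(w):
                    acc = b[o]
                    for ci in range(cin):
                        for u in range(kh):
                            for v in range(kw):
                                acc += W[o, ci, u, v] * xp[ni, ci, i + u, j + v]
                    y[ni, o, i, j] = acc
    return y


def naive_batchnorm(x, gamma, beta, eps=1e-5):
    mu = x.mean(axis=(0, 2, 3))
    var = x.var(axis=(0, 2, 3))
    out = np.empty_like(x, dtype=np.float64)
    for c in range(x.shape[1]):
        out[:, c] = gamma[c] * (x[:, c] - mu[c]) / np.sqrt(var[c] + eps) + beta[c]
    return out


def naive_maxpool(x):
    n, c, h, w = x.shape
    ho, wo = h // 2, w // 2
    y = np.zeros((n, c, ho, wo), dtype=x.dtype)
    idx = np.zeros((n, c, ho, wo), dtype=np.int64)
    for ni in range(n):
        for ci in range(c):
            for i in range(ho):
                for j in range(wo):
                    win = x[ni, ci, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2]
                    k = int(win.argmax())
                    idx[ni, ci, i, j] = k
                    y[ni, ci, i, j] = win.flat[k]
    return y, idx


def naive_unpool(y, idx, out_shape):
    n, c, h, w = out_shape
    out = np.zeros(out_shape, dtype=y.dtype)
    ho, wo = y.shape[2], y.shape[3]
    for ni in range(n):
        for ci in range(c):
            for i in range(ho):
                for j in range(wo):
                    k = idx[ni, ci, i, j]
                    out[ni, ci, 2 * i + k // 2, 2 * j + k % 2] = y[ni, ci, i, j]
    return out


def naive_vessnet_forward(net: VessNet, x):
    """Full forward pass composed from the naive ops (training-mode BN)."""

    def conv_bn(h, name):
        h = naive_conv2d(h, net.params[f"{name}/W"], net.params[f"{name}/b"])
        return naive_batchnorm(
            h, net.params[f"{name}/gamma"], net.params[f"{name}/beta"]
        )

    enc = [b for b in net.plan.blocks if b.role == "encoder"]
    dec = [b for b in net.plan.blocks if b.role == "decoder"]
    taps, recs = {}, {}
    h = x.astype(np.float64)
    for blk in enc:
        i = int(blk.block_id[-1])
        t = np.maximum(conv_bn(h, blk.layers[0].name), 0)
        taps[i] = t
        s = conv_bn(t, blk.layers[1].name)
        if blk.irsp is not None:
            s = s + conv_bn(h, blk.irsp.name)
        elif blk.layers[1].relu_after:
            pass
        a = np.maximum(s, 0)
        h, idx = naive_maxpool(a)
        recs[i] = (idx, a.shape)
    for blk in dec:
        j = int(blk.block_id[-1])
        idx, shape = recs[j]
        d = naive_unpool(h, idx, shape)
        k = np.maximum(conv_bn(d, blk.layers[0].name), 0)
        t_enr = k + taps[j]
        s = conv_bn(t_enr, blk.layers[1].name)
        if blk.irsp is not None:
            s = s + conv_bn(d, blk.irsp.name)
        h = np.maximum(s, 0)
    e = np.exp(h - h.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


# --- fixtures -------------------------------------------------------------

@pytest.fixture(scope="session")
def tiny_plan():
    """Width-scaled plan on a 16x16 input, full 4+4-block topology."""
    return plan_vessnet(TensorShape(16, 16, 3), num_classes=2, base_channels=4)


@pytest.fixture(scope="session")
def tiny_net(tiny_plan):
    return VessNet(tiny_plan, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
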