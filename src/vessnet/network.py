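"""Executable Vess-Net: parameters, forward pass, and reverse-mode gradients.

The dataflow realized here, per block (channel width C in, C' out):

encoder block i (input Ei, post-pool):
    T(Ei)  = ReLU(BN(conv3x3(Ei)))            # tapped for the outer stream
    S(Ei)  = BN(conv3x3(T(Ei)))
    F(Ei)  = BN(conv1x1(Ei))                  # inner projection (blocks 2-4)
    Yi     = S(Ei) + F(Ei)                    # elementwise; block 1: Yi = S
    out    = pool(ReLU(Yi))                   # indices recorded

decoder block j (input Dj, post-unpool with encoder block j's indices):
    K(Dj)  = ReLU(BN(conv3x3(Dj)))
    T'(Dj) = K(Dj) + T(Ej)                    # outer identity stream
    S'(Dj) = BN(conv3x3(T'(Dj)))
    F(Dj)  = BN(conv1x1(Dj))                  # inner projection (blocks 4-2)
    Zj     = ReLU(S'(Dj) + F(Dj))
    block 1 instead ends ReLU(BN(conv3x3(T'(D1)))) with num_classes filters,
    followed by per-pixel softmax.

ReLU is applied after each residual add and before pool/unpool; since max
pooling and ReLU commute, this matches placing the pool before the
activation as well.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import nn
from .plan import (
    ConvLayerSpec,
    NetworkPlan,
    TensorShape,
    plan_vessnet,
)

__all__ = ["BlockTensors", "VessNet", "forward", "encoder_block_forward",
           "decoder_block_forward"]


@dataclass
class BlockTensors:
    """Named intermediate activations of one block's forward pass."""

    block_input: np.ndarray
    after_first_relu: np.ndarray          # T(Ei) or K(Dj)
    after_second_conv_bn: np.ndarray      # S(Ei) or S'(Dj)
    projection_branch: np.ndarray | None  # F(Ei) / F(Dj); None without IRSP
    orsp_enriched: np.ndarray | None      # T'(Dj), decoder only
    block_output: np.ndarray              # Yi (pre-ReLU) or Zj (pre-ReLU)


def _he_init(rng: np.random.Generator, spec: ConvLayerSpec) -> np.ndarray:
    kh, kw = spec.kernel
    fan_in = kh * kw * spec.in_channels
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, (spec.out_channels, spec.in_channels, kh, kw)).astype(
        np.float32
    )


class VessNet:
    """A Vess-Net instance: a plan plus its trainable parameters.

    Parameters are held in a flat dict keyed ``"<layer>/W"``, ``"<layer>/b"``,
    ``"<layer>/gamma"``, ``"<layer>/beta"``; BN running statistics live in a
    parallel dict and are not trainable.
    """

    def __init__(self, plan: NetworkPlan, seed: int = 0):
        self.plan = plan
        self.params: dict[str, np.ndarray] = {}
        self.running: dict[str, dict[str, np.ndarray]] = {}
        rng = np.random.default_rng(seed)
        for spec in plan.all_layers():
            self.params[f"{spec.name}/W"] = _he_init(rng, spec)
            self.params[f"{spec.name}/b"] = np.zeros(spec.out_channels, np.float32)
            self.params[f"{spec.name}/gamma"] = np.ones(spec.out_channels, np.float32)
            self.params[f"{spec.name}/beta"] = np.zeros(spec.out_channels, np.float32)
            self.running[spec.name] = {
                "mean": np.zeros(spec.out_channels, np.float64),
                "var": np.ones(spec.out_channels, np.float64),
            }

    # -- single layers ----------------------------------------------------

    def _conv_bn(self, x, name, training):
        y, ccache = nn.conv2d_forward(
            x, self.params[f"{name}/W"], self.params[f"{name}/b"]
        )
        y, bcache = nn.batchnorm_forward(
            y,
            self.params[f"{name}/gamma"],
            self.params[f"{name}/beta"],
            training=training,
            running=self.running[name],
        )
        return y, (name, ccache, bcache)

    def _conv_bn_backward(self, dy, cache, grads):
        name, ccache, bcache = cache
        dy, dgamma, dbeta = nn.batchnorm_backward(dy, bcache)
        dx, dW, db = nn.conv2d_backward(dy, ccache)
        grads[f"{name}/W"] = grads.get(f"{name}/W", 0) + dW
        grads[f"{name}/b"] = grads.get(f"{name}/b", 0) + db
        grads[f"{name}/gamma"] = grads.get(f"{name}/gamma", 0) + dgamma
        grads[f"{name}/beta"] = grads.get(f"{name}/beta", 0) + dbeta
        return dx

    # -- blocks -----------------------------------------------------------

    def encoder_block_forward(self, x, block, training=True):
        """Returns (pooled output, PoolRecord, outer-stream tap, tensors, cache)."""
        first, second = block.layers
        t, c1 = self._conv_bn(x, first.name, training)
        t, m1 = nn.relu_forward(t)
        s, c2 = self._conv_bn(t, second.name, training)
        if block.irsp is not None:
            f, cp = self._conv_bn(x, block.irsp.name, training)
            y = s + f
        else:
            f, cp = None, None
            y = s
        a, m2 = nn.relu_forward(y)
        out, rec = nn.maxpool_forward(a)
        tensors = BlockTensors(x, t, s, f, None, y)
        cache = (c1, m1, c2, cp, m2, rec, block)
        return out, rec, t, tensors, cache

    def _encoder_block_backward(self, d_out, d_tap, cache, grads):
        c1, m1, c2, cp, m2, rec, block = cache
        da = nn.maxpool_backward(d_out, rec)
        dy = nn.relu_backward(da, m2)
        dt = self._conv_bn_backward(dy, c2, grads)  # through second conv
        if d_tap is not None:
            dt = dt + d_tap  # outer-stream gradient from the decoder
        dt = nn.relu_backward(dt, m1)
        dx = self._conv_bn_backward(dt, c1, grads)
        if cp is not None:
            dx = dx + self._conv_bn_backward(dy, cp, grads)
        return dx

    def decoder_block_forward(self, x, rec, orsp_in, block, training=True):
        """x is pre-unpool; returns (block output, tensors, cache)."""
        if rec is None:
            raise ValueError(f"{block.block_id}: missing PoolRecord")
        d = nn.maxunpool_forward(x, rec)
        first, second = block.layers
        k, c1 = self._conv_bn(d, first.name, training)
        k, m1 = nn.relu_forward(k)
        if orsp_in.shape != k.shape:
            raise ValueError(
                f"{block.block_id}: outer-stream shape {orsp_in.shape} "
                f"does not match {k.shape}"
            )
        t_enr = k + orsp_in
        s, c2 = self._conv_bn(t_enr, second.name, training)
        if block.irsp is not None:
            f, cp = self._conv_bn(d, block.irsp.name, training)
            z = s + f
        else:
            f, cp = None, None
            z = s
        out, m2 = nn.relu_forward(z)
        tensors = BlockTensors(d, k, s, f, t_enr, z)
        cache = (rec, c1, m1, c2, cp, m2, block)
        return out, tensors, cache

    def _decoder_block_backward(self, d_out, cache, grads):
        rec, c1, m1, c2, cp, m2, block = cache
        dz = nn.relu_backward(d_out, m2)
        dt_enr = self._conv_bn_backward(dz, c2, grads)
        d_tap = dt_enr  # flows back along the identity path to the encoder
        dk = nn.relu_backward(dt_enr, m1)
        dd = self._conv_bn_backward(dk, c1, grads)
        if cp is not None:
            dd = dd + self._conv_bn_backward(dz, cp, grads)
        dx = nn.maxunpool_backward(dd, rec)
        return dx, d_tap

    # -- whole network ----------------------------------------------------

    def forward(self, x, training=False, capture=False):
        """Per-pixel class probabilities for a batch (N, 3, H, W) in [0, 1].

        Returns ``probs`` of shape (N, num_classes, H, W); with
        ``capture=True`` returns ``(probs, {block_id: BlockTensors})``.
        """
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != self.plan.input_shape.channels:
            raise ValueError(f"expected (N, 3, H, W) input, got {x.shape}")
        if x.shape[2:] != (self.plan.input_shape.height, self.plan.input_shape.width):
            raise ValueError(
                f"input spatial dims {x.shape[2:]} do not match plan "
                f"{(self.plan.input_shape.height, self.plan.input_shape.width)}"
            )
        probs, _, tensors = self._forward_full(x, training=training)
        return (probs, tensors) if capture else probs

    def _forward_full(self, x, training):
        enc = [b for b in self.plan.blocks if b.role == "encoder"]
        dec = [b for b in self.plan.blocks if b.role == "decoder"]
        taps, recs, ecaches = {}, {}, []
        tensors: dict[str, BlockTensors] = {}
        h = x
        for blk in enc:
            h, rec, tap, bt, cache = self.encoder_block_forward(h, blk, training)
            i = int(blk.block_id[-1])
            taps[i], recs[i] = tap, rec
            ecaches.append(cache)
            tensors[blk.block_id] = bt
        dcaches = []
        for blk in dec:
            j = int(blk.block_id[-1])
            h, bt, cache = self.decoder_block_forward(
                h, recs[j], taps[j], blk, training
            )
            dcaches.append(cache)
            tensors[blk.block_id] = bt
        probs = nn.softmax(h, axis=1)
        cache = (ecaches, dcaches, probs)
        return probs, cache, tensors

    def forward_backward(self, x, dlogit_fn):
        """One forward/backward pass in training mode.

        ``dlogit_fn(probs) -> (loss, dlogits)`` supplies the loss gradient
        with respect to the pre-softmax map.  Returns (loss, probs, grads).
        """
        if not np.issubdtype(np.asarray(x).dtype, np.floating):
            x = np.asarray(x, dtype=np.float32)
        x = np.ascontiguousarray(x)
        probs, (ecaches, dcaches, _), _ = self._forward_full(x, training=True)
        loss, dlogits = dlogit_fn(probs)
        grads: dict[str, np.ndarray] = {}
        d_taps: dict[int, np.ndarray] = {}
        d = dlogits
        for cache in reversed(dcaches):
            blk = cache[-1]
            d, d_tap = self._decoder_block_backward(d, cache, grads)
            d_taps[int(blk.block_id[-1])] = d_tap
        for cache in reversed(ecaches):
            blk = cache[-1]
            d = self._encoder_block_backward(
                d, d_taps.get(int(blk.block_id[-1])), cache, grads
            )
        return loss, probs, grads

    def predict(self, x, batch_size=4):
        """Binary vessel mask(s) by per-pixel argmax; ties -> background.

        Accepts (N, 3, H, W) or a single (3, H, W) image.
        """
        single = x.ndim == 3
        xb = x[None] if single else x
        masks = []
        for i in range(0, xb.shape[0], batch_size):
            p = self.forward(xb[i : i + batch_size], training=False)
            masks.append((p[:, 1] > p[:, 0]).astype(np.uint8))
        out = np.concatenate(masks, axis=0)
        return out[0] if single else out

    # -- serialization ----------------------------------------------------

    def save(self, path):
        meta = {
            "input_shape": [
                self.plan.input_shape.height,
                self.plan.input_shape.width,
                self.plan.input_shape.channels,
            ],
            "num_classes": self.plan.num_classes,
            "base_channels": self.plan.blocks[0].layers[0].out_channels,
        }
        arrays = dict(self.params)
        for name, stats in self.running.items():
            arrays[f"{name}/running_mean"] = stats["mean"]
            arrays[f"{name}/running_var"] = stats["var"]
        np.savez_compressed(path, __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path):
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        h, w, c = meta["input_shape"]
        plan = plan_vessnet(
            TensorShape(h, w, c),
            num_classes=meta["num_classes"],
            base_channels=meta["base_channels"],
        )
        net = cls(plan, seed=0)
        for key in net.params:
            net.params[key] = data[key]
        for name in net.running:
            net.running[name] = {
                "mean": data[f"{name}/running_mean"],
                "var": data[f"{name}/running_var"],
            }
        return net


def forward(plan_or_net, image, seed: int = 0):
    """Convenience single-image forward: (H, W, 3) in [0,1] -> (H, W, classes)."""
    net = plan_or_net if isinstance(plan_or_net, VessNet) else VessNet(plan_or_net, seed)
    x = np.ascontiguousarray(image, dtype=np.float32).transpose(2, 0, 1)[None]
    # untrained nets have no meaningful running stats; use batch statistics
    probs = net.forward(x, training=True)
    return probs[0].transpose(1, 2, 0)


def encoder_block_forward(net: VessNet, x, block, training=True):
    """Module-level wrapper returning (output, PoolRecord, tap, BlockTensors)."""
    out, rec, tap, tensors, _ = net.encoder_block_forward(x, block, training)
    return out, rec, tap, tensors


def decoder_block_forward(net: VessNet, x, rec, orsp_in, block, training=True):
    out, tensors, _ = net.decoder_block_forward(x, rec, orsp_in, block, training)
    return out, tensors
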