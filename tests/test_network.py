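"""Forward-pass semantics: residual-add identities, probability maps,
block behavior under degenerate weights, and full-network oracle
equivalence on tiny tensors."""

import numpy as np
import pytest

from vessnet import TensorShape, plan_vessnet
from vessnet.network import VessNet

from conftest import naive_vessnet_forward


@pytest.fixture(scope="module")
def net16():
    plan = plan_vessnet(TensorShape(16, 16, 3), base_channels=4)
    return VessNet(plan, seed=3)


@pytest.fixture(scope="module")
def x16():
    return np.random.default_rng(5).random((2, 3, 16, 16)).astype(np.float32)


class TestResidualIdentities:
    def test_inner_adds_hold_exactly(self, net16, x16):
        """Y = S + F and Z = S' + F elementwise on every captured block."""
        _, tensors = net16.forward(x16, training=True, capture=True)
        checked = 0
        for bid, bt in tensors.items():
            if bt.projection_branch is not None:
                np.testing.assert_array_equal(
                    bt.block_output,
                    bt.after_second_conv_bn + bt.projection_branch,
                    err_msg=bid,
                )
                checked += 1
        assert checked == 6  # blocks 2-4 on both sides

    def test_outer_adds_hold_exactly(self, net16, x16):
        """T'(Dj) = K(Dj) + T(Ej) elementwise in every decoder block."""
        _, tensors = net16.forward(x16, training=True, capture=True)
        for j in range(1, 5):
            dec = tensors[f"DCB-{j}"]
            enc = tensors[f"ECB-{j}"]
            np.testing.assert_array_equal(
                dec.orsp_enriched, dec.after_first_relu + enc.after_first_relu
            )

    def test_addends_shape_identical(self, net16, x16):
        _, tensors = net16.forward(x16, training=True, capture=True)
        for bt in tensors.values():
            if bt.projection_branch is not None:
                assert bt.projection_branch.shape == bt.after_second_conv_bn.shape


class TestBlockDegenerateCases:
    def test_zero_everything_gives_zero_tensors(self):
        plan = plan_vessnet(TensorShape(16, 16, 3), base_channels=4)
        net = VessNet(plan, seed=0)
        for k in net.params:
            if k.endswith(("/W", "/b", "/beta")):
                net.params[k] = np.zeros_like(net.params[k])
        blk = plan.blocks[0]
        x = np.zeros((1, 3, 16, 16), np.float32)
        out, rec, tap, bt, _ = net.encoder_block_forward(x, blk)
        for t in (out, tap, bt.after_second_conv_bn, bt.block_output):
            assert not t.any()

    def test_zeroed_projection_makes_output_equal_s(self, x16):
        """With the F branch silenced, the pre-ReLU block output is S(Ei)."""
        plan = plan_vessnet(TensorShape(16, 16, 3), base_channels=4)
        net = VessNet(plan, seed=1)
        blk = plan.blocks[1]  # ECB-2, has projection
        for suffix in ("W", "b", "gamma", "beta"):
            net.params[f"{blk.irsp.name}/{suffix}"] = np.zeros_like(
                net.params[f"{blk.irsp.name}/{suffix}"]
            )
        x = np.random.default_rng(0).random((1, 4, 8, 8)).astype(np.float32)
        _, _, _, bt, _ = net.encoder_block_forward(x, blk)
        np.testing.assert_array_equal(bt.block_output, bt.after_second_conv_bn)

    def test_zero_orsp_makes_enriched_equal_k(self, net16):
        """T'(Dj) = K(Dj) when the outer-stream input is zero."""
        plan = net16.plan
        blk = next(b for b in plan.blocks if b.block_id == "DCB-4")
        rng = np.random.default_rng(2)
        x = rng.random((1, 32, 2, 2)).astype(np.float32)
        from vessnet import nn

        pooled, rec = nn.maxpool_forward(rng.random((1, 32, 4, 4)).astype(np.float32))
        orsp = np.zeros((1, 32, 4, 4), np.float32)
        _, bt, _ = net16.decoder_block_forward(x, rec, orsp, blk)
        np.testing.assert_array_equal(bt.orsp_enriched, bt.after_first_relu)

    def test_missing_pool_record_raises(self, net16):
        blk = next(b for b in net16.plan.blocks if b.role == "decoder")
        with pytest.raises(ValueError):
            net16.decoder_block_forward(
                np.zeros((1, 32, 2, 2), np.float32), None,
                np.zeros((1, 32, 4, 4), np.float32), blk
            )


class TestForward:
    def test_probabilities_sum_to_one(self, net16, x16):
        probs = net16.forward(x16, training=True)
        assert probs.shape == (2, 2, 16, 16)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_output_shape_tracks_plan(self):
        plan = plan_vessnet(TensorShape(32, 32, 3), base_channels=4)
        net = VessNet(plan, seed=0)
        x = np.random.default_rng(0).random((1, 3, 32, 32), dtype=np.float32)
        assert net.forward(x, training=True).shape == (1, 2, 32, 32)

    def test_constant_image_gives_constant_encoder_interior(self, net16):
        """Translation equivariance: on a constant input, encoder activations
        are spatially constant away from the zero-padded borders.  (Decoder
        maps are only periodic: unpooling a constant map scatters each value
        to one corner of its 2x2 window, breaking pixelwise constancy.)"""
        x = np.full((1, 3, 16, 16), 0.5, np.float32)
        _, tensors = net16.forward(x, training=True, capture=True)
        tap = tensors["ECB-1"].after_first_relu  # one conv deep: 1-px border
        interior = tap[0, :, 2:14, 2:14]
        assert np.abs(interior - interior[:, :1, :1]).max() < 1e-5
        s = tensors["ECB-1"].after_second_conv_bn  # two convs: 2-px border
        interior2 = s[0, :, 3:13, 3:13]
        assert np.abs(interior2 - interior2[:, :1, :1]).max() < 1e-5

    def test_wrong_spatial_dims_rejected(self, net16):
        with pytest.raises(ValueError):
            net16.forward(np.zeros((1, 3, 8, 8), np.float32))


class TestOracleEquivalence:
    def test_full_forward_matches_naive_reference(self, net16, x16):
        """im2col engine vs direct per-pixel composition, <=16x16 tensors."""
        fast = net16.forward(x16, training=True)
        slow = naive_vessnet_forward(net16, x16)
        np.testing.assert_allclose(fast, slow, rtol=1e-5, atol=1e-6)


class TestSerialization:
    def test_save_load_roundtrip(self, net16, x16, tmp_path):
        path = tmp_path / "model.npz"
        net16.forward(x16, training=True)  # populate running stats
        net16.save(path)
        loaded = VessNet.load(path)
        np.testing.assert_array_equal(
            net16.forward(x16, training=False), loaded.forward(x16, training=False)
        )
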