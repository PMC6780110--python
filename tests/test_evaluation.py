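"""Confusion counts, Se/Sp/Acc identities, AUC vs Mann-Whitney oracle,
overlay losslessness, and dataset aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vessnet.evaluation import (
    ConfusionCounts,
    OverlayStyle,
    confusion,
    render_overlay,
    roc_auc,
    se_sp_acc,
)


def mann_whitney_auc(probs, labels):
    """Brute-force pairwise concordance: P(score_pos > score_neg) + ties/2."""
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_prediction(self, rng):
        gt = (rng.random((5, 5)) < 0.4).astype(np.uint8)
        c = confusion(gt, gt)
        assert c.fp == c.fn == 0
        assert c.tp == gt.sum() and c.total == 25

    def test_inverted_prediction(self, rng):
        gt = (rng.random((5, 5)) < 0.4).astype(np.uint8)
        c = confusion(1 - gt, gt)
        assert c.tp == c.tn == 0

    def test_3x3_toy_by_hand(self):
        gt = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 0]], np.uint8)
        pred = np.array([[1, 1, 0], [0, 0, 0], [0, 0, 0]], np.uint8)
        c = confusion(pred, gt)
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 6, 1)

    def test_eval_region_restricts_counts(self):
        gt = np.ones((2, 2), np.uint8)
        pred = np.zeros((2, 2), np.uint8)
        region = np.array([[1, 0], [0, 0]], np.uint8)
        c = confusion(pred, gt, region)
        assert c.total == 1 and c.fn == 1

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.array([[2]]), np.array([[1]]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((2, 2), np.uint8), np.zeros((3, 3), np.uint8))


class TestSeSpAcc:
    def test_all_half(self):
        assert se_sp_acc(ConfusionCounts(1, 1, 1, 1)) == (0.5, 0.5, 0.5)

    def test_perfect(self):
        assert se_sp_acc(ConfusionCounts(10, 0, 90, 0)) == (1.0, 1.0, 1.0)

    def test_reference_mask_arithmetic(self):
        """A 447x447 mask with 19,551 vessel pixels: 180,258 background,
        199,809 total; full agreement gives Acc = 1."""
        c = ConfusionCounts(tp=19551, fp=0, tn=180258, fn=0)
        assert c.total == 199_809 == 447 * 447
        assert se_sp_acc(c) == (1.0, 1.0, 1.0)

    def test_zero_denominator_is_nan(self):
        se, sp, acc = se_sp_acc(ConfusionCounts(0, 1, 1, 0))
        assert np.isnan(se) and sp == 0.5

    def test_label_swap_exchanges_se_sp(self, rng):
        gt = (rng.random((8, 8)) < 0.3).astype(np.uint8)
        pred = (rng.random((8, 8)) < 0.5).astype(np.uint8)
        se, sp, acc = se_sp_acc(confusion(pred, gt))
        se2, sp2, acc2 = se_sp_acc(confusion(1 - pred, 1 - gt))
        assert (se2, sp2) == (sp, se) and acc2 == acc

    def test_acc_between_se_and_sp(self, rng):
        gt = (rng.random((10, 10)) < 0.25).astype(np.uint8)
        pred = (rng.random((10, 10)) < 0.4).astype(np.uint8)
        se, sp, acc = se_sp_acc(confusion(pred, gt))
        assert min(se, sp) <= acc <= max(se, sp)


class TestRocAuc:
    def test_perfect_separation(self):
        gt = np.array([[0, 0, 1, 1]], np.uint8)
        probs = np.array([[0.1, 0.2, 0.8, 0.9]])
        assert roc_auc(probs, gt) == 1.0

    def test_constant_probabilities_give_half(self):
        gt = np.array([[0, 1, 0, 1]], np.uint8)
        probs = np.full((1, 4), 0.5)
        assert roc_auc(probs, gt) == 0.5

    def test_six_pixel_toy_matches_pair_counting(self):
        probs = np.array([[0.9, 0.3, 0.8, 0.2, 0.6, 0.4]])
        gt = np.array([[1, 1, 1, 0, 0, 0]], np.uint8)
        assert roc_auc(probs, gt) == pytest.approx(
            mann_whitney_auc(probs.ravel(), gt.ravel())
        )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=10),
        st.data(),
    )
    def test_matches_mann_whitney_on_random_toys(self, probs, data):
        labels = data.draw(
            st.lists(st.sampled_from([0, 1]), min_size=len(probs), max_size=len(probs))
        )
        probs, labels = np.array([probs]), np.array([labels], dtype=np.uint8)
        if labels.all() or not labels.any():
            with pytest.raises(ValueError):
                roc_auc(probs, labels)
        else:
            assert roc_auc(probs, labels) == pytest.approx(
                mann_whitney_auc(probs.ravel(), labels.ravel())
            )

    def test_single_class_undefined(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([[0.5, 0.6]]), np.array([[1, 1]], np.uint8))


class TestOverlay:
    def test_perfect_prediction_shows_only_tp_color(self, rng):
        gt = (rng.random((6, 6)) < 0.4).astype(np.uint8)
        img = rng.integers(0, 256, (6, 6, 3), dtype=np.uint8)
        out = render_overlay(img, gt, gt)
        style = OverlayStyle()
        assert (out[gt == 1] == style.tp_color).all()
        assert not (out == style.fp_color).all(axis=-1).any() or not gt.all()

    def test_all_background_prediction_shows_only_fn(self, rng):
        gt = (rng.random((6, 6)) < 0.4).astype(np.uint8)
        img = rng.integers(0, 256, (6, 6, 3), dtype=np.uint8)
        out = render_overlay(img, np.zeros_like(gt), gt)
        assert (out[gt == 1] == OverlayStyle().fn_color).all()

    def test_2x2_toy_exact_colors(self):
        img = np.full((2, 2, 3), 200, np.uint8)
        gt = np.array([[1, 1], [0, 0]], np.uint8)
        pred = np.array([[1, 0], [1, 0]], np.uint8)
        out = render_overlay(img, pred, gt)
        s = OverlayStyle()
        assert tuple(out[0, 0]) == s.tp_color
        assert tuple(out[0, 1]) == s.fn_color
        assert tuple(out[1, 0]) == s.fp_color
        assert tuple(out[1, 1]) == (200 // 2 + 32,) * 3  # dimmed tn

    def test_recounting_colors_reproduces_confusion(self, rng):
        gt = (rng.random((16, 16)) < 0.3).astype(np.uint8)
        pred = (rng.random((16, 16)) < 0.3).astype(np.uint8)
        img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        out = render_overlay(img, pred, gt)
        s = OverlayStyle()
        c = confusion(pred, gt)
        assert (out == s.tp_color).all(axis=-1).sum() == c.tp
        assert (out == s.fp_color).all(axis=-1).sum() == c.fp
        assert (out == s.fn_color).all(axis=-1).sum() == c.fn

    def test_identical_colors_rejected(self):
        with pytest.raises(ValueError):
            OverlayStyle(tp_color=(0, 0, 0), fp_color=(0, 0, 0), fn_color=(1, 1, 1))


@pytest.fixture(scope="module")
def trained_setup():
    from vessnet import TensorShape, plan_vessnet
    from vessnet.network import VessNet
    from vessnet.augment import SamplePair

    plan = plan_vessnet(TensorShape(16, 16, 3), base_channels=4)
    net = VessNet(plan, seed=0)
    net.forward(np.random.default_rng(0).random((2, 3, 16, 16), dtype=np.float32),
                training=True)  # seed running stats
    rng = np.random.default_rng(1)
    pairs = [
        SamplePair(
            rng.integers(0, 256, (16, 16, 3), dtype=np.uint8),
            (rng.random((16, 16)) < 0.2).astype(np.uint8),
        )
        for _ in range(3)
    ]
    return net, pairs


class TestEvaluateDataset:
    def test_row_count_is_images_plus_pooled(self, trained_setup):
        from vessnet.evaluation import evaluate_dataset

        net, pairs = trained_setup
        rows = evaluate_dataset(net, pairs)
        assert len(rows) == 4 and rows[-1]["image"] == "pooled"

    def test_duplicated_image_aggregate_equals_single(self, trained_setup):
        from vessnet.evaluation import evaluate_dataset

        net, pairs = trained_setup
        single = evaluate_dataset(net, pairs[:1], with_auc=False)
        double = evaluate_dataset(net, pairs[:1] * 2, with_auc=False)
        assert double[-1]["Acc"] == pytest.approx(single[-1]["Acc"])
        assert double[-1]["tp"] == 2 * single[-1]["tp"]

    def test_pooled_acc_is_count_weighted_mean(self, trained_setup):
        from vessnet.evaluation import evaluate_dataset

        net, pairs = trained_setup
        rows = evaluate_dataset(net, pairs, with_auc=False)
        per_img = rows[:-1]
        total = sum(r["tp"] + r["fp"] + r["tn"] + r["fn"] for r in per_img)
        weighted = sum(
            r["Acc"] * (r["tp"] + r["fp"] + r["tn"] + r["fn"]) for r in per_img
        )
        assert rows[-1]["Acc"] == pytest.approx(weighted / total)

    def test_empty_set_rejected(self, trained_setup):
        from vessnet.evaluation import evaluate_dataset

        net, _ = trained_setup
        with pytest.raises(ValueError):
            evaluate_dataset(net, [])
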