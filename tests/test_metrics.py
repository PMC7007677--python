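"""Loss and metric oracles: exhaustive small-grid enumeration against
hand-computed formulas, plus the Dice/F1 identity for binary masks."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rootseg import metrics
from rootseg.metrics import ConfusionCounts


def all_binary_2x2():
    for bits in itertools.product((0, 1), repeat=4):
        yield np.array(bits).reshape(2, 2)


def brute_dice_loss(p, g):
    """Independent hand evaluation: DL = 1 - 2*sum(p*g)/(sum(p)+sum(g))."""
    inter = sum(pi * gi for pi, gi in zip(p.flat, g.flat))
    denom = sum(p.flat) + sum(g.flat)
    return 0.0 if denom == 0 else 1.0 - 2.0 * inter / denom


class TestDiceLoss:
    def test_matches_brute_force_on_all_2x2_pairs(self):
        for p in all_binary_2x2():
            for g in all_binary_2x2():
                assert metrics.dice_loss(p, g) == pytest.approx(brute_dice_loss(p, g))

    def test_hand_examples(self):
        assert metrics.dice_loss(np.array([1, 1, 0, 0]), np.array([1, 0, 1, 0])) == pytest.approx(0.5)
        g = np.array([1, 1, 0, 0])
        assert metrics.dice_loss(g, g) == 0.0
        assert metrics.dice_loss(np.array([1, 0]), np.array([0, 1])) == 1.0
        assert metrics.dice_loss(np.zeros(4), np.zeros(4)) == 0.0

    def test_symmetric_and_bounded_for_binary_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = (rng.uniform(size=16) < 0.4).astype(float)
            g = (rng.uniform(size=16) < 0.4).astype(int)
            dl = metrics.dice_loss(p, g)
            assert 0.0 <= dl <= 1.0
            assert dl == pytest.approx(metrics.dice_loss(g.astype(float), p.astype(int)))

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20), st.data())
    def test_soft_predictions_bounded(self, probs, data):
        p = np.array(probs)
        g = np.array(data.draw(st.lists(st.integers(0, 1), min_size=len(probs), max_size=len(probs))))
        assert 0.0 <= metrics.dice_loss(p, g) <= 1.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            metrics.dice_loss(np.zeros(3), np.zeros(4))


class TestCrossEntropy:
    def test_confident_correct_is_near_zero(self):
        g = np.array([1, 0, 1])
        assert metrics.cross_entropy_loss(g.astype(float), g) < 1e-6

    def test_uniform_prediction_is_ln2(self):
        g = np.array([1, 0, 1, 0])
        assert metrics.cross_entropy_loss(np.full(4, 0.5), g) == pytest.approx(math.log(2))

    def test_finite_at_certainty_via_clipping(self):
        val = metrics.cross_entropy_loss(np.array([1.0, 0.0]), np.array([0, 1]))
        assert math.isfinite(val) and val > 10


class TestCombinedLoss:
    def test_equals_sum_of_components(self):
        p = np.array([0.9, 0.2, 0.7, 0.1])
        g = np.array([1, 0, 1, 0])
        expect = metrics.dice_loss(p, g) + 0.3 * metrics.cross_entropy_loss(p, g)
        assert metrics.combined_loss(p, g) == pytest.approx(expect)

    def test_zero_weight_reduces_to_dice(self):
        p = np.array([0.9, 0.2])
        g = np.array([1, 0])
        assert metrics.combined_loss(p, g, ce_weight=0.0) == metrics.dice_loss(p, g)

    def test_perfect_confident_prediction_near_zero(self):
        g = np.array([1, 0, 1])
        assert metrics.combined_loss(g.astype(float), g) < 1e-6

    def test_batch_loss_is_mean_of_items_and_grad_matches_numerics(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.05, 0.95, (3, 1, 4, 4))
        g = (rng.uniform(size=(3, 1, 4, 4)) < 0.3).astype(float)
        loss, grad = metrics.batch_loss_and_grad(p, g)
        per_item = [metrics.combined_loss(p[i, 0], g[i, 0].astype(int)) for i in range(3)]
        assert loss == pytest.approx(np.mean(per_item))
        # central-difference check of the analytic gradient at a few pixels
        for idx in [(0, 0, 1, 2), (2, 0, 3, 3)]:
            eps = 1e-6
            pp, pm = p.copy(), p.copy()
            pp[idx] += eps
            pm[idx] -= eps
            num = (metrics.batch_loss_and_grad(pp, g)[0] - metrics.batch_loss_and_grad(pm, g)[0]) / (2 * eps)
            assert grad[idx] == pytest.approx(num, rel=1e-4)


class TestConfusionAndReport:
    def test_hand_count(self):
        pred = np.array([[1, 1], [0, 0]])
        gt = np.array([[1, 0], [1, 0]])
        c = metrics.confusion_counts(pred, gt)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)
        assert c.total == 4

    def test_perfect_and_empty(self):
        gt = np.array([[1, 0], [0, 1]])
        c = metrics.confusion_counts(gt, gt)
        assert c.fp == 0 and c.fn == 0
        c0 = metrics.confusion_counts(np.zeros((2, 2), int), np.zeros((2, 2), int))
        assert c0.tp == 0 and c0.tn == 4

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            metrics.confusion_counts(np.array([2]), np.array([1]))

    def test_report_hand_example(self):
        rep = metrics.classification_metrics(ConfusionCounts(tp=1, fp=1, fn=1, tn=1))
        assert rep.precision == 0.5 and rep.recall == 0.5 and rep.f1 == pytest.approx(0.5)
        assert rep.accuracy == 0.5
        assert rep.prediction_mean == 0.5 and rep.true_mean == 0.5

    def test_undefined_ratios_flagged_as_nan(self):
        rep = metrics.classification_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=9))
        assert math.isnan(rep.precision) and math.isnan(rep.recall) and math.isnan(rep.f1)
        assert rep.accuracy == 1.0

    def test_f1_equals_one_minus_dice_loss_for_all_binary_pairs(self):
        for pred in all_binary_2x2():
            for gt in all_binary_2x2():
                rep = metrics.classification_metrics(metrics.confusion_counts(pred, gt))
                dl = metrics.dice_loss(pred.astype(float), gt)
                if pred.sum() == 0 and gt.sum() == 0:
                    assert math.isnan(rep.f1) and dl == 0.0
                else:
                    assert rep.f1 == pytest.approx(1.0 - dl)


class TestAggregation:
    def _pair(self, seed, empty_gt=False):
        rng = np.random.default_rng(seed)
        pred = (rng.uniform(size=(8, 8)) < 0.3).astype(np.uint8)
        gt = np.zeros((8, 8), np.uint8) if empty_gt else (rng.uniform(size=(8, 8)) < 0.3).astype(np.uint8)
        return pred, gt

    def test_single_image_pooled_equals_per_image(self):
        pair = self._pair(0)
        pooled, stats = metrics.aggregate_metrics([pair])
        assert stats.n_images == 1
        assert stats.f1_mean == pytest.approx(pooled.f1)
        assert stats.f1_sd == 0.0

    def test_root_free_images_excluded_from_per_image_only(self):
        pairs = [self._pair(1), self._pair(2, empty_gt=True)]
        pooled, stats = metrics.aggregate_metrics(pairs)
        assert stats.n_images == 1
        # pooled uses both images: its false positives include those on the
        # root-free image
        fp_total = sum(metrics.confusion_counts(p, g).fp for p, g in pairs)
        assert round(pooled.prediction_mean * 128) - round(pooled.true_mean * 128) >= 0
        assert pooled.accuracy <= 1.0
        assert fp_total > metrics.confusion_counts(*pairs[0]).fp

    def test_pooled_f1_differs_from_mean_per_image_f1_when_imbalanced(self):
        # image A: large and perfectly predicted; image B: tiny and all wrong
        a = (np.ones((10, 10), np.uint8), np.ones((10, 10), np.uint8))
        b = (np.zeros((2, 2), np.uint8), np.ones((2, 2), np.uint8))
        pooled, stats = metrics.aggregate_metrics([a, b])
        # hand values: pooled F1 = 2*100/(200+4); mean per-image = (1+0)/2
        assert pooled.f1 == pytest.approx(200 / 204)
        assert stats.f1_mean == pytest.approx(0.5)

    def test_all_root_free_flagged(self):
        pairs = [self._pair(3, empty_gt=True)]
        _, stats = metrics.aggregate_metrics(pairs)
        assert stats.n_images == 0 and math.isnan(stats.f1_mean)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            metrics.aggregate_metrics([])
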