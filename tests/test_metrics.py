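"""Loss and metric definitions against hand evaluations and brute-force oracles."""

import numpy as np
import pytest

from softgleason.metrics import (
    LossConfig,
    MetricConfig,
    ZeroSupportPolicy,
    confusion,
    hard_cross_entropy,
    hard_dice_loss,
    hard_dice_metrics,
    l1_metric,
    macro_soft_dice,
    soft_cross_entropy,
    soft_dice_loss,
)
from softgleason.ontology import IGNORE_LABEL


def brute_force_dice(pred_mask: np.ndarray, target_mask: np.ndarray) -> float:
    """Classical set-overlap Dice for binary masks."""
    inter = np.logical_and(pred_mask, target_mask).sum()
    total = pred_mask.sum() + target_mask.sum()
    return 2.0 * inter / total if total else 1.0


class TestSoftDiceLoss:
    def test_perfect_one_hot_prediction(self, rng):
        labels = rng.integers(0, 3, (8, 8))
        onehot = np.eye(3)[labels]
        mask = np.ones((8, 8), bool)
        assert soft_dice_loss(onehot, onehot, mask) == pytest.approx(0.0, abs=1e-5)

    def test_disjoint_support_loss_one(self):
        pred = np.zeros((2, 1, 2))
        pred[..., 0] = 1.0
        tgt = np.zeros((2, 1, 2))
        tgt[..., 1] = 1.0
        mask = np.ones((2, 1), bool)
        assert soft_dice_loss(pred, tgt, mask) == pytest.approx(1.0, abs=1e-5)

    def test_hand_example_half(self):
        """Single class, two pixels, p=(1,0), y=(0.5,0.5): d = 1/2 as ε→0."""
        pred = np.array([[[1.0]], [[0.0]]])
        tgt = np.array([[[0.5]], [[0.5]]])
        mask = np.ones((2, 1), bool)
        loss = soft_dice_loss(pred, tgt, mask, LossConfig(epsilon=1e-12))
        assert loss == pytest.approx(0.5, abs=1e-9)

    def test_gradient_matches_finite_differences(self, rng):
        pred = rng.dirichlet(np.ones(3), size=(4,))
        tgt = rng.dirichlet(np.ones(3), size=(4,))
        mask = np.ones(4, bool)
        loss, g = soft_dice_loss(pred, tgt, mask, grad=True)
        eps = 1e-7
        for i, c in [(0, 1), (2, 0), (3, 2)]:
            p2 = pred.copy()
            p2[i, c] += eps
            num = (soft_dice_loss(p2, tgt, mask) - loss) / eps
            assert num == pytest.approx(g[i, c], rel=1e-4, abs=1e-8)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            soft_dice_loss(np.ones((2, 2, 2)), np.ones((2, 2, 2)), np.zeros((2, 2), bool))


class TestSoftCrossEntropy:
    def test_one_hot_match_zero(self):
        onehot = np.eye(2)[np.array([[0, 1]])]
        assert soft_cross_entropy(onehot, onehot, np.ones((1, 2), bool)) == \
            pytest.approx(0.0, abs=1e-9)

    def test_uniform_uniform_ln2(self):
        p = np.full((1, 1, 2), 0.5)
        assert soft_cross_entropy(p, p, np.ones((1, 1), bool)) == \
            pytest.approx(np.log(2), abs=1e-12)

    def test_minimized_at_target(self, rng):
        y = rng.dirichlet(np.ones(4), size=(6,))
        mask = np.ones(6, bool)
        at_target = soft_cross_entropy(y, y, mask)
        for _ in range(10):
            other = rng.dirichlet(np.ones(4), size=(6,))
            assert soft_cross_entropy(other, y, mask) >= at_target - 1e-12


class TestHardLosses:
    def test_perfect_prediction_zero(self):
        labels = np.array([[0, 1], [1, 0]])
        pred = np.eye(2)[labels]
        mask = np.ones((2, 2), bool)
        assert hard_dice_loss(pred, labels, mask) == pytest.approx(0.0, abs=1e-5)
        assert hard_cross_entropy(pred, labels, mask) == pytest.approx(0.0, abs=1e-9)

    def test_all_ignored_rejected(self):
        labels = np.full((2, 2), IGNORE_LABEL)
        with pytest.raises(ValueError):
            hard_cross_entropy(np.ones((2, 2, 2)) / 2, labels, np.ones((2, 2), bool))

    def test_ignore_pixel_excluded_from_sums(self):
        """Four pixels with one ignore: CE averages over exactly 3 pixels."""
        labels = np.array([[0, 1], [0, IGNORE_LABEL]])
        pred = np.full((2, 2, 2), 0.5)
        ce = hard_cross_entropy(pred, labels, np.ones((2, 2), bool))
        assert ce == pytest.approx(np.log(2), abs=1e-12)  # mean over the 3 valid
        pred2 = pred.copy()
        pred2[1, 1] = [0.99, 0.01]  # touching the ignored pixel changes nothing
        assert hard_cross_entropy(pred2, labels, np.ones((2, 2), bool)) == \
            pytest.approx(ce, abs=1e-12)


class TestMacroSoftDice:
    def test_identity_scores_one_exactly(self, rng):
        p = rng.dirichlet(np.ones(4), size=(5, 5))
        mask = np.ones((5, 5), bool)
        assert macro_soft_dice(p, p.copy(), mask) == pytest.approx(1.0, abs=1e-12)

    def test_reduces_to_classical_dice_on_binary_masks(self, rng):
        """On one-hot inputs the L1 semimetric equals set-overlap Dice,
        verified against a brute-force oracle on 200 random mask pairs."""
        for _ in range(200):
            pm = rng.random((6, 6)) < rng.uniform(0.2, 0.8)
            tm = rng.random((6, 6)) < rng.uniform(0.2, 0.8)
            pred = np.stack([pm, ~pm], axis=-1).astype(float)
            tgt = np.stack([tm, ~tm], axis=-1).astype(float)
            expected = 0.5 * (brute_force_dice(pm, tm) + brute_force_dice(~pm, ~tm))
            got = macro_soft_dice(pred, tgt, np.ones((6, 6), bool))
            assert got == pytest.approx(expected, abs=1e-9)

    def test_hand_example_half(self):
        pred = np.array([[[1.0]], [[0.0]]])
        tgt = np.array([[[0.5]], [[0.5]]])
        assert macro_soft_dice(pred, tgt, np.ones((2, 1), bool)) == \
            pytest.approx(0.5, abs=1e-12)

    def test_symmetric_at_equal_weights(self, rng):
        p = rng.dirichlet(np.ones(3), size=(8,))
        y = rng.dirichlet(np.ones(3), size=(8,))
        mask = np.ones(8, bool)
        assert macro_soft_dice(p, y, mask) == pytest.approx(
            macro_soft_dice(y, p, mask), abs=1e-12
        )

    def test_zero_support_policies(self):
        pred = np.zeros((1, 1, 3))
        pred[..., 0] = 1.0
        tgt = pred.copy()
        mask = np.ones((1, 1), bool)
        excl = macro_soft_dice(pred, tgt, mask, MetricConfig())
        one = macro_soft_dice(
            pred, tgt, mask,
            MetricConfig(zero_support_policy=ZeroSupportPolicy.SCORE_ONE),
        )
        assert excl == pytest.approx(1.0)
        assert one == pytest.approx(1.0)


class TestL1Metric:
    def test_identity_zero(self, rng):
        p = rng.dirichlet(np.ones(3), size=(4, 4))
        assert l1_metric(p, p.copy(), np.ones((4, 4), bool)) == 0.0

    def test_hand_example_quarter(self):
        """N=1, P=1, C=2, p=(0.75,0.25), y=(0.25,0.75): 1/(2·1·2·1)·1 = 0.25."""
        p = np.array([[[0.75, 0.25]]])
        y = np.array([[[0.25, 0.75]]])
        assert l1_metric(p, y, np.ones((1, 1), bool)) == pytest.approx(0.25, abs=1e-12)

    def test_disjoint_one_hot_half(self):
        """Fully disjoint one-hot distributions at C=2 score 0.5 under the
        printed 1/(2NCP) normalization (and 1.0 under the /2NP variant)."""
        p = np.array([[[1.0, 0.0]]])
        y = np.array([[[0.0, 1.0]]])
        mask = np.ones((1, 1), bool)
        assert l1_metric(p, y, mask) == pytest.approx(0.5, abs=1e-12)
        assert l1_metric(p, y, mask, normalizer="2np") == pytest.approx(1.0, abs=1e-12)

    def test_triangle_inequality_spot_checks(self, rng):
        mask = np.ones((3, 3), bool)
        for _ in range(25):
            a, b, c = (rng.dirichlet(np.ones(4), size=(3, 3)) for _ in range(3))
            ab = l1_metric(a, b, mask)
            bc = l1_metric(b, c, mask)
            ac = l1_metric(a, c, mask)
            assert ac <= ab + bc + 1e-12
            assert ab == pytest.approx(l1_metric(b, a, mask), abs=1e-15)
            assert ab >= 0.0

    def test_per_image_average_over_unequal_sizes(self):
        p1 = np.array([[[1.0, 0.0]]])
        y1 = np.array([[[0.0, 1.0]]])
        p2 = np.full((2, 1, 2), 0.5)
        y2 = p2.copy()
        masks = [np.ones((1, 1), bool), np.ones((2, 1), bool)]
        assert l1_metric([p1, p2], [y1, y2], masks) == pytest.approx(0.25, abs=1e-12)


class TestHardMetrics:
    def test_perfect(self):
        labels = np.array([[0, 1], [1, 0]])
        dice, macro, per_class = hard_dice_metrics(labels, labels, np.ones((2, 2), bool), 2)
        assert dice == macro == 1.0
        np.testing.assert_allclose(per_class, 1.0)

    def test_one_misclassified_of_four(self):
        """2-class 4-pixel fixture, one error: global Dice 3/4; per-class from
        hand confusion counts TP0=2, TP1=1, FP1... ."""
        target = np.array([[0, 0], [1, 1]])
        pred = np.array([[0, 1], [1, 1]])
        mask = np.ones((2, 2), bool)
        dice, macro, per_class = hard_dice_metrics(pred, target, mask, 2)
        assert dice == pytest.approx(0.75)
        assert per_class[0] == pytest.approx(2 * 1 / (2 * 1 + 1 + 0))  # 2TP/(2TP+FN)
        assert per_class[1] == pytest.approx(2 * 2 / (2 * 2 + 1 + 0))
        counts, percent = confusion(pred, target, mask, 2)
        np.testing.assert_array_equal(counts, [[1, 1], [0, 2]])
        assert percent[0].sum() == pytest.approx(100.0, abs=0.1)
        assert percent[0, 1] == pytest.approx(50.0)

    def test_never_predicted_class_scores_zero(self):
        target = np.array([[0, 1]])
        pred = np.array([[0, 0]])
        _, _, per_class = hard_dice_metrics(pred, target, np.ones((1, 2), bool), 2)
        assert per_class[1] == 0.0

    def test_off_mask_values_never_read(self, rng):
        """All metrics are invariant to NaN-poisoning off-mask pixels."""
        mask = rng.random((5, 5)) < 0.6
        pred = rng.dirichlet(np.ones(3), size=(5, 5))
        tgt = rng.dirichlet(np.ones(3), size=(5, 5))
        labels = rng.integers(0, 3, (5, 5))
        plabels = rng.integers(0, 3, (5, 5))
        poisoned_pred = pred.copy()
        poisoned_tgt = tgt.copy()
        poisoned_pred[~mask] = np.nan
        poisoned_tgt[~mask] = np.nan
        assert macro_soft_dice(poisoned_pred, poisoned_tgt, mask) == \
            pytest.approx(macro_soft_dice(pred, tgt, mask))
        assert l1_metric(poisoned_pred, poisoned_tgt, mask) == \
            pytest.approx(l1_metric(pred, tgt, mask))
        assert soft_dice_loss(poisoned_pred, poisoned_tgt, mask) == \
            pytest.approx(soft_dice_loss(pred, tgt, mask))
        d1 = hard_dice_metrics(plabels, labels, mask, 3)[0]
        assert d1 == hard_dice_metrics(plabels, labels, mask, 3)[0]
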