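"""Focal loss closed forms and metric oracles."""
import math

import numpy as np
import pytest
from sklearn.metrics import confusion_matrix, roc_auc_score

import angioseg as ag
from angioseg import nn
from angioseg.losses import FocalLossParams


def probs_from_vessel(p_vessel):
    """(N,2,H,W) simplex map from a vessel-probability plane."""
    pv = np.asarray(p_vessel, dtype=np.float64)
    return np.stack([1.0 - pv, pv], axis=1)


class TestWeightedCE:
    def test_perfect_prediction_is_zero(self):
        t = np.array([[[0, 1], [1, 0]]])
        p = probs_from_vessel(t.astype(float))
        assert ag.weighted_ce(p, t) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_prediction_unit_weights_is_ln2(self):
        t = np.array([[[0, 1], [1, 0]]])
        p = probs_from_vessel(np.full((1, 2, 2), 0.5))
        assert ag.weighted_ce(p, t, (1.0, 1.0)) == pytest.approx(math.log(2))

    def test_two_by_two_toy_matches_hand_summation(self):
        # pixels: vessel p=0.9, vessel p=0.6, background p_bg=0.8, p_bg=0.3
        pv = np.array([[[0.9, 0.6], [0.2, 0.7]]])
        t = np.array([[[1, 1], [0, 0]]])
        expected = (-20 * math.log(0.9) - 20 * math.log(0.6)
                    - math.log(0.8) - math.log(0.3)) / 4
        got = ag.weighted_ce(probs_from_vessel(pv), t, (1.0, 20.0))
        assert got == pytest.approx(expected, rel=1e-9)

    def test_zero_probability_clamped_finite(self):
        t = np.array([[[1]]])
        p = probs_from_vessel(np.array([[[0.0]]]))
        assert np.isfinite(ag.weighted_ce(p, t))


class TestFocalLoss:
    def test_perfect_prediction_is_zero(self):
        t = np.array([[[0, 1], [1, 0]]])
        p = probs_from_vessel(t.astype(float))
        assert ag.focal_loss(p, t) == pytest.approx(0.0, abs=1e-6)

    def test_gamma_zero_alpha_one_reduces_to_weighted_ce(self, rng):
        pv = rng.uniform(0.05, 0.95, (2, 8, 8))
        t = (rng.random((2, 8, 8)) < 0.3).astype(np.uint8)
        params = FocalLossParams(alpha=1.0, gamma=0.0, class_weights=(1.0, 20.0))
        assert ag.focal_loss(probs_from_vessel(pv), t, params) == pytest.approx(
            ag.weighted_ce(probs_from_vessel(pv), t, (1.0, 20.0)), rel=1e-9)

    def test_single_vessel_pixel_hand_value(self):
        # alpha (1-p)^gamma w (-ln p) = 0.8 * 0.25^2 * 20 * (-ln 0.75)
        t = np.array([[[1]]])
        p = probs_from_vessel(np.array([[[0.75]]]))
        expected = 0.8 * 0.25 ** 2 * 20 * (-math.log(0.75))
        assert expected == pytest.approx(0.28768, abs=5e-6)
        assert ag.focal_loss(p, t) == pytest.approx(expected, rel=1e-9)

    def test_monotone_decreasing_in_true_class_probability(self):
        t = np.ones((1, 1, 1), dtype=np.uint8)
        vals = [ag.focal_loss(probs_from_vessel(np.full((1, 1, 1), p)), t)
                for p in np.linspace(0.05, 0.99, 20)]
        assert np.all(np.diff(vals) < 0)

    def test_tensor_path_matches_numpy_path_and_is_differentiable(self, rng):
        pv = rng.uniform(0.1, 0.9, (1, 4, 4))
        t = (rng.random((1, 4, 4)) < 0.4).astype(np.uint8)
        logits = nn.Tensor(np.log(probs_from_vessel(pv)).astype(np.float32),
                           requires_grad=True)
        probs = nn.softmax(logits, axis=1)
        loss = ag.focal_loss(probs, t)
        assert loss.item() == pytest.approx(
            ag.focal_loss(probs.numpy(), t), rel=1e-4)
        loss.backward()
        assert logits.grad is not None and np.all(np.isfinite(logits.grad))

    def test_literal_form_switch(self):
        t = np.array([[[1, 0]]])
        p = probs_from_vessel(np.array([[[0.7, 0.2]]]))
        lit = ag.focal_loss(p, t, FocalLossParams(literal_form=True))
        std = ag.focal_loss(p, t)
        assert np.isfinite(lit) and lit != pytest.approx(std)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FocalLossParams(alpha=0.0)
        with pytest.raises(ValueError):
            FocalLossParams(gamma=-1.0)


class TestDice:
    def test_identical_disjoint_and_half_overlap(self):
        a = np.zeros((4, 4), np.uint8)
        a[0, :4] = 1
        assert ag.dice_score(a, a) == 1.0
        b = np.zeros((4, 4), np.uint8)
        b[1, :4] = 1
        assert ag.dice_score(a, b) == 0.0
        c = np.zeros((4, 4), np.uint8)
        c[0, 2:4] = 1
        c[1, 0:2] = 1
        assert ag.dice_score(a, c) == 0.5

    def test_symmetry_and_empty_convention(self, rng):
        x = (rng.random((16, 16)) < 0.2).astype(np.uint8)
        y = (rng.random((16, 16)) < 0.2).astype(np.uint8)
        assert ag.dice_score(x, y) == ag.dice_score(y, x)
        assert ag.dice_score(np.zeros((4, 4)), np.zeros((4, 4))) == 1.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            ag.dice_score(np.zeros((4, 4)), np.zeros((4, 5)))


class TestConfusionMetrics:
    def test_perfect_and_inverted_predictions(self, rng):
        t = (rng.random((8, 8)) < 0.4).astype(np.uint8)
        m = ag.confusion_metrics(t, t)
        assert all(m[k] == 1.0 for k in m)
        inv = ag.confusion_metrics(1 - t, t)
        assert inv["sensitivity"] == 0 and inv["specificity"] == 0 and inv["accuracy"] == 0

    def test_constructed_grid_counts(self):
        truth = np.zeros((4, 4), np.uint8)
        truth.ravel()[[0, 1, 2, 3]] = 1          # 4 vessel pixels
        pred = np.zeros((4, 4), np.uint8)
        pred.ravel()[[0, 1, 4]] = 1              # TP=2, FN=2, FP=1, TN=11
        m = ag.confusion_metrics(pred, truth)
        assert m["sensitivity"] == pytest.approx(0.5)
        assert m["specificity"] == pytest.approx(11 / 12)
        assert m["accuracy"] == pytest.approx(13 / 16)
        assert m["precision"] == pytest.approx(2 / 3)

    def test_undefined_ratio_flagged_null(self):
        m = ag.confusion_metrics(np.zeros((4, 4)), np.zeros((4, 4)))
        assert m["sensitivity"] is None and m["precision"] is None
        assert m["specificity"] == 1.0

    def test_agrees_with_sklearn_on_random_masks(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            t = (rng.random((16, 16)) < rng.uniform(0.1, 0.9)).astype(int)
            p = (rng.random((16, 16)) < rng.uniform(0.1, 0.9)).astype(int)
            m = ag.confusion_metrics(p, t)
            tn, fp, fn, tp = confusion_matrix(t.ravel(), p.ravel(),
                                              labels=[0, 1]).ravel()
            if tp + fn:
                assert m["sensitivity"] == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert m["specificity"] == pytest.approx(tn / (tn + fp))
            if tp + fp:
                assert m["precision"] == pytest.approx(tp / (tp + fp))
            assert m["accuracy"] == pytest.approx((tp + tn) / 256)


class TestAUC:
    def test_perfect_separation_and_worked_example(self):
        assert ag.auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert ag.auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(3)
        scores = rng.random(4000)
        labels = rng.integers(0, 2, 4000)
        assert ag.auc(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_ties_half_credit_matches_sklearn(self):
        rng = np.random.default_rng(4)
        scores = rng.integers(0, 5, 200) / 4.0      # heavy ties
        labels = rng.integers(0, 2, 200)
        assert ag.auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), rel=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            ag.auc([0.1, 0.9], [1, 1])


class TestMetricsReport:
    def test_aggregate_matches_hand_mean_sd_on_three_images(self, rng):
        report = ag.MetricsReport()
        dices = []
        for i in range(3):
            t = (rng.random((8, 8)) < 0.3).astype(np.uint8)
            p = (rng.random((8, 8)) < 0.3).astype(np.uint8)
            report.add(p, t, f"img{i}")
            dices.append(ag.dice_score(p, t))
        agg = report.aggregate()["dice"]
        assert agg["mean"] == pytest.approx(np.mean(dices))
        assert agg["sd"] == pytest.approx(np.std(dices, ddof=1))
        assert min(dices) <= agg["mean"] <= max(dices)

    def test_round_trip_serialization(self, tmp_path, rng):
        report = ag.MetricsReport()
        t = (rng.random((8, 8)) < 0.3).astype(np.uint8)
        report.add(t, t, "a")
        report.to_csv(tmp_path / "m.csv")
        text = report.to_json(tmp_path / "m.json")
        assert (tmp_path / "m.csv").exists() and '"dice": 1.0' in text

    def test_binarize_is_argmax(self, rng):
        pv = rng.random((1, 4, 4))
        mask = ag.binarize(probs_from_vessel(pv)[0])
        assert np.array_equal(mask, (pv[0] > 0.5).astype(np.uint8))
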