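"""Classifier head, loss family, training loop, and evaluation metrics."""

import numpy as np
import pytest

from motionsentry import detector as det
from motionsentry.detector import (
    ClassifierHead,
    DetectorConfig,
    LossWeights,
    Predictions,
    baseline_threshold_detector,
    classify,
    consistency_loss,
    cross_entropy,
    evaluate,
    loss_regularized,
    smoothing_loss,
    temporal_reg_loss,
    total_loss,
    weighted_consistency_loss,
)


class TestBaselineThresholdDetector:
    def test_zero_weights_give_half(self, rng):
        A = rng.normal(size=(10, 4, 3))
        assert baseline_threshold_detector(A, np.zeros(4)) == pytest.approx(0.5)

    def test_monotone_in_acceleration_scale(self, rng):
        A = np.abs(rng.normal(size=(10, 4, 3)))
        w = np.full(4, 0.3)
        p1 = baseline_threshold_detector(A, w)
        p2 = baseline_threshold_detector(2 * A, w)
        assert p2 >= p1

    def test_hand_sigmoid_case(self):
        # single joint with time-mean norm ln 3 and weight 1 -> sigmoid(ln 3)
        A = np.zeros((2, 1, 3))
        A[:, 0, 0] = np.log(3.0)
        assert baseline_threshold_detector(A, np.array([1.0])) == pytest.approx(0.75)


class TestClassify:
    def test_zero_weight_head_outputs_half(self, rng):
        head = ClassifierHead(
            W1=np.zeros((7, 4)), b1=np.zeros(4), w2=np.zeros(4), b2=np.zeros(1)
        )
        P = classify(rng.normal(size=(5, 4)), rng.normal(size=(5, 3)), head)
        np.testing.assert_allclose(P, 0.5)

    def test_probabilities_in_unit_interval(self, rng):
        head = ClassifierHead.init(7, 4, rng)
        P = classify(rng.normal(size=(9, 4)) * 5, rng.normal(size=(9, 3)) * 5, head)
        assert np.all((P > 0) & (P < 1))

    def test_matches_hand_forward_pass(self):
        head = ClassifierHead(
            W1=np.array([[1.0], [0.5]]), b1=np.array([0.1]),
            w2=np.array([2.0]), b2=np.array([-0.2]),
        )
        feats = np.array([[0.3]])
        scores = np.array([[0.4]])
        hidden = max(0.0, 0.3 * 1.0 + 0.4 * 0.5 + 0.1)
        expected = 1 / (1 + np.exp(-(2.0 * hidden - 0.2)))
        np.testing.assert_allclose(classify(feats, scores, head), [expected])

    def test_length_mismatch_rejected(self, rng):
        head = ClassifierHead.init(5, 3, rng)
        with pytest.raises(ValueError, match="frame count"):
            classify(rng.normal(size=(4, 2)), rng.normal(size=(5, 3)), head)


class TestPredictions:
    def test_pooling_and_threshold(self):
        p = Predictions(frame_probs=np.array([0.4, 0.8]), threshold=0.5)
        assert p.sequence_prob == pytest.approx(0.6)
        assert p.label == 1
        assert Predictions(frame_probs=np.array([0.4, 0.5])).label == 0


class TestLosses:
    def test_regularized_reduces_to_cross_entropy(self):
        p, y = 0.8, 1.0
        ce = float(cross_entropy(p, y))
        assert loss_regularized(p, y, np.zeros((3, 2)), 0.7) == pytest.approx(ce)
        assert loss_regularized(p, y, np.ones((3, 2)), 0.0) == pytest.approx(ce)

    def test_regularized_hand_case(self):
        # perfect prediction, S summing to 2, lambda 0.5 -> loss 1
        S = np.array([[1.5, 0.5]])
        assert loss_regularized(1.0, 1.0, S, 0.5) == pytest.approx(1.0, abs=1e-9)

    def test_consistency_constant_zero_and_single_step(self):
        assert consistency_loss(np.full(6, 0.3)) == 0.0
        assert consistency_loss(np.array([0.0, 1.0])) == pytest.approx(1.0)

    def test_weighted_consistency_reduces_at_gamma_zero(self):
        P = np.array([0.1, 0.7, 0.2])
        assert weighted_consistency_loss(P, 0.0) == pytest.approx(
            consistency_loss(P)
        )
        assert weighted_consistency_loss(np.array([0.0, 1.0]), 2.0) == pytest.approx(3.0)

    def test_smoothing_telescopes_on_monotone_ramp(self):
        for steps in (2, 5, 11):
            P = np.linspace(0, 1, steps)
            assert smoothing_loss(P) == pytest.approx(1.0)
        assert smoothing_loss(np.array([0.2, 0.5])) == pytest.approx(0.3)

    def test_temporal_reg_lag_matching(self):
        assert temporal_reg_loss(np.full(6, 0.4), 2) == 0.0
        osc = np.array([0.0, 1.0, 0.0, 1.0, 0.0])
        assert temporal_reg_loss(osc, 2) == 0.0
        assert temporal_reg_loss(np.array([0.0, 0.0, 1.0]), 2) == pytest.approx(1.0)

    def test_temporal_reg_empty_sum_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            assert temporal_reg_loss(np.array([0.1, 0.2]), 5) == 0.0

    def test_total_loss_composition(self):
        P = np.array([0.2, 0.9, 0.3])
        y = 1.0
        w = LossWeights(lambda1=0.5, lambda2=0.25, lambda3=0.1, gap_k=2)
        total, parts = total_loss(P, y, w)
        expected = (
            parts["classification"]
            + 0.5 * parts["consistency"]
            + 0.25 * parts["smoothing"]
            + 0.1 * parts["temporal_reg"]
        )
        assert total == pytest.approx(expected)
        assert parts["total"] >= parts["classification"]

    def test_total_loss_classification_only(self):
        P = np.array([0.2, 0.9, 0.3])
        w = LossWeights(lambda1=0.0, lambda2=0.0, lambda3=0.0)
        total, parts = total_loss(P, 1.0, w)
        assert total == pytest.approx(parts["classification"])

    def test_total_loss_linear_in_each_weight(self):
        P = np.array([0.2, 0.9, 0.3, 0.6, 0.5, 0.7])
        base, _ = total_loss(P, 0.0, LossWeights(lambda1=0, lambda2=0, lambda3=0))
        one, _ = total_loss(P, 0.0, LossWeights(lambda1=1, lambda2=0, lambda3=0))
        two, _ = total_loss(P, 0.0, LossWeights(lambda1=2, lambda2=0, lambda3=0))
        assert two - one == pytest.approx(one - base)

    @pytest.mark.parametrize("seed", range(3))
    def test_all_terms_nonnegative(self, seed):
        P = np.random.default_rng(seed).uniform(0.01, 0.99, size=10)
        _, parts = total_loss(P, 1.0, LossWeights())
        assert all(v >= 0 for v in parts.values())

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(lambda1=-0.1)


class TestTraining:
    def test_one_epoch_smoke_and_determinism(self, small_corpus):
        cfg = DetectorConfig(epochs=1)
        f1 = det.train(small_corpus, cfg, seed=3)
        f2 = det.train(small_corpus, cfg, seed=3)
        assert f1.log["epochs"][0] == f2.log["epochs"][0]
        for a, b in zip(f1.model.state_arrays(), f2.model.state_arrays()):
            np.testing.assert_array_equal(a, b)
        preds = det.predict(f1, small_corpus.sequences[:2], small_corpus.bundles[:2])
        assert len(preds) == 2
        assert 0.0 <= preds[0].sequence_prob <= 1.0

    def test_loss_decreases_over_training(self):
        """Mean training loss later in training beats the first epoch (3 seeds)."""
        from motionsentry import SyntheticSpec, make_corpus

        improved = 0
        for seed in range(3):
            corpus = make_corpus(SyntheticSpec(n_sequences=24, seed=50 + seed))
            f = det.train(corpus, DetectorConfig(epochs=5), seed=seed)
            first = f.log["epochs"][0]["train"]["total"]
            last = f.log["epochs"][-1]["train"]["total"]
            improved += last < first
        assert improved >= 2

    def test_log_records_loss_breakdown(self, small_corpus):
        f = det.train(small_corpus, DetectorConfig(epochs=1), seed=0)
        entry = f.log["epochs"][0]
        for split in ("train", "val"):
            assert set(entry[split]) == {
                "classification", "consistency", "smoothing", "temporal_reg", "total",
            }


class TestEvaluate:
    def test_perfect_predictions(self):
        m = evaluate([0.9, 0.1, 0.8, 0.2], [1, 0, 1, 0])
        assert m == {"accuracy": 1.0, "recall": 1.0, "f1": 1.0, "auc": 1.0}

    def test_all_positive_predictor_on_balanced_labels(self):
        m = evaluate([0.9, 0.9, 0.9, 0.9], [1, 0, 1, 0])
        assert m["accuracy"] == pytest.approx(0.5)
        assert m["recall"] == pytest.approx(1.0)
        assert m["f1"] == pytest.approx(2 / 3)

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(0)
        aucs = []
        for _ in range(50):
            scores = rng.random(100)
            labels = rng.integers(0, 2, 100)
            if len(np.unique(labels)) < 2:
                continue
            aucs.append(evaluate(scores, labels)["auc"])
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)
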