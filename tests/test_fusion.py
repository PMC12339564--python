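"""Static and adaptive multi-modality fusion."""

import numpy as np
import pytest

from motionsentry import detector as det
from motionsentry import make_corpus, SyntheticSpec
from motionsentry.fusion import (
    FusionParams,
    ModalityBundle,
    fuse,
    fuse_sequence,
    modality_weights,
    project_modalities,
    static_mix,
    temporal_context,
)


def bundle_from(vision, imu, pressure):
    return ModalityBundle(
        features={"vision": vision, "imu": imu, "pressure": pressure}
    )


@pytest.fixture()
def tiny_bundle(rng):
    T, J = 6, 3
    return bundle_from(
        rng.normal(size=(T, J, 3)),
        rng.normal(size=(T, J, 3)),
        rng.normal(size=(T, J, 1)),
    )


class TestStaticMix:
    def test_one_hot_returns_that_modality(self, rng):
        v = rng.normal(size=(4, 2, 3))
        b = bundle_from(v, rng.normal(size=(4, 2, 3)), rng.normal(size=(4, 2, 3)))
        out = static_mix(b, {"vision": 1.0, "imu": 0.0, "pressure": 0.0})
        np.testing.assert_allclose(out, v)

    def test_convex_mix_of_equal_channels(self, rng):
        v = rng.normal(size=(4, 2, 3))
        b = bundle_from(v, v.copy(), v.copy())
        out = static_mix(b, {"vision": 0.5, "imu": 0.5, "pressure": 0.0})
        np.testing.assert_allclose(out, v)

    def test_all_zero_coefficients_warn(self, rng):
        v = rng.normal(size=(3, 2, 3))
        b = bundle_from(v, v, v)
        with pytest.warns(UserWarning, match="zero"):
            out = static_mix(b, {"vision": 0.0, "imu": 0.0, "pressure": 0.0})
        np.testing.assert_allclose(out, 0.0)

    def test_negative_coefficient_rejected(self, rng):
        with pytest.raises(ValueError, match="nonnegative"):
            ModalityBundle(
                features={"vision": rng.normal(size=(3, 2, 3))},
                static_coefficients={"vision": -1.0},
            )


class TestBundleInvariants:
    def test_frame_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="frame count"):
            ModalityBundle(
                features={
                    "vision": rng.normal(size=(4, 2, 3)),
                    "imu": rng.normal(size=(5, 2, 3)),
                }
            )

    def test_missing_modality_is_absent_not_zero(self, rng):
        b = ModalityBundle(features={"vision": rng.normal(size=(4, 2, 3))})
        assert "imu" not in b.features
        assert b.names == ["vision"]


class TestProjection:
    def test_identity_passthrough(self, rng):
        x = rng.normal(size=(4, 2, 3))
        params = FusionParams(
            projections={"vision": (np.eye(3), np.zeros(3))},
            w_score=np.zeros(2),
            W_score=np.zeros((3, 2)),
            b_score=np.zeros(2),
        )
        out = project_modalities({"vision": x}, params)
        np.testing.assert_allclose(out["vision"], x)

    def test_zero_weights_give_bias_rows(self, rng):
        x = rng.normal(size=(4, 2, 3))
        b = np.array([1.0, -2.0])
        params = FusionParams(
            projections={"vision": (np.zeros((3, 2)), b)},
            w_score=np.zeros(2),
            W_score=np.zeros((2, 2)),
            b_score=np.zeros(2),
        )
        out = project_modalities({"vision": x}, params)
        np.testing.assert_allclose(out["vision"], np.broadcast_to(b, (4, 2, 2)))

    def test_random_case_matches_hand_product(self, rng):
        x = rng.normal(size=(3, 2, 4))
        W, b = rng.normal(size=(4, 5)), rng.normal(size=5)
        params = FusionParams(
            projections={"imu": (W, b)},
            w_score=np.zeros(2),
            W_score=np.zeros((5, 2)),
            b_score=np.zeros(2),
        )
        out = project_modalities({"imu": x}, params)
        for t in range(3):
            for j in range(2):
                np.testing.assert_allclose(out["imu"][t, j], x[t, j] @ W + b)

    def test_unknown_modality_rejected(self, rng):
        params = FusionParams.init({"vision": 3}, 4, rng)
        with pytest.raises(KeyError, match="pressure"):
            project_modalities({"pressure": rng.normal(size=(2, 2, 3))}, params)


class TestModalityWeights:
    def test_identical_embeddings_uniform(self, rng):
        params = FusionParams.init({"a": 3}, 4, rng, use_context=False)
        emb = np.tile(rng.normal(size=(1, 4)), (3, 1))
        alpha = modality_weights(emb, params)
        np.testing.assert_allclose(alpha, 1 / 3, atol=1e-12)

    def test_hand_softmax_quarter_three_quarters(self):
        # engineer scores (0, ln 3): s_i = 2 * tanh(emb_i), emb = arctanh(s/2)
        params = FusionParams(
            projections={},
            w_score=np.array([2.0]),
            W_score=np.array([[1.0]]),
            b_score=np.array([0.0]),
        )
        target = np.array([0.0, np.log(3.0)])
        emb = np.arctanh(target / 2.0)[:, None]
        alpha = modality_weights(emb, params)
        np.testing.assert_allclose(alpha, [0.25, 0.75], atol=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_weights_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        params = FusionParams.init({"a": 3}, 4, rng, use_context=False)
        alpha = modality_weights(rng.normal(size=(5, 4)) * 3, params)
        assert alpha.sum() == pytest.approx(1.0, abs=1e-9)
        assert (alpha > 0).all()

    def test_context_changes_scores(self, rng):
        params = FusionParams.init({"a": 3}, 4, rng, use_context=True)
        emb = rng.normal(size=(3, 4))
        a0 = modality_weights(emb, params, context=np.zeros(4))
        a1 = modality_weights(emb, params, context=rng.normal(size=4) * 2)
        assert not np.allclose(a0, a1)


class TestFuse:
    def test_one_hot_selects_embedding(self, rng):
        emb = rng.normal(size=(3, 5))
        np.testing.assert_allclose(fuse(emb, np.array([0.0, 1.0, 0.0])), emb[1])

    def test_opposite_vectors_cancel(self):
        emb = np.array([[1.0, -2.0], [-1.0, 2.0]])
        np.testing.assert_allclose(fuse(emb, np.array([0.5, 0.5])), 0.0)

    def test_hand_summed_three_modalities(self):
        emb = np.array([[1.0], [2.0], [4.0]])
        alpha = np.array([0.2, 0.3, 0.5])
        assert fuse(emb, alpha)[0] == pytest.approx(0.2 + 0.6 + 2.0)

    def test_coordinates_stay_in_envelope(self, rng):
        emb = rng.normal(size=(4, 6))
        alpha = rng.dirichlet(np.ones(4))
        out = fuse(emb, alpha)
        assert np.all(out <= emb.max(axis=0) + 1e-12)
        assert np.all(out >= emb.min(axis=0) - 1e-12)

    def test_permutation_invariance(self, rng):
        emb = rng.normal(size=(3, 4))
        alpha = rng.dirichlet(np.ones(3))
        perm = np.array([2, 0, 1])
        np.testing.assert_allclose(
            fuse(emb, alpha), fuse(emb[perm], alpha[perm]), atol=1e-12
        )


class TestTemporalContext:
    def test_empty_history_is_none(self):
        assert temporal_context([], 5) is None

    def test_constant_history_returns_constant(self):
        h = [np.array([1.0, 2.0])] * 7
        np.testing.assert_allclose(temporal_context(h, 3), [1.0, 2.0])

    def test_ramp_history_window_two_gives_midpoint(self):
        h = [np.array([0.0]), np.array([1.0]), np.array([2.0])]
        np.testing.assert_allclose(temporal_context(h, 2), [1.5])


class TestFuseSequence:
    def test_context_and_no_context_paths_agree_on_shapes(self, tiny_bundle, rng):
        for use_context in (False, True):
            params = FusionParams.init(
                {"vision": 3, "imu": 3, "pressure": 1}, 4, rng,
                use_context=use_context,
            )
            x_fused, alpha = fuse_sequence(tiny_bundle, params)
            assert x_fused.shape == (6, 3, 4)
            assert alpha.shape == (6, 3)
            np.testing.assert_allclose(np.sum(alpha, axis=1), 1.0, atol=1e-9)

    def test_missing_modality_renormalizes_over_present(self, rng):
        b = ModalityBundle(
            features={"vision": rng.normal(size=(4, 2, 3)),
                      "imu": rng.normal(size=(4, 2, 3))}
        )
        params = FusionParams.init(
            {"vision": 3, "imu": 3, "pressure": 1}, 4, rng, use_context=False
        )
        _, alpha = fuse_sequence(b, params)
        assert alpha.shape == (4, 2)
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-9)


class TestAdaptiveRobustness:
    """Training down-weights a modality corrupted by high-variance noise."""

    @staticmethod
    def _mean_imu_alpha(corrupt: bool, seed: int) -> float:
        corpus = make_corpus(SyntheticSpec(n_sequences=32, seed=seed))
        if corrupt:
            noise_rng = np.random.default_rng(seed + 1000)
            for b in corpus.bundles:
                b.features["imu"] = b.features["imu"] + noise_rng.normal(
                    0.0, 50.0, b.features["imu"].shape
                )
        cfg = det.DetectorConfig(epochs=20)
        fitted = det.train(corpus, cfg, seed=seed)
        alphas = []
        for i in range(8):
            sample = det.preprocess_sample(
                corpus.sequences[i], corpus.bundles[i], corpus.skeleton,
                fitted.stats, cfg,
            )
            _, alpha = fitted.model.forward(sample)
            alphas.append(alpha.data.mean(axis=0))
        names = corpus.bundles[0].names
        return float(np.mean(alphas, axis=0)[names.index("imu")])

    def test_corrupted_modality_loses_attention(self):
        deltas = []
        for seed in range(5):
            clean = self._mean_imu_alpha(False, seed)
            noisy = self._mean_imu_alpha(True, seed)
            deltas.append(clean - noisy)
        # average learned weight strictly decreases, and in most repeats
        assert np.mean(deltas) > 0
        assert sum(d > 0 for d in deltas) >= 4
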