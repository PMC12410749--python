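"""Corrective-learning loss components against independent oracles."""

import numpy as np
import pytest

from allinsam.mocl import (
    EmptyAnnotationError,
    confidence_map,
    mocl_loss,
    select_topk,
    similarity_map,
    soft_dice_loss,
    weight_maps,
    weighted_bce_loss,
)
from allinsam.types import MOCLConfig, PrototypeSet, ValidationError


class TestConfidenceMap:
    def test_uniform_prediction(self):
        p = np.full((4, 4, 2), 0.5)
        assert np.all(confidence_map(p, 1) == 0.5)

    def test_one_hot_prediction(self):
        p = np.zeros((4, 4, 2))
        p[:, :, 1] = 1.0
        assert np.all(confidence_map(p, 1) == 1.0)

    def test_slice_semantics(self):
        p = np.zeros((1, 1, 2))
        p[0, 0] = [0.3, 0.7]
        assert confidence_map(p, 1)[0, 0] == pytest.approx(0.7)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValidationError):
            confidence_map(np.full((2, 2, 2), 0.6), 0)


class TestSelectTopK:
    def test_single_pixel_forced(self):
        E = np.arange(8, dtype=float).reshape(2, 2, 2)
        W = np.zeros((2, 2))
        Y = np.zeros((2, 2))
        Y[1, 0] = 1
        protos = select_topk(E, W, Y, 1)
        assert np.array_equal(protos.embeddings[0], E[1, 0])

    def test_exhaustive_k_sorted(self):
        rng = np.random.default_rng(0)
        E = rng.random((4, 4, 3))
        W = rng.random((4, 4))
        Y = np.ones((4, 4))
        protos = select_topk(E, W, Y, 16)
        assert protos.k == 16
        assert np.all(np.diff(protos.confidences) <= 1e-12)

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(200):
            E = rng.random((16, 16, 4))
            # quantized confidences force ties; row-major order breaks them
            W = np.round(rng.random((16, 16)), 1)
            Y = (rng.random((16, 16)) < 0.4).astype(int)
            if Y.sum() == 0:
                Y[0, 0] = 1
            k = int(rng.integers(1, Y.sum() + 1))
            protos = select_topk(E, W, Y, k)
            # oracle: full stable sort of (confidence, row-major index) pairs
            idx = np.flatnonzero(Y.ravel())
            order = sorted(range(len(idx)), key=lambda i: (-W.ravel()[idx[i]], idx[i]))
            expect = idx[np.array(order[:k])]
            got_emb = protos.embeddings
            exp_emb = E.reshape(-1, 4)[expect]
            assert np.array_equal(got_emb, exp_emb)

    def test_k_clamped_with_warning(self):
        E = np.ones((2, 2, 2))
        Y = np.zeros((2, 2))
        Y[0, 0] = 1
        protos = select_topk(E, np.ones((2, 2)), Y, 10)
        assert protos.k == 1

    def test_empty_annotation_raises(self):
        with pytest.raises(EmptyAnnotationError):
            select_topk(np.ones((2, 2, 2)), np.ones((2, 2)), np.zeros((2, 2)), 1)


class TestSimilarityMap:
    def _single_proto(self, vec):
        return PrototypeSet(np.asarray([vec], dtype=float), np.asarray([1.0]))

    def test_self_similarity_is_one(self):
        E = np.zeros((1, 2, 2))
        E[0, 0] = [1.0, 2.0]
        E[0, 1] = [0.5, 0.1]
        S = similarity_map(E, self._single_proto([1.0, 2.0]))
        assert S[0, 0] == pytest.approx(1.0)

    def test_orthogonal_is_zero(self):
        E = np.zeros((1, 1, 2))
        E[0, 0] = [1.0, 0.0]
        S = similarity_map(E, self._single_proto([0.0, 1.0]))
        assert S[0, 0] == pytest.approx(0.0)

    def test_hand_value_inv_sqrt2(self):
        E = np.zeros((1, 1, 2))
        E[0, 0] = [1.0, 0.0]
        S = similarity_map(E, self._single_proto([1.0, 1.0]))
        assert S[0, 0] == pytest.approx(1.0 / np.sqrt(2.0), abs=1e-12)

    def test_bounded_on_random_draws(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            E = rng.normal(size=(4, 4, 3))
            k = int(rng.integers(1, 5))
            protos = PrototypeSet(
                rng.normal(size=(k, 3)), np.sort(rng.random(k))[::-1]
            )
            agg = "mean" if rng.random() < 0.5 else "max"
            S = similarity_map(E, protos, agg)
            assert S.min() >= -1.0 and S.max() <= 1.0

    def test_zero_norm_pixel_scores_zero(self):
        E = np.zeros((1, 2, 2))
        E[0, 1] = [1.0, 0.0]
        S = similarity_map(E, self._single_proto([1.0, 0.0]))
        assert S[0, 0] == 0.0
        assert S[0, 1] == pytest.approx(1.0)

    def test_max_aggregation_dominates_mean(self):
        rng = np.random.default_rng(5)
        E = rng.normal(size=(3, 3, 4))
        protos = PrototypeSet(rng.normal(size=(3, 4)), np.array([0.9, 0.5, 0.1]))
        assert np.all(
            similarity_map(E, protos, "max") >= similarity_map(E, protos, "mean") - 1e-12
        )


class TestWeightMaps:
    def test_zero_confidence_gives_annotation_mask(self):
        Y = np.eye(3)
        wm = weight_maps(np.zeros((3, 3)), np.ones((3, 3)), Y)
        assert np.array_equal(wm.w_conf, Y)

    def test_neutral_setting_is_unit_weight(self):
        wm = weight_maps(np.zeros((3, 3)), np.ones((3, 3)), np.ones((3, 3)), 1.0)
        assert np.allclose(wm.combined, 1.0)

    def test_hand_value_e_times_half(self):
        Y = np.ones((1, 1))
        wm = weight_maps(np.ones((1, 1)), np.full((1, 1), 0.5), Y)
        assert wm.combined[0, 0] == pytest.approx(np.e * 0.5, abs=1e-12)

    def test_negative_similarity_clipped(self):
        Y = np.ones((1, 1))
        wm = weight_maps(np.ones((1, 1)), np.full((1, 1), -0.5), Y)
        assert wm.combined[0, 0] == 0.0
        assert wm.w_sim[0, 0] == -0.5  # raw omega(S) keeps its sign

    def test_background_weight_applied_off_annotation(self):
        Y = np.zeros((2, 2))
        wm = weight_maps(np.ones((2, 2)), np.ones((2, 2)), Y, background_weight=0.25)
        assert np.allclose(wm.combined, 0.25)


class TestLosses:
    def test_dice_perfect_prediction(self):
        Y = np.zeros((4, 4))
        Y[1:3, 1:3] = 1
        assert soft_dice_loss(Y, Y, smooth=1e-12) == pytest.approx(0.0, abs=1e-9)

    def test_dice_total_miss(self):
        Y = np.zeros((4, 4))
        Y[0, 0] = 1
        P = 1.0 - Y
        assert soft_dice_loss(Y, P, smooth=1e-12) == pytest.approx(1.0, abs=1e-9)

    def test_dice_half_overlap_hand_count(self):
        Y = np.zeros((4, 4))
        Y[0, 0] = Y[0, 1] = 1
        P = np.zeros((4, 4))
        P[0, 1] = P[0, 2] = 1
        assert soft_dice_loss(Y, P, smooth=1e-15) == pytest.approx(0.5, abs=1e-9)

    def test_bce_half_probability_is_ln2(self):
        Y = np.ones((1, 1))
        P = np.full((1, 1), 0.5)
        assert weighted_bce_loss(Y, P) == pytest.approx(np.log(2.0), abs=1e-12)

    def test_bce_linear_in_weights(self):
        rng = np.random.default_rng(0)
        Y = (rng.random((5, 5)) < 0.5).astype(float)
        P = rng.random((5, 5))
        w = rng.random((5, 5))
        assert weighted_bce_loss(Y, P, 2 * w) == pytest.approx(
            2 * weighted_bce_loss(Y, P, w), rel=1e-12
        )

    def test_bce_perfect_prediction_near_zero(self):
        Y = np.zeros((3, 3))
        Y[1, 1] = 1
        assert weighted_bce_loss(Y, Y) <= 1e-6


def scripted_composition(Y, P, E, cfg):
    """Independent step-by-step evaluation of the five-stage corrective loss."""
    Yb = (Y > 0).astype(float)
    W = P  # stage 1: confidence is the foreground probability slice
    # stage 2: top-k annotated pixels by confidence, row-major tie-break
    flat = np.flatnonzero(Yb.ravel())
    order = sorted(range(len(flat)), key=lambda i: (-W.ravel()[flat[i]], flat[i]))
    k = cfg.resolve_k(len(flat))
    chosen = flat[np.array(order[:k])]
    protos = E.reshape(-1, E.shape[2])[chosen]
    # stage 3: cosine similarity against each prototype, aggregated
    S = np.zeros(Y.shape)
    for r in range(Y.shape[0]):
        for c in range(Y.shape[1]):
            e = E[r, c]
            sims = []
            for p in protos:
                den = np.sqrt((e**2).sum()) * np.sqrt((p**2).sum())
                sims.append((e * p).sum() / den if den > 0 else 0.0)
            S[r, c] = np.mean(sims) if cfg.aggregation == "mean" else np.max(sims)
    # stage 4: omega(W) = exp(W) Y, omega(S) = S Y, combined with background 1
    combined = np.where(Yb > 0, np.clip(np.exp(W) * S, 0, None), cfg.background_weight)
    # stage 5: weighted Dice + weighted BCE
    s = cfg.dice_smooth
    dice = 1 - (2 * (combined * Yb * P).sum() + s) / (
        (combined * Yb).sum() + (combined * P).sum() + s
    )
    Pc = np.clip(P, 1e-7, 1 - 1e-7)
    bce = (combined * (-Yb * np.log(Pc) - (1 - Yb) * np.log(1 - Pc))).mean()
    return dice + bce


class TestMOCLLoss:
    def _fixture(self):
        rng = np.random.default_rng(88)
        Y = (rng.random((8, 8)) < 0.4).astype(int)
        P = rng.random((8, 8))
        E = rng.random((8, 8, 4))
        return Y, P, E

    def test_matches_scripted_composition(self):
        Y, P, E = self._fixture()
        for cfg in (MOCLConfig(), MOCLConfig(k=3, aggregation="max")):
            loss, diag = mocl_loss(Y, P, E, cfg)
            expect = scripted_composition(Y, P, E, cfg)
            assert loss == pytest.approx(expect, rel=1e-10)
            assert diag["corrective"]

    def test_identity_reduction_neutral_case(self):
        # zero confidence (P = 0) and identical embeddings (S = 1) make every
        # corrective weight exactly 1, recovering the plain Dice + BCE
        Y = np.zeros((6, 6))
        Y[2:4, 2:4] = 1
        P = np.zeros((6, 6))
        E = np.ones((6, 6, 3))
        cfg = MOCLConfig(background_weight=1.0)
        loss, _ = mocl_loss(Y, P, E, cfg)
        plain = soft_dice_loss(Y, P, smooth=cfg.dice_smooth) + weighted_bce_loss(Y, P)
        assert loss == pytest.approx(plain, rel=1e-12)

    def test_empty_annotation_falls_back_unweighted(self):
        Y = np.zeros((4, 4))
        P = np.random.default_rng(1).random((4, 4))
        E = np.ones((4, 4, 2))
        loss, diag = mocl_loss(Y, P, E)
        plain = soft_dice_loss(Y, P, smooth=MOCLConfig().dice_smooth) + weighted_bce_loss(Y, P)
        assert loss == pytest.approx(plain, rel=1e-12)
        assert not diag["corrective"]

    def test_invariant_to_embedding_rescaling(self):
        Y, P, E = self._fixture()
        a, _ = mocl_loss(Y, P, E)
        b, _ = mocl_loss(Y, P, 3.7 * E)
        assert a == pytest.approx(b, rel=1e-12)

    def test_noise_pixels_get_smaller_gradient(self):
        # a low-confidence, low-similarity annotated pixel must pull the
        # prediction less than under unit weights (finite differences)
        Y = np.zeros((6, 6))
        Y[1:3, 1:3] = 1  # trusted region
        Y[5, 5] = 1  # noise pixel
        P = np.full((6, 6), 0.05)
        P[1:3, 1:3] = 0.9  # model confident on the trusted region
        P[5, 5] = 0.02  # model rejects the noise pixel
        E = np.zeros((6, 6, 2))
        E[..., 0] = 1.0  # background-like embedding everywhere
        E[1:3, 1:3] = [0.0, 1.0]  # trusted region embeds differently
        cfg = MOCLConfig(k=2)

        def grad_at(loss_fn, r, c, eps=1e-6):
            Pp, Pm = P.copy(), P.copy()
            Pp[r, c] += eps
            Pm[r, c] -= eps
            return (loss_fn(Pp) - loss_fn(Pm)) / (2 * eps)

        g_mocl = grad_at(lambda p: mocl_loss(Y, p, E, cfg)[0], 5, 5)
        g_unit = grad_at(
            lambda p: soft_dice_loss(Y, p, smooth=cfg.dice_smooth)
            + weighted_bce_loss(Y, p),
            5,
            5,
        )
        assert abs(g_mocl) < abs(g_unit)
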