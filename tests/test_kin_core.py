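"""Tests for contribution weights, the weighted dissimilarity, voting and
the composed KIN pipeline."""

import json
import math

import numpy as np
import pytest

from kin import (
    KinModel,
    NullModelError,
    PenaltyConfig,
    WeightVector,
    feature_weights,
    fit_kin,
    fit_knn,
    lambda_grid,
    model_from_json,
    model_to_json,
    predict_kin,
    predict_knn,
    select_k,
    vote_and_break_ties,
    weighted_distance,
)


class TestFeatureWeights:
    @pytest.mark.parametrize(
        "coefs, expected",
        [
            ((2.0, 0.0, 0.0, 1.0), (2 / 3, 0.0, 0.0, 1 / 3)),
            ((-1.0, 1.0), (0.5, 0.5)),  # absolute-value convention
        ],
    )
    def test_values(self, coefs, expected):
        w = feature_weights(np.array(coefs))
        np.testing.assert_allclose(w.w, expected)

    def test_normalization_and_support(self, rng):
        coefs = rng.standard_normal(30)
        coefs[rng.random(30) < 0.6] = 0.0
        if not coefs.any():
            coefs[0] = 1.0
        w = feature_weights(coefs)
        assert w.w.sum() == pytest.approx(1.0)
        np.testing.assert_array_equal(w.support, np.flatnonzero(coefs))

    def test_all_zero_raises_null_model(self):
        with pytest.raises(NullModelError):
            feature_weights(np.zeros(5))


class TestWeightedDistance:
    def test_zero_weight_coordinate_ignored(self):
        w = WeightVector(np.array([1.0, 0.0]))
        assert weighted_distance([0.0, 9.0], [3.0, 100.0], w) == pytest.approx(3.0)

    def test_identity(self, rng):
        x = rng.standard_normal(6)
        w = WeightVector(np.full(6, 1 / 6))
        assert weighted_distance(x, x, w) == 0.0

    def test_matches_termwise_oracle(self, rng):
        for _ in range(20):
            xa, xb = rng.standard_normal((2, 5))
            w = rng.random(5)
            w /= w.sum()
            oracle = math.sqrt(sum(w[j] * (xa[j] - xb[j]) ** 2 for j in range(5)))
            assert weighted_distance(xa, xb, WeightVector(w)) == pytest.approx(oracle, abs=1e-12)

    def test_metric_properties_on_support(self, rng):
        w = WeightVector(rng.dirichlet(np.ones(4)))
        xa, xb = rng.standard_normal((2, 4))
        assert weighted_distance(xa, xb, w) == pytest.approx(weighted_distance(xb, xa, w))
        assert weighted_distance(xa, xb, w) >= 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            weighted_distance([1.0], [1.0, 2.0], WeightVector(np.array([1.0, 0.0])))


class TestVote:
    @pytest.mark.parametrize(
        "labels, dists, expected",
        [
            ((0, 0, 1), (0.1, 0.2, 0.05), 0),   # simple majority
            ((1, 1, 0), (0.1, 0.2, 0.05), 1),
            ((0, 1), (0.3, 0.5), 0),            # tie -> smaller summed distance
            ((0, 1), (0.5, 0.3), 1),
            ((0, 1), (0.4, 0.4), 0),            # equal sums -> class 0
        ],
    )
    def test_rules(self, labels, dists, expected):
        assert vote_and_break_ties(labels, dists) == expected

    def test_total_for_even_k(self, rng):
        """Every even-k vote resolves to a label."""
        for _ in range(50):
            k = rng.integers(1, 5) * 2
            labels = rng.integers(0, 2, k)
            dists = np.sort(rng.random(k))
            assert vote_and_break_ties(labels, dists) in (0, 1)


class TestSelectK:
    def test_singleton_grid(self, separable_toy):
        X, y = separable_toy
        w = WeightVector(np.array([0.5, 0.5]))
        assert select_k(X, y, w, [3], seed=0) == 3

    def test_deterministic(self, separable_toy):
        X, y = separable_toy
        w = WeightVector(np.array([0.5, 0.5]))
        grid = list(range(1, 9))
        assert select_k(X, y, w, grid, seed=3) == select_k(X, y, w, grid, seed=3)

    def test_separable_data_prefers_smallest_k(self, separable_toy):
        """CV error is 0 at every k on separated blobs; ties resolve to the
        smallest k."""
        X, y = separable_toy
        w = WeightVector(np.array([0.5, 0.5]))
        assert select_k(X, y, w, [1, 2, 3, 4, 5], seed=0) == 1

    def test_too_small_training_set(self):
        X = np.zeros((6, 2))
        y = np.array([0, 1, 0, 1, 0, 1])
        w = WeightVector(np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            select_k(X, y, w, [1], n_folds=5, seed=0)


class TestFitPredict:
    def test_training_row_recalled_at_k1(self, separable_toy):
        X, y = separable_toy
        model = fit_kin(X, y, seed=0)
        model.k_selected = 1
        preds = predict_kin(model, X)
        np.testing.assert_array_equal(preds, y)

    def test_row_order_equivariance(self, separable_toy, rng):
        X, y = separable_toy
        model = fit_kin(X, y, seed=0)
        Xt = rng.standard_normal((15, 2))
        preds = predict_kin(model, Xt)
        perm = rng.permutation(15)
        np.testing.assert_array_equal(predict_kin(model, Xt[perm]), preds[perm])

    def test_agrees_with_bruteforce_oracle(self, rng):
        """Vectorized prediction equals an explicit all-pairs loop."""
        X = rng.standard_normal((30, 10))
        y = (rng.random(30) < 0.5).astype(int)
        y[:3] = [0, 1, 0]  # both classes guaranteed
        w = WeightVector(rng.dirichlet(np.ones(10)))
        model = KinModel(
            train_X=X, train_y=y, weights=w, k_selected=4, k_grid=[4],
            mean_=np.zeros(10), scale_=np.ones(10),
        )
        Xt = rng.standard_normal((12, 10))
        preds = predict_kin(model, Xt)
        for i in range(12):
            d = np.array([weighted_distance(Xt[i], X[j], w) for j in range(30)])
            idx = np.argsort(d, kind="stable")[:4]
            assert preds[i] == vote_and_break_ties(y[idx], d[idx])

    def test_zero_weight_features_cannot_affect_predictions(self, rng):
        X = rng.standard_normal((40, 6))
        y = (X[:, 0] > 0).astype(int)
        w = np.array([0.7, 0.3, 0.0, 0.0, 0.0, 0.0])
        model = KinModel(
            train_X=X, train_y=y, weights=WeightVector(w), k_selected=3,
            k_grid=[3], mean_=np.zeros(6), scale_=np.ones(6),
        )
        Xt = rng.standard_normal((20, 6))
        base = predict_kin(model, Xt)
        Xt_pert = Xt.copy()
        Xt_pert[:, 2:] += rng.standard_normal((20, 4)) * 100
        np.testing.assert_array_equal(predict_kin(model, Xt_pert), base)

    def test_uniform_weights_reduce_to_knn(self, rng):
        """With uniform weights KIN's dissimilarity is Euclidean/sqrt(p),
        so predictions match the KNN baseline at any shared odd k."""
        X = rng.standard_normal((50, 8))
        y = (X[:, 0] + 0.5 * X[:, 1] + 0.3 * rng.standard_normal(50) > 0).astype(int)
        Xt = rng.standard_normal((25, 8))
        knn = fit_knn(X, y, seed=0)
        kin = KinModel(
            train_X=knn.train_X, train_y=knn.train_y,
            weights=WeightVector(np.full(8, 1 / 8)),
            k_selected=0, k_grid=[], mean_=knn.mean_, scale_=knn.scale_,
        )
        for k in (1, 3, 5, 7):
            knn.k_selected = k
            kin.k_selected = k
            np.testing.assert_array_equal(predict_kin(kin, Xt), predict_knn(knn, Xt))

    def test_feature_count_mismatch(self, separable_toy):
        X, y = separable_toy
        model = fit_kin(X, y, seed=0)
        with pytest.raises(ValueError):
            predict_kin(model, np.zeros((3, 5)))

    def test_reproducible_under_seed(self, separable_toy):
        X, y = separable_toy
        m1 = fit_kin(X, y, seed=9)
        m2 = fit_kin(X, y, seed=9)
        assert m1.k_selected == m2.k_selected
        np.testing.assert_array_equal(m1.weights.w, m2.weights.w)

    def test_k_bound_respected(self, separable_toy):
        X, y = separable_toy
        model = fit_kin(X, y, seed=0)
        assert 1 <= model.k_selected <= math.isqrt(len(y))


class TestNullFallback:
    def test_null_model_predicts_majority(self, small_logistic_data):
        X, y = small_logistic_data
        lam_max = lambda_grid((X - X.mean(0)) / X.std(0), y)[0]
        cfg = PenaltyConfig(lam_grid=np.array([lam_max * 2.0]))
        with pytest.warns(RuntimeWarning, match="majority"):
            model = fit_kin(X, y, cfg=cfg, seed=0)
        assert model.is_null
        majority = int(np.bincount(y).argmax())
        preds = predict_kin(model, X)
        assert np.all(preds == majority)


class TestPersistence:
    def test_json_roundtrip_preserves_predictions(self, separable_toy, rng):
        X, y = separable_toy
        model = fit_kin(X, y, seed=0)
        restored = model_from_json(model_to_json(model))
        Xt = rng.standard_normal((10, 2))
        np.testing.assert_array_equal(predict_kin(restored, Xt), predict_kin(model, Xt))

    def test_json_document_fields(self, separable_toy):
        X, y = separable_toy
        doc = json.loads(model_to_json(fit_kin(X, y, seed=0)))
        for key in ("weights", "support", "k_selected", "mean", "scale", "lam_selected", "seed"):
            assert key in doc
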