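"""Weighted similarity, affinity propagation, cluster-variance weights."""

import itertools
import logging

import numpy as np
import pytest

from glucostack.ap_weighting import (
    ClusterAssignment,
    SimilarityConfig,
    affinity_propagation,
    APWeighter,
    cluster_weighted_variance,
    combine_predictions,
    net_similarity,
    normalize_weights,
    weighted_similarity,
    _median_off_diagonal,
)
from glucostack.base_models import PredictionMatrix


def brute_force_optimum(S, preference):
    """Exhaustive search over all nonempty exemplar subsets (oracle)."""
    n = S.shape[0]
    best = -np.inf
    for r in range(1, n + 1):
        for subset in itertools.combinations(range(n), r):
            best = max(best, net_similarity(S, subset, preference))
    return best


class TestWeightedSimilarity:
    def test_alpha_zero_is_negated_distance_matrix(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 3))
        S = weighted_similarity(X, SimilarityConfig(similarity_alpha=0.0)).S
        from scipy.spatial.distance import cdist
        np.testing.assert_allclose(S, -cdist(X, X), atol=1e-12)

    def test_worked_two_point_example(self):
        # dis = sqrt(8), var1 = var2 = 0.25, alpha = 0.5
        S = weighted_similarity(np.array([[1.0, 2.0], [3.0, 4.0]])).S
        assert S[0, 1] == pytest.approx(-(np.sqrt(8) + 0.5 * 0.5), abs=1e-10)
        assert S[0, 1] == pytest.approx(-3.0784, abs=1e-4)
        assert S[1, 0] == S[0, 1]

    def test_duplicated_points_leave_only_variance_term(self):
        row = np.array([2.0, 4.0])  # own-feature variance 1.0
        S = weighted_similarity(np.vstack([row, row])).S
        assert S[0, 1] == pytest.approx(-2 * 0.5 * 1.0)

    def test_symmetry_and_nonpositive_off_diagonal(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 4))
        S = weighted_similarity(X).S
        np.testing.assert_allclose(S, S.T)
        off = S[~np.eye(8, dtype=bool)]
        assert (off <= 0).all()

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            weighted_similarity(np.array([[1.0, np.nan], [0.0, 1.0]]))


class TestAffinityPropagation:
    def test_single_point_is_own_exemplar(self):
        a = affinity_propagation(np.zeros((1, 1)))
        assert a.n_clusters == 1
        assert a.labels[0] == 0

    def test_two_well_separated_groups_recovered(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([np.tile([0.0, 0.0], (3, 1)),
                         np.tile([10.0, 10.0], (3, 1))]) + rng.normal(0, 0.01, (6, 2))
        a = affinity_propagation(weighted_similarity(pts))
        assert a.n_clusters == 2
        np.testing.assert_array_equal(a.labels[:3], [a.labels[0]] * 3)
        np.testing.assert_array_equal(a.labels[3:], [a.labels[3]] * 3)
        assert a.exemplar_indices[0] in (0, 1, 2)
        assert a.exemplar_indices[1] in (3, 4, 5)

    def test_near_optimal_on_small_random_instances(self):
        rng = np.random.default_rng(42)
        for trial in range(20):
            n = int(rng.integers(2, 9))
            pts = rng.normal(size=(n, int(rng.integers(1, 4))))
            sim = weighted_similarity(pts)
            pref = _median_off_diagonal(sim.S)
            a = affinity_propagation(sim)
            achieved = net_similarity(sim.S, a.exemplar_indices, pref)
            optimum = brute_force_optimum(sim.S, pref)
            assert optimum - achieved <= 0.01 * abs(optimum) + 1e-12

    def test_each_exemplar_labels_itself(self):
        rng = np.random.default_rng(5)
        a = affinity_propagation(weighted_similarity(rng.normal(size=(10, 2))))
        for ci, ex in enumerate(a.exemplar_indices):
            assert a.labels[ex] == ci


class TestClusterVariance:
    def test_constant_model_column_gets_zero(self):
        X = np.column_stack([np.full(4, 3.0), [0.0, 1, 2, 3]])
        a = ClusterAssignment(np.array([0]), np.zeros(4, dtype=int))
        w = cluster_weighted_variance(X, a)
        assert w[0] == 0.0
        assert w[1] > 0

    def test_single_cluster_worked_example(self):
        # points 0 and 2, mean 1, C=1: w = (0-1)^2 + (2-1)^2 = 2
        a = ClusterAssignment(np.array([0]), np.array([0, 0]))
        w = cluster_weighted_variance(np.array([[0.0], [2.0]]), a)
        assert w[0] == pytest.approx(2.0)

    def test_two_cluster_worked_example(self):
        # clusters {0,2} and {10,14}: contributions 2 and 8, C=2 -> w = 5
        a = ClusterAssignment(np.array([0, 2]), np.array([0, 0, 1, 1]))
        w = cluster_weighted_variance(np.array([[0.0], [2.0], [10.0], [14.0]]), a)
        assert w[0] == pytest.approx(5.0)

    def test_inconsistent_labels_rejected(self):
        a = ClusterAssignment(np.array([0]), np.array([0, 1]))
        with pytest.raises(ValueError):
            cluster_weighted_variance(np.zeros((2, 1)), a)


class TestNormalizeWeights:
    def test_equal_raw_weights_uniform(self):
        np.testing.assert_allclose(normalize_weights([2.0, 2, 2]).weights, 1 / 3)

    def test_proportional_normalization(self):
        np.testing.assert_allclose(normalize_weights([1.0, 3.0]).weights, [0.25, 0.75])

    def test_all_zero_falls_back_to_uniform_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            wv = normalize_weights([0.0, 0.0, 0.0])
        np.testing.assert_allclose(wv.weights, 1 / 3)
        assert "uniform" in caplog.text

    def test_invert_flag_reverses_ordering(self):
        wv = normalize_weights([1.0, 4.0], invert_flag=True)
        assert wv.weights[0] > wv.weights[1]
        assert wv.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_sum_is_one_within_tolerance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            wv = normalize_weights(rng.random(4))
            assert wv.weights.sum() == pytest.approx(1.0, abs=1e-9)


class TestCombinePredictions:
    def test_one_hot_weights_select_single_model(self):
        rng = np.random.default_rng(0)
        mats = [rng.random((4, 3)) for _ in range(3)]
        out = combine_predictions(mats, [1.0, 0.0, 0.0])
        np.testing.assert_array_equal(out.values, mats[0])

    def test_uniform_weights_are_elementwise_mean(self):
        mats = [np.full((2, 2), v) for v in (1.0, 2.0, 6.0)]
        out = combine_predictions(mats, [1 / 3] * 3)
        np.testing.assert_allclose(out.values, 3.0)

    def test_scalar_worked_example(self):
        mats = [np.array([[10.0]]), np.array([[20.0]]), np.array([[30.0]])]
        out = combine_predictions(mats, [0.5, 0.3, 0.2])
        assert out.values[0, 0] == pytest.approx(17.0)

    def test_combination_within_envelope(self):
        rng = np.random.default_rng(3)
        mats = [rng.random((6, 4)) for _ in range(3)]
        w = rng.random(3)
        w /= w.sum()
        out = combine_predictions(mats, w).values
        lo = np.min(mats, axis=0)
        hi = np.max(mats, axis=0)
        assert (out >= lo - 1e-12).all() and (out <= hi + 1e-12).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            combine_predictions([np.zeros((2, 2)), np.zeros((3, 2))], [0.5, 0.5])

    def test_prediction_matrix_inputs_preserve_scale(self):
        mats = [PredictionMatrix(np.ones((2, 2)), scale="mg_dl") for _ in range(2)]
        assert combine_predictions(mats, [0.5, 0.5]).scale == "mg_dl"


class TestAPWeighter:
    def test_identical_base_models_get_uniform_weights(self):
        rng = np.random.default_rng(0)
        col = rng.random(30)
        points = np.column_stack([col, col, col])
        w = APWeighter(seed=0).fit(points).weights_
        np.testing.assert_allclose(w, 1 / 3, atol=1e-9)

    def test_oracle_model_gets_largest_weight_under_inversion(self):
        # clustered targets plus per-model noise; the noise-free "oracle"
        # column has the smallest within-cluster variance, so with the
        # inverted normalization it must receive the largest weight
        rng = np.random.default_rng(1)
        centers = rng.choice([0.2, 0.5, 0.8], size=120)
        y = centers + rng.normal(0, 0.01, 120)
        noisy1 = y + rng.normal(0, 0.05, 120)
        noisy2 = y + rng.normal(0, 0.08, 120)
        points = np.column_stack([noisy1, noisy2, y])
        w = APWeighter(invert_flag=True, seed=0).fit(points).weights_
        assert np.argmax(w) == 2

    def test_sample_cap_subsamples_deterministically(self):
        rng = np.random.default_rng(2)
        points = rng.random((50, 3))
        a = APWeighter(sample_cap=20, seed=3).fit(points)
        b = APWeighter(sample_cap=20, seed=3).fit(points)
        assert len(a.points_) == 20
        np.testing.assert_array_equal(a.points_, b.points_)
        np.testing.assert_array_equal(a.weights_, b.weights_)
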