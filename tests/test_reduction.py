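"""Gaussian affinities, KL divergence and exact t-SNE."""

import numpy as np
import pytest

from dermafusion.matrix import FeatureMatrix
from dermafusion.reduction import (
    REDUCTION_DIMS,
    TSNEParams,
    kl_divergence,
    pairwise_affinities,
    reduce_features,
    tsne_reduce,
)
from dermafusion.synthetic import generate_feature_matrix


class TestPairwiseAffinities:
    def test_closest_pair_holds_largest_affinity(self):
        local = np.random.default_rng(5)
        X = local.random((12, 3)) * 10
        X[1] = X[0] + 0.01  # force a closest pair
        P = pairwise_affinities(X, perplexity=3)
        i, j = np.unravel_index(np.argmax(P), P.shape)
        assert {i, j} == {0, 1}

    def test_colinear_three_points_match_hand_evaluated_gaussians(self):
        # points at 0, 1, 3 with a fixed common bandwidth sigma=1:
        # conditionals from point 0: exp(-0.5)/Z, exp(-4.5)/Z
        from dermafusion.reduction import _entropy_and_probs

        d0 = np.array([1.0, 9.0])  # squared distances from x=0 to 1, 3
        _, p = _entropy_and_probs(d0, beta=0.5)  # beta = 1/(2 sigma^2)
        z = np.exp(-0.5) + np.exp(-4.5)
        np.testing.assert_allclose(p, [np.exp(-0.5) / z, np.exp(-4.5) / z], atol=1e-12)

    def test_entropy_matches_log_perplexity_after_bisection(self, rng):
        X = rng.normal(size=(30, 5))
        perplexity = 8.0
        P, sigmas = pairwise_affinities(X, perplexity, return_sigmas=True)
        # recompute each conditional entropy from the returned sigmas
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(X, "sqeuclidean"))
        idx = np.arange(30)
        for i in range(30):
            beta = 1.0 / (2.0 * sigmas[i] ** 2)
            logits = -D[i, idx != i] * beta
            logits -= logits.max()
            p = np.exp(logits)
            p /= p.sum()
            h = -(p[p > 0] * np.log(p[p > 0])).sum()
            assert abs(h - np.log(perplexity)) <= 1e-3

    def test_matrix_invariants(self, rng):
        X = rng.normal(size=(20, 4))
        P = pairwise_affinities(X, perplexity=7)
        assert abs(P.sum() - 1.0) <= 1e-9
        np.testing.assert_allclose(P, P.T, atol=1e-15)
        assert np.all(np.diag(P) == 0) and P.min() >= 0

    def test_duplicate_only_input_reported(self):
        X = np.zeros((5, 3))
        with pytest.raises(ValueError, match="bisection"):
            pairwise_affinities(X, perplexity=2)

    def test_perplexity_bounds(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            pairwise_affinities(X, perplexity=5)


class TestKLDivergence:
    def test_identical_distributions_give_zero(self, rng):
        P = rng.random((6, 6))
        np.fill_diagonal(P, 0)
        P /= P.sum()
        assert kl_divergence(P, P) == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_two_cell_example(self):
        P = np.array([[0.0, 0.6], [0.4, 0.0]])
        Q = np.array([[0.0, 0.5], [0.5, 0.0]])
        expected = 0.6 * np.log(0.6 / 0.5) + 0.4 * np.log(0.4 / 0.5)
        assert kl_divergence(P, Q) == pytest.approx(expected, abs=1e-12)

    def test_nonnegative_over_random_pairs(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            P = rng.random((5, 5))
            Q = rng.random((5, 5))
            np.fill_diagonal(P, 0)
            np.fill_diagonal(Q, 0)
            P /= P.sum()
            Q /= Q.sum()
            assert kl_divergence(P, Q) >= -1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kl_divergence(np.zeros((3, 3)), np.zeros((4, 4)))


class TestTSNE:
    @pytest.fixture(scope="class")
    def two_clusters(self):
        fm, y = generate_feature_matrix(30, 20, 8.0, 2, seed=3)
        return fm, y

    def test_output_shape_and_alignment(self, two_clusters):
        fm, _ = two_clusters
        emb = tsne_reduce(fm, TSNEParams(out_dim=2, perplexity=15, seed=0))
        assert emb.shape == (60, 2)
        assert emb.row_ids == fm.row_ids

    def test_kl_decreases_after_exaggeration_phase(self, two_clusters):
        fm, _ = two_clusters
        params = TSNEParams(out_dim=2, perplexity=15, seed=0)
        _, trace = tsne_reduce(fm, params, return_trace=True)
        assert trace[-1] <= trace[params.exaggeration_iter]

    def test_two_clusters_embed_with_good_silhouette(self, two_clusters):
        from sklearn.metrics import silhouette_score

        fm, y = two_clusters
        emb = tsne_reduce(fm, TSNEParams(out_dim=2, perplexity=15, seed=0))
        assert silhouette_score(emb.values, y) >= 0.5

    def test_seed_determinism(self, two_clusters):
        fm, _ = two_clusters
        p = TSNEParams(out_dim=2, perplexity=10, iterations=50, seed=42)
        a = tsne_reduce(fm, p)
        b = tsne_reduce(fm, p)
        np.testing.assert_array_equal(a.values, b.values)

    def test_invalid_out_dim_rejected(self, two_clusters):
        fm, _ = two_clusters
        with pytest.raises(ValueError):
            tsne_reduce(fm, TSNEParams(out_dim=20, perplexity=10))


class TestReduceFeatures:
    def test_registry_dimensions(self):
        assert REDUCTION_DIMS["densenet121"] == 724
        assert REDUCTION_DIMS["mobilenet"] == 694
        assert REDUCTION_DIMS["vgg19"] == 921

    @pytest.mark.parametrize("backbone,target", [("densenet121", 724), ("vgg19", 921)])
    def test_embed_mode_column_count(self, rng, backbone, target):
        # n < d: the embedding is capped at n-1 live dimensions and
        # zero-padded to the registry width
        p = 1024 if backbone == "densenet121" else 4096
        fm = FeatureMatrix(rng.normal(size=(12, p)))
        red = reduce_features(
            fm, backbone, seed=0, params=TSNEParams(iterations=5, perplexity=3)
        )
        assert red.shape == (12, target)
        assert red.row_ids == fm.row_ids

    def test_select_mode_keeps_highest_variance_columns(self, rng):
        values = rng.normal(size=(10, 1024))
        values[:, 5] *= 50.0  # make one column dominate
        fm = FeatureMatrix(values)
        red = reduce_features(fm, "densenet121", mode="select")
        assert red.shape == (10, 724)
        assert np.any(np.all(red.values == values[:, 5:6], axis=0))

    def test_unknown_backbone_rejected(self, rng):
        fm = FeatureMatrix(rng.normal(size=(5, 10)))
        with pytest.raises(KeyError):
            reduce_features(fm, "alexnet")

    def test_registry_dim_must_be_smaller_than_source(self, rng):
        fm = FeatureMatrix(rng.normal(size=(5, 100)))
        with pytest.raises(ValueError, match="smaller"):
            reduce_features(fm, "densenet121")
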