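import numpy as np
import pytest
import scipy.sparse as sp

from dropstab import (
    GraphCommunityClustering,
    RandomWithinTypeClustering,
    SilhouetteAgglomerative,
    SilhouetteKMeans,
    SimulationParams,
    adjusted_rand_index,
    simulate_baseline,
)
from dropstab.clustering import (
    agglomerative_cluster,
    community_cluster,
    estimate_k,
    kmeans_cluster,
    knn_graph,
    pca_embed,
    preprocess,
    random_clusters,
)


class TestPreprocess:
    def test_equal_depth_cells_only_log1p(self):
        X = np.array([[1, 2, 3], [3, 2, 1], [2, 2, 2]], dtype=float)
        np.testing.assert_allclose(preprocess(X), np.log1p(X))

    def test_doubling_a_cell_leaves_its_row_unchanged(self):
        # scale invariance of depth normalization (median target unaffected
        # by one cell when enough cells surround it)
        rng = np.random.default_rng(0)
        X = rng.poisson(5.0, size=(21, 10)).astype(float)
        X2 = X.copy()
        X2[3] *= 2
        np.testing.assert_allclose(preprocess(X)[3], preprocess(X2)[3])

    def test_zero_cell_left_as_zeros(self):
        X = np.array([[0.0, 0, 0], [1, 2, 3], [4, 5, 6]])
        assert not preprocess(X)[0].any()


class TestPCA:
    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 6))
        emb = pca_embed(X, 6)
        # scores preserve all pairwise distances at full rank
        from scipy.spatial.distance import pdist
        np.testing.assert_allclose(pdist(emb), pdist(X), atol=1e-8)

    def test_components_ordered_by_variance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 10)) * np.arange(1, 11)
        emb = pca_embed(X, 5)
        variances = emb.var(axis=0)
        assert (np.diff(variances) <= 1e-12).all()

    def test_duplicate_cells_map_to_identical_points(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 5))
        X = np.vstack([X, X[0]])
        emb = pca_embed(X, 3)
        np.testing.assert_allclose(emb[0], emb[-1], atol=1e-10)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError, match="n_components"):
            pca_embed(np.ones((5, 4)), 10)


class TestKnnGraph:
    def test_identical_points_are_mutual_neighbors(self):
        X = np.array([[0.0, 0], [0, 0], [10, 10], [10, 10]])
        g = knn_graph(X, n_neighbors=2, weighted=False)
        assert g[0, 1] > 0 and g[1, 0] > 0
        assert g[2, 3] > 0 and g[3, 2] > 0
        assert g[0, 2] == 0

    def test_all_neighbors_gives_complete_graph(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 3))
        g = knn_graph(X, n_neighbors=8, weighted=False)  # self counts as one
        assert (np.asarray(g.todense()) + np.eye(8) > 0).all()

    def test_deterministic_across_calls(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 5))
        a = knn_graph(X, 10)
        b = knn_graph(X, 10)
        assert (a != b).nnz == 0

    def test_weights_in_unit_interval(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 5))
        g = knn_graph(X, 10, weighted=True)
        assert g.data.min() > 0 and g.data.max() <= 1.0

    def test_too_many_neighbors_rejected(self):
        with pytest.raises(ValueError, match="n_neighbors"):
            knn_graph(np.ones((5, 2)), 7)


def _two_cliques(n=8):
    g = np.zeros((2 * n, 2 * n))
    g[:n, :n] = 1
    g[n:, n:] = 1
    np.fill_diagonal(g, 0)
    return sp.csr_matrix(g)


class TestCommunityCluster:
    @pytest.mark.parametrize("method", ["leiden", "louvain"])
    def test_two_disjoint_cliques(self, method):
        labels = community_cluster(_two_cliques(), method, random_state=0)
        assert len(np.unique(labels)) == 2
        assert len(set(labels[:8])) == 1 and len(set(labels[8:])) == 1

    @pytest.mark.parametrize("method", ["leiden", "louvain"])
    def test_same_seed_identical_partition(self, method):
        g = knn_graph(np.random.default_rng(6).normal(size=(60, 4)), 10)
        a = community_cluster(g, method, random_state=99)
        b = community_cluster(g, method, random_state=99)
        np.testing.assert_array_equal(a, b)

    def test_labels_contiguous_from_zero(self):
        labels = community_cluster(_two_cliques(), "leiden", 0)
        assert set(labels) == set(range(labels.max() + 1))

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            community_cluster(sp.csr_matrix((0, 0)), "leiden", 0)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            community_cluster(_two_cliques(), "walktrap", 0)


class TestEstimateK:
    def test_three_blobs_recovered(self, blobs3):
        X, _ = blobs3
        assert estimate_k(X, (2, 8), n_runs=3, random_state=0) == 3
        assert estimate_k(X, (2, 8), random_state=0,
                          method="agglomerative") == 3

    def test_degenerate_range_returns_lower_bound(self, blobs3):
        assert estimate_k(blobs3[0], (2, 2), random_state=0) == 2

    def test_invalid_range_rejected(self, blobs3):
        with pytest.raises(ValueError, match="k_range"):
            estimate_k(blobs3[0], (1, 5), random_state=0)


class TestPartitioners:
    def test_two_blobs_recovered_exactly(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(0, 1, (30, 4)), rng.normal(30, 1, (30, 4))])
        y = np.repeat([0, 1], 30)
        for labels in (kmeans_cluster(X, 2, 0), agglomerative_cluster(X, 2)):
            assert adjusted_rand_index(y, labels) == 1.0

    def test_k_equal_n_gives_singletons(self):
        X = np.random.default_rng(9).normal(size=(6, 3))
        assert len(np.unique(kmeans_cluster(X, 6, 0))) == 6

    def test_k_one_rejected(self):
        X = np.ones((5, 2))
        with pytest.raises(ValueError):
            kmeans_cluster(X, 1, 0)
        with pytest.raises(ValueError):
            agglomerative_cluster(X, 1)


class TestRandomClusters:
    def test_one_cluster_per_type_equals_type_partition(self):
        types = np.array(["a", "a", "b", "b", "c"])
        labels = random_clusters(types, 1, seed=0)
        assert adjusted_rand_index(types, labels) == 1.0

    def test_uniform_within_type_sizes(self):
        types = np.repeat(["a", "b"], 3000)
        labels = random_clusters(types, 3, seed=1)
        for t in ("a", "b"):
            _, counts = np.unique(labels[types == t], return_counts=True)
            assert counts.size == 3
            np.testing.assert_allclose(counts, 1000, atol=120)

    def test_ari_vs_independent_random_partition_near_zero(self):
        types = np.repeat(["a", "b", "c"], 100)
        rng = np.random.default_rng(2)
        aris = []
        for i in range(100):
            a = random_clusters(types, 4, seed=1000 + i)
            b = rng.integers(0, 12, size=types.size)
            aris.append(adjusted_rand_index(a, b))
        assert abs(np.mean(aris)) < 0.02


class TestEstimators:
    @pytest.mark.parametrize("method", ["leiden", "louvain"])
    def test_recovers_separated_types(self, sep3_small, method):
        X = np.asarray(sep3_small.X)
        truth = sep3_small.obs["cell_type"].to_numpy()
        est = GraphCommunityClustering(algorithm=method).fit(X)
        assert adjusted_rand_index(truth, est.labels_) > 0.9

    def test_perfect_structure_recovery_all_algorithms(self, sep3_small):
        """Strongly separated types, zero corruption: every arm finds them."""
        X = np.asarray(sep3_small.X)
        truth = sep3_small.obs["cell_type"].to_numpy()
        for est in (GraphCommunityClustering(algorithm="leiden"),
                    GraphCommunityClustering(algorithm="louvain"),
                    SilhouetteKMeans(n_clusters=3),
                    SilhouetteAgglomerative(n_clusters=3)):
            est.fit(X)
            assert adjusted_rand_index(truth, est.labels_) >= 0.95

    def test_end_to_end_determinism(self, sep3_small):
        X = np.asarray(sep3_small.X)
        a = GraphCommunityClustering(random_state=7).fit(X).labels_
        b = GraphCommunityClustering(random_state=7).fit(X).labels_
        np.testing.assert_array_equal(a, b)

    def test_silhouette_kmeans_estimates_three_types(self, sep3_small):
        X = np.asarray(sep3_small.X)
        est = SilhouetteKMeans(k_range=(2, 8), n_silhouette_runs=3).fit(X)
        assert est.k_estimate_ == 3

    def test_random_within_type_requires_labels(self):
        with pytest.raises(ValueError, match="labels"):
            RandomWithinTypeClustering().fit(np.ones((4, 2)))

    def test_sklearn_param_interface(self):
        est = GraphCommunityClustering(n_neighbors=10)
        assert est.get_params()["n_neighbors"] == 10
        est.set_params(metric="cosine")
        assert est.get_params()["metric"] == "cosine"
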