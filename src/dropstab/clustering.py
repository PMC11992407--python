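"""Clustering arms: graph community detection, K-Means, Agglomerative, random null.

The baseline pipeline mirrors the default single-cell workflow: per-cell
depth normalization to the median total count and log1p, PCA, an exact
k-nearest-neighbor graph with UMAP-style fuzzy connectivity weights, and
Leiden or Louvain community detection at resolution 1.0. Defaults are the
printed pipeline parameters: 15 principal components, 30 neighbors,
Euclidean metric, random_state 12345.

K-Means and Ward Agglomerative clustering run on the same PCA embedding,
with the number of clusters chosen by silhouette score over k in 2..50
(for K-Means the rounded mean of per-run argmaxes over 10 seeded runs).
The random-within-type null assigns each cell uniformly to one of n
clusters of its own cell type, modeling clusters with correct global
structure but no sub-type information.

Everything is exposed both as sklearn-compatible estimators
(:class:`GraphCommunityClustering`, :class:`SilhouetteKMeans`,
:class:`SilhouetteAgglomerative`, :class:`RandomWithinTypeClustering`)
and as thin module-level functions over arrays.
"""

from __future__ import annotations

import logging

import igraph as ig
import leidenalg
import networkx as nx
import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors
from sklearn.utils import check_random_state
from sklearn.utils.validation import check_is_fitted
from umap.umap_ import fuzzy_simplicial_set

logger = logging.getLogger(__name__)

__all__ = [
    "preprocess",
    "pca_embed",
    "knn_graph",
    "community_cluster",
    "estimate_k",
    "kmeans_cluster",
    "agglomerative_cluster",
    "random_clusters",
    "GraphCommunityClustering",
    "SilhouetteKMeans",
    "SilhouetteAgglomerative",
    "RandomWithinTypeClustering",
]

SILHOUETTE_MAX_CELLS = 5000


def preprocess(X) -> np.ndarray:
    """Depth-normalize each cell to the median total count, then log1p.

    All-zero cells are left as zeros (and logged); the transform is
    invariant to rescaling any single cell's counts.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("expression matrix must be nonnegative")
    totals = X.sum(axis=1)
    zero_rows = totals == 0
    if zero_rows.any():
        logger.warning("%d all-zero cells left unnormalized", int(zero_rows.sum()))
    target = np.median(totals[~zero_rows]) if (~zero_rows).any() else 1.0
    factors = np.ones_like(totals)
    factors[~zero_rows] = target / totals[~zero_rows]
    return np.log1p(X * factors[:, None])


def pca_embed(X: np.ndarray, n_components: int = 15,
              random_state: int | None = 12345) -> np.ndarray:
    """Principal-component scores, components by decreasing explained variance."""
    X = np.asarray(X, dtype=float)
    max_rank = min(X.shape)
    if n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds min(n_cells, n_genes)={max_rank}"
        )
    # auto solver: exact SVD on small inputs, seeded randomized SVD at scale
    pca = PCA(n_components=n_components, svd_solver="auto",
              random_state=random_state)
    return pca.fit_transform(X)


def knn_graph(embedding: np.ndarray, n_neighbors: int = 30,
              metric: str = "euclidean", weighted: bool = True,
              random_state: int | None = 12345) -> sp.csr_matrix:
    """Symmetric kNN graph over cells, from exact neighbor search.

    Each cell is linked to its ``n_neighbors`` nearest cells (self
    included, as in the standard single-cell neighborhood routine) and the
    edge set is symmetrized. With ``weighted=True``, edges carry UMAP-style
    fuzzy connectivity weights in (0, 1]; otherwise unit weights.
    """
    embedding = np.asarray(embedding, dtype=float)
    n = embedding.shape[0]
    if n_neighbors >= n + 1:
        raise ValueError("n_neighbors must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=n_neighbors, metric=metric)
    nn.fit(embedding)
    dists, inds = nn.kneighbors(embedding)
    if weighted:
        conn, _, _ = fuzzy_simplicial_set(
            embedding, n_neighbors, check_random_state(random_state), metric,
            knn_indices=inds, knn_dists=dists,
        )
        graph = sp.csr_matrix(conn)
    else:
        rows = np.repeat(np.arange(n), n_neighbors)
        adj = sp.csr_matrix(
            (np.ones(rows.size), (rows, inds.ravel())), shape=(n, n)
        )
        adj = adj.maximum(adj.T)
        adj.setdiag(0)
        adj.eliminate_zeros()
        graph = adj.tocsr()
    return graph


def community_cluster(graph: sp.spmatrix, method: str = "leiden",
                      random_state: int | None = 12345,
                      resolution: float = 1.0) -> np.ndarray:
    """Leiden (igraph) or Louvain (networkx) communities of a weighted graph.

    Returns contiguous integer labels 0..k-1, ordered by first cell
    occurrence; seeded and deterministic.
    """
    graph = sp.csr_matrix(graph)
    n = graph.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    if method == "leiden":
        coo = sp.triu(graph, k=1).tocoo()
        g = ig.Graph(n=n, edges=list(zip(coo.row.tolist(), coo.col.tolist())))
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights=coo.data.tolist(),
            resolution_parameter=resolution,
            seed=random_state if random_state is not None else 0,
        )
        membership = np.asarray(part.membership)
    elif method == "louvain":
        g = nx.from_scipy_sparse_array(graph)
        communities = nx.algorithms.community.louvain_communities(
            g, weight="weight", resolution=resolution, seed=random_state
        )
        membership = np.empty(n, dtype=int)
        for label, members in enumerate(communities):
            membership[list(members)] = label
    else:
        raise ValueError(f"unknown method {method!r}; choose 'leiden' or 'louvain'")
    # relabel contiguously by first occurrence for a canonical form
    _, first = np.unique(membership, return_index=True)
    order = membership[np.sort(first)]
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[m] for m in membership], dtype=int)


def _silhouette(embedding: np.ndarray, labels: np.ndarray,
                random_state: int | None) -> float:
    sample = SILHOUETTE_MAX_CELLS if embedding.shape[0] > SILHOUETTE_MAX_CELLS else None
    return silhouette_score(embedding, labels, sample_size=sample,
                            random_state=random_state)


def estimate_k(embedding: np.ndarray, k_range: tuple[int, int] = (2, 50),
               n_runs: int = 10, random_state: int | None = 12345,
               method: str = "kmeans") -> int:
    """Silhouette-based cluster-number estimate.

    For every k in ``k_range`` fit the partitioner and score the silhouette
    on the embedding; take the argmax. For K-Means this is repeated over
    ``n_runs`` seeded runs and the mean argmax is rounded half-up to an
    integer; Ward agglomerative clustering is deterministic, so a single
    pass suffices.
    """
    embedding = np.asarray(embedding, dtype=float)
    lo, hi = k_range
    hi = min(hi, embedding.shape[0] - 1)
    if lo < 2 or lo > hi:
        raise ValueError(f"invalid k_range ({lo}, {hi}) for {embedding.shape[0]} cells")
    ks = range(lo, hi + 1)
    if lo == hi:
        return lo
    rs = np.random.default_rng(random_state)
    if method == "agglomerative":
        n_runs = 1
    best_ks = []
    for _ in range(n_runs):
        run_seed = int(rs.integers(0, 2**31 - 1))
        scores = []
        for k in ks:
            if method == "kmeans":
                labels = KMeans(n_clusters=k, n_init="auto",
                                random_state=run_seed).fit_predict(embedding)
            elif method == "agglomerative":
                labels = AgglomerativeClustering(n_clusters=k).fit_predict(embedding)
            else:
                raise ValueError(f"unknown method {method!r}")
            scores.append(_silhouette(embedding, labels, run_seed))
        best_ks.append(list(ks)[int(np.argmax(scores))])
    return int(np.floor(np.mean(best_ks) + 0.5))


def kmeans_cluster(embedding: np.ndarray, k: int,
                   random_state: int | None = 12345) -> np.ndarray:
    """Seeded K-Means partition of the embedding into exactly k clusters."""
    if k < 2 or k > embedding.shape[0]:
        raise ValueError("k must lie in [2, n_cells]")
    return KMeans(n_clusters=k, n_init="auto",
                  random_state=random_state).fit_predict(embedding)


def agglomerative_cluster(embedding: np.ndarray, k: int) -> np.ndarray:
    """Deterministic Ward-linkage agglomerative partition into k clusters."""
    if k < 2 or k > embedding.shape[0]:
        raise ValueError("k must lie in [2, n_cells]")
    return AgglomerativeClustering(n_clusters=k).fit_predict(embedding)


def random_clusters(annotation, n_clusters_per_type: int,
                    seed: int | None = None) -> np.ndarray:
    """Uniform random partition within each cell type.

    Cells are assigned independently and uniformly to one of
    ``n_clusters_per_type`` clusters of their own type; clusters of
    different types get disjoint labels, so the global type structure is
    preserved exactly while sub-type assignment is pure noise.
    """
    if n_clusters_per_type < 1:
        raise ValueError("n_clusters_per_type must be >= 1")
    labels = np.asarray(annotation)
    rng = np.random.default_rng(seed)
    out = np.empty(labels.shape[0], dtype=int)
    for offset, cls in enumerate(np.unique(labels)):
        rows = np.flatnonzero(labels == cls)
        out[rows] = offset * n_clusters_per_type + rng.integers(
            0, n_clusters_per_type, size=rows.size
        )
    # contiguous relabeling (some clusters may come out empty by chance)
    _, inv = np.unique(out, return_inverse=True)
    return inv.astype(int)


class GraphCommunityClustering(ClusterMixin, BaseEstimator):
    """Default single-cell clustering: normalize, PCA, kNN graph, communities.

    Parameters default to the printed baseline pipeline: 15 principal
    components, 30 neighbors, Euclidean metric, random_state 12345,
    resolution 1.0. ``algorithm`` selects Leiden or Louvain community
    detection on the fuzzy-weighted kNN graph (``weighted=False`` gives
    the plain unit-weight graph).

    Attributes after :meth:`fit`: ``labels_``, ``n_clusters_``,
    ``embedding_`` (PCA scores) and ``graph_`` (sparse connectivities).
    """

    def __init__(self, algorithm: str = "leiden", n_components: int = 15,
                 n_neighbors: int = 30, metric: str = "euclidean",
                 resolution: float = 1.0, weighted: bool = True,
                 random_state: int | None = 12345):
        self.algorithm = algorithm
        self.n_components = n_components
        self.n_neighbors = n_neighbors
        self.metric = metric
        self.resolution = resolution
        self.weighted = weighted
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X)
        norm = preprocess(X)
        self.embedding_ = pca_embed(norm, self.n_components, self.random_state)
        self.graph_ = knn_graph(self.embedding_, self.n_neighbors, self.metric,
                                self.weighted, self.random_state)
        self.labels_ = community_cluster(self.graph_, self.algorithm,
                                         self.random_state, self.resolution)
        self.n_clusters_ = int(self.labels_.max()) + 1
        self.n_features_in_ = X.shape[1]
        return self

    def rerun_communities(self, random_state: int | None) -> np.ndarray:
        """Re-detect communities on the fitted graph with another seed.

        Normalization, PCA and the exact kNN graph are deterministic, so
        seed-to-seed variability of the pipeline lives entirely in the
        community detection; this supports the 100-rerun variability
        protocol without recomputing the graph.
        """
        check_is_fitted(self, "graph_")
        return community_cluster(self.graph_, self.algorithm, random_state,
                                 self.resolution)


class _PCAClusterBase(ClusterMixin, BaseEstimator):
    def __init__(self, n_components: int = 15, n_clusters: int | None = None,
                 k_range: tuple[int, int] = (2, 50),
                 n_silhouette_runs: int = 10,
                 random_state: int | None = 12345):
        self.n_components = n_components
        self.n_clusters = n_clusters
        self.k_range = k_range
        self.n_silhouette_runs = n_silhouette_runs
        self.random_state = random_state

    _method = ""

    def fit(self, X, y=None):
        X = np.asarray(X)
        norm = preprocess(X)
        self.embedding_ = pca_embed(norm, self.n_components, self.random_state)
        if self.n_clusters is not None:
            self.k_estimate_ = int(self.n_clusters)
        else:
            self.k_estimate_ = estimate_k(
                self.embedding_, self.k_range, self.n_silhouette_runs,
                self.random_state, method=self._method,
            )
        self.labels_ = self._partition(self.embedding_, self.k_estimate_)
        self.n_clusters_ = int(np.unique(self.labels_).size)
        self.n_features_in_ = X.shape[1]
        return self


class SilhouetteKMeans(_PCAClusterBase):
    """K-Means on the PCA embedding with silhouette-selected k.

    When ``n_clusters`` is None, k is the rounded mean of the per-run
    silhouette argmax over ``n_silhouette_runs`` seeded runs across
    ``k_range``.
    """

    _method = "kmeans"

    def _partition(self, embedding, k):
        return kmeans_cluster(embedding, k, self.random_state)


class SilhouetteAgglomerative(_PCAClusterBase):
    """Ward agglomerative clustering on PCA with silhouette-selected k.

    Fully deterministic: repeated fits on the same data give identical
    partitions regardless of random_state.
    """

    _method = "agglomerative"

    def _partition(self, embedding, k):
        return agglomerative_cluster(embedding, k)


class RandomWithinTypeClustering(ClusterMixin, BaseEstimator):
    """Null model: random sub-clusters inside each true cell type.

    ``fit(X, y)`` requires the true type labels ``y``; X is accepted for
    API compatibility and ignored.
    """

    def __init__(self, n_clusters_per_type: int = 1,
                 random_state: int | None = None):
        self.n_clusters_per_type = n_clusters_per_type
        self.random_state = random_state

    def fit(self, X, y=None):
        if y is None:
            raise ValueError("RandomWithinTypeClustering requires type labels y")
        self.labels_ = random_clusters(y, self.n_clusters_per_type,
                                       self.random_state)
        self.n_clusters_ = int(np.unique(self.labels_).size)
        return self
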