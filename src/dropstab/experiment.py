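"""Experiment orchestration: baselines, corruption sweeps, null models.

Protocol: a baseline matrix is simulated (or loaded) once and stored; each
corruption level is applied to that *same* baseline, never cumulatively.
The baseline partition B is the clustering of the uncorrupted matrix with
the default pipeline parameters and seed. Stability of a corrupted-data
partition K is ARI(K, B); quality is homogeneity / completeness /
v-measure (and ARI) against the true simulated cell types.

Each (corruption kind, level, algorithm, parameter combination) cell of a
sweep is run ``runs_per_combination`` times with per-run seeds derived
from the master seed by a stable hash, so a sweep is fully reproducible.
Results come back as a tidy DataFrame, one row per run.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd

from . import metrics
from .clustering import (
    GraphCommunityClustering,
    RandomWithinTypeClustering,
    SilhouetteAgglomerative,
    SilhouetteKMeans,
    agglomerative_cluster,
    kmeans_cluster,
)
from .corruption import add_dropouts, add_noise, downsample_depth

__all__ = [
    "SweepConfig",
    "BaselineResult",
    "derive_seed",
    "apply_corruption",
    "run_baseline",
    "run_sweep",
    "run_random_null",
    "evaluate_external_matrix",
    "RESULT_COLUMNS",
]

#: Tidy result schema: one row per evaluated partition.
RESULT_COLUMNS = [
    "dataset_id", "kind", "level", "run", "algorithm", "config_hash", "seed",
    "status", "ari_vs_baseline", "ari_vs_truth", "homogeneity",
    "completeness", "v_measure", "n_clusters",
]

CORRUPTION_KINDS = ("dropout_expression", "dropout_depth",
                    "noise1", "noise2", "noise3")

DEFAULT_LEVELS = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1))


def derive_seed(master_seed: int, *parts) -> int:
    """Stable per-run seed from the master seed and any context parts.

    SHA-256 over the string rendering keeps seeds collision-free across
    the grid and independent of iteration order; the value fits in 31 bits.
    """
    key = "|".join([str(master_seed), *map(str, parts)])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def apply_corruption(adata: ad.AnnData, kind: str, level: float,
                     seed: int) -> ad.AnnData:
    """Dispatch one corruption operator at one level onto a baseline copy."""
    if kind == "dropout_expression":
        return add_dropouts(adata, f=level, seed=seed)
    if kind == "dropout_depth":
        # level is the corruption intensity; depth factor 1 - level thins reads
        return downsample_depth(adata, depth_factor=1.0 - level, seed=seed)
    if kind in ("noise1", "noise2", "noise3"):
        return add_noise(adata, model=int(kind[-1]), p=level, seed=seed)
    raise ValueError(f"unknown corruption kind {kind!r}; "
                     f"choose from {CORRUPTION_KINDS}")


def _make_estimator(algorithm: str, random_state: int, **overrides):
    if algorithm in ("leiden", "louvain"):
        return GraphCommunityClustering(algorithm=algorithm,
                                        random_state=random_state, **overrides)
    if algorithm == "kmeans":
        return SilhouetteKMeans(random_state=random_state, **overrides)
    if algorithm == "agglomerative":
        return SilhouetteAgglomerative(random_state=random_state, **overrides)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _evaluate(labels: np.ndarray, baseline: np.ndarray | None,
              truth: np.ndarray) -> dict:
    row = {
        "ari_vs_truth": metrics.adjusted_rand_index(truth, labels),
        "homogeneity": metrics.homogeneity(truth, labels),
        "completeness": metrics.completeness(truth, labels),
        "v_measure": metrics.v_measure(truth, labels),
        "n_clusters": int(np.unique(labels).size),
    }
    row["ari_vs_baseline"] = (
        metrics.adjusted_rand_index(baseline, labels)
        if baseline is not None else np.nan
    )
    return row


@dataclass
class BaselineResult:
    """Baseline partition B and the seed-to-seed variability around it."""

    labels: np.ndarray
    variability_ari: np.ndarray
    estimator: object

    @property
    def n_clusters(self) -> int:
        return int(np.unique(self.labels).size)


def run_baseline(adata: ad.AnnData, algorithm: str = "leiden",
                 n_variability_runs: int = 100,
                 random_state: int = 12345,
                 master_seed: int = 0, **estimator_kwargs) -> BaselineResult:
    """Cluster the uncorrupted matrix and quantify algorithmic variability.

    The baseline partition B uses the default pipeline seed; the matrix is
    then re-clustered ``n_variability_runs`` times with distinct derived
    seeds and each re-run is scored by ARI against B. For the graph
    pipelines only community detection consumes the seed (normalization,
    PCA and exact kNN search are deterministic), so the fitted graph is
    reused across re-runs; deterministic Agglomerative re-runs score 1.0
    by construction.
    """
    X = np.asarray(adata.X)
    est = _make_estimator(algorithm, random_state, **estimator_kwargs).fit(X)
    base = est.labels_
    seeds = [derive_seed(master_seed, "variability", algorithm, i)
             for i in range(n_variability_runs)]
    aris = np.empty(n_variability_runs)
    for i, s in enumerate(seeds):
        if isinstance(est, GraphCommunityClustering):
            labels = est.rerun_communities(s)
        elif isinstance(est, SilhouetteKMeans):
            # refit K-Means with the new seed on the fitted embedding
            labels = kmeans_cluster(est.embedding_, est.k_estimate_, s)
        else:  # deterministic agglomerative
            labels = agglomerative_cluster(est.embedding_, est.k_estimate_)
        aris[i] = metrics.adjusted_rand_index(base, labels)
    return BaselineResult(labels=base, variability_ari=aris, estimator=est)


@dataclass
class SweepConfig:
    """Grid definition for a corruption sweep."""

    kinds: Sequence[str] = ("dropout_expression",)
    levels: Sequence[float] = DEFAULT_LEVELS
    algorithms: Sequence[str] = ("leiden", "louvain")
    runs_per_combination: int = 10
    master_seed: int = 0
    dataset_id: str = "dataset"
    #: optional pipeline-parameter grid, e.g. {"n_neighbors": [5, 30, 100]}
    param_grid: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.kinds or not self.levels or not self.algorithms:
            raise ValueError("kinds, levels and algorithms must be non-empty")
        for lv in self.levels:
            if not 0.0 <= lv <= 1.0:
                raise ValueError("corruption levels must lie in [0, 1]")


def _param_combos(grid: dict):
    if not grid:
        yield {}
        return
    keys = sorted(grid)
    for values in itertools.product(*(grid[k] for k in keys)):
        yield dict(zip(keys, values))


def run_sweep(adata: ad.AnnData, config: SweepConfig,
              baselines: dict[str, BaselineResult] | None = None) -> pd.DataFrame:
    """Corrupt, cluster and evaluate over the full grid.

    ``baselines`` may carry precomputed :func:`run_baseline` results per
    algorithm; missing ones are computed here (with 0 variability re-runs,
    which are a separate protocol). A failing grid cell is recorded with
    ``status='error'`` rather than dropped.
    """
    truth = adata.obs["cell_type"].to_numpy()
    baselines = dict(baselines or {})
    for alg in config.algorithms:
        if alg not in baselines:
            baselines[alg] = run_baseline(adata, alg, n_variability_runs=0,
                                          master_seed=config.master_seed)
    rows = []
    for kind in config.kinds:
        for level in config.levels:
            corrupted_cache: dict[int, ad.AnnData] = {}
            for alg, combo in itertools.product(config.algorithms,
                                                _param_combos(config.param_grid)):
                combo_hash = hashlib.sha256(
                    repr(sorted(combo.items())).encode()).hexdigest()[:8]
                for run in range(config.runs_per_combination):
                    seed = derive_seed(config.master_seed, config.dataset_id,
                                       kind, level, alg, combo_hash, run)
                    corr_seed = derive_seed(config.master_seed,
                                            config.dataset_id, kind, level, run)
                    row = {
                        "dataset_id": config.dataset_id, "kind": kind,
                        "level": level, "run": run, "algorithm": alg,
                        "config_hash": combo_hash, "seed": seed, "status": "ok",
                    }
                    try:
                        if corr_seed not in corrupted_cache:
                            corrupted_cache[corr_seed] = apply_corruption(
                                adata, kind, level, corr_seed)
                        corrupted = corrupted_cache[corr_seed]
                        est = _make_estimator(alg, seed, **combo)
                        est.fit(np.asarray(corrupted.X))
                        row.update(_evaluate(est.labels_,
                                             baselines[alg].labels, truth))
                    except Exception as exc:  # recorded, not dropped
                        row["status"] = f"error: {exc}"
                        row.update({k: np.nan for k in
                                    ("ari_vs_baseline", "ari_vs_truth",
                                     "homogeneity", "completeness",
                                     "v_measure", "n_clusters")})
                    rows.append(row)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def run_random_null(adata: ad.AnnData, cluster_counts: Sequence[int],
                    n_seeds: int = 100,
                    baseline: BaselineResult | None = None,
                    master_seed: int = 0) -> pd.DataFrame:
    """Evaluate per-type random partitions as the non-informative reference.

    ``cluster_counts`` is the set of per-type cluster numbers to try,
    conventionally the cluster counts the baseline pipeline produced
    across all corruption levels of the sweep.
    """
    truth = adata.obs["cell_type"].to_numpy()
    base_labels = baseline.labels if baseline is not None else None
    rows = []
    for n in cluster_counts:
        for i in range(n_seeds):
            seed = derive_seed(master_seed, "random_null", n, i)
            est = RandomWithinTypeClustering(n_clusters_per_type=n,
                                             random_state=seed)
            est.fit(None, truth)
            row = {"dataset_id": "random_null", "kind": "random",
                   "level": float(n), "run": i, "algorithm": "random",
                   "config_hash": "", "seed": seed, "status": "ok"}
            row.update(_evaluate(est.labels_, base_labels, truth))
            rows.append(row)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def evaluate_external_matrix(matrix, baseline: BaselineResult, truth,
                             algorithm: str = "leiden",
                             random_state: int = 12345,
                             cell_ids=None, **estimator_kwargs) -> pd.Series:
    """Push any externally produced matrix through the cluster->evaluate path.

    Intended for externally imputed matrices: the same pipeline and
    metrics apply, so results are directly comparable with the sweep.
    ``cell_ids``, when given, must match the baseline's cell set in order.
    """
    if isinstance(matrix, ad.AnnData):
        if cell_ids is None:
            cell_ids = list(matrix.obs_names)
        matrix = np.asarray(matrix.X)
    matrix = np.asarray(matrix)
    if np.any(matrix < 0):
        raise ValueError("external matrix must be nonnegative")
    if matrix.shape[0] != baseline.labels.shape[0]:
        raise ValueError("external matrix does not match the baseline cell set")
    if isinstance(truth, pd.Series):
        if cell_ids is not None and list(truth.index) != list(cell_ids):
            raise ValueError("cell ids do not match the truth annotation")
        truth = truth.to_numpy()
    est = _make_estimator(algorithm, random_state, **estimator_kwargs)
    est.fit(matrix)
    row = {"dataset_id": "external", "kind": "external", "level": np.nan,
           "run": 0, "algorithm": algorithm, "config_hash": "",
           "seed": random_state, "status": "ok"}
    row.update(_evaluate(est.labels_, baseline.labels, np.asarray(truth)))
    return pd.Series(row)[RESULT_COLUMNS]
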