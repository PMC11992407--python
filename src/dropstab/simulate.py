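"""Synthetic baseline count matrices with cell-type tree structure.

The generator emulates a two-step single-cell simulation: biological
structure first (cell types on a divergence tree, per-cell heterogeneity),
technical corruption later (see :mod:`dropstab.corruption`). Counts follow
a hierarchical gamma--negative-binomial model:

* per-gene baseline means ``mu_g ~ Gamma(shape, rate)``;
* per-gene log-fold effects propagated down the cell-type tree, each edge
  adding ``Normal(0, sqrt(branch_weight * type_effect_scale))``, so leaf
  profiles diverge in proportion to tree distance;
* per-cell library-size factors ``L_i ~ LogNormal(location, scale)``;
* counts ``x_ig ~ NB(mean = L_i * mu_g * exp(effect_{leaf(i),g}),
  var = mean + dispersion * mean^2)``.

Defaults keep the uncorrupted matrix denser than the smallest corruption
level of the standard sparsity grid (f = 0.1), so every dropout level in
the grid is reachable from the baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .tree import CellTypeTree, preset_tree

__all__ = ["SimulationParams", "simulate_baseline", "zero_fraction"]


@dataclass
class SimulationParams:
    """Parameters of the hierarchical count simulator.

    ``type_effect_scale`` multiplies branch weights when drawing log-fold
    effects; 0 removes all between-type structure. ``dispersion`` is the
    negative-binomial overdispersion (variance = m + dispersion * m^2).
    """

    n_cells: int = 1000
    n_genes: int = 2000
    tree: CellTypeTree = field(default_factory=lambda: preset_tree("separate3"))
    library_size_location: float = 0.0
    library_size_scale: float = 0.25
    gene_mean_shape: float = 3.0
    gene_mean_rate: float = 0.3
    dispersion: float = 0.2
    type_effect_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise ValueError("n_cells and n_genes must be positive")
        for name in ("gene_mean_shape", "gene_mean_rate", "dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.library_size_scale < 0:
            raise ValueError("library_size_scale must be nonnegative")
        if self.type_effect_scale < 0:
            raise ValueError("type_effect_scale must be nonnegative")
        if not self.tree.leaves:
            raise ValueError("tree has no leaves")


def _leaf_effects(tree: CellTypeTree, n_genes: int, scale: float,
                  rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-gene log-fold effect of each leaf, accumulated along the tree."""
    effects: dict[str, np.ndarray] = {tree.root: np.zeros(n_genes)}
    # preorder: parents before children
    pending = [n for n in tree.nodes if n != tree.root]
    order: list[str] = [tree.root]
    while pending:
        for n in list(pending):
            if tree.parent[n] in order:
                order.append(n)
                pending.remove(n)
    for node in order[1:]:
        sd = np.sqrt(tree.branch_weight.get(node, 0.0) * scale)
        effects[node] = effects[tree.parent[node]] + rng.normal(0.0, sd, n_genes)
    return {leaf: effects[leaf] for leaf in tree.leaves}


def simulate_baseline(params: SimulationParams) -> ad.AnnData:
    """Simulate an uncorrupted labeled count matrix.

    Returns an :class:`anndata.AnnData` of shape ``n_cells x n_genes`` with
    integer counts, true leaf labels in ``obs["cell_type"]`` (plus the
    parent type in ``obs["cell_group"]`` for nested designs) and a
    provenance record in ``uns["provenance"]``. Identical parameters,
    including the seed, give bitwise-identical output.
    """
    rng = np.random.default_rng(params.seed)
    tree = params.tree
    leaves = sorted(tree.leaves)

    fractions = np.array([tree.cell_fractions[l] for l in leaves])
    counts_per_leaf = np.floor(params.n_cells * fractions).astype(int)
    # distribute the rounding remainder to the largest fractional parts
    rem = params.n_cells - counts_per_leaf.sum()
    frac_part = params.n_cells * fractions - np.floor(params.n_cells * fractions)
    for i in np.argsort(-frac_part)[:rem]:
        counts_per_leaf[i] += 1
    labels = np.repeat(leaves, counts_per_leaf)

    mu = rng.gamma(params.gene_mean_shape, 1.0 / params.gene_mean_rate,
                   params.n_genes)
    effects = _leaf_effects(tree, params.n_genes, params.type_effect_scale, rng)
    lib = rng.lognormal(params.library_size_location, params.library_size_scale,
                        params.n_cells)

    X = np.empty((params.n_cells, params.n_genes), dtype=np.int64)
    nb_n = 1.0 / params.dispersion
    for leaf in leaves:
        rows = np.flatnonzero(labels == leaf)
        if rows.size == 0:
            continue
        mean = lib[rows, None] * (mu * np.exp(effects[leaf]))[None, :]
        # NB(mean m, var m + phi m^2) == Poisson-Gamma mixture
        p = nb_n / (nb_n + mean)
        X[rows] = rng.negative_binomial(nb_n, p)

    obs = pd.DataFrame(
        {"cell_type": pd.Categorical(labels)},
        index=[f"cell{i}" for i in range(params.n_cells)],
    )
    if any(tree.depth(l) > 1 for l in leaves):
        obs["cell_group"] = pd.Categorical([tree.group_of(l) for l in labels])
    var = pd.DataFrame(index=[f"gene{j}" for j in range(params.n_genes)])
    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.uns["provenance"] = [
        f"simulate_baseline(n_cells={params.n_cells}, n_genes={params.n_genes}, "
        f"leaves={len(leaves)}, seed={params.seed})"
    ]
    adata.uns["tree_newick"] = tree.to_newick()
    return adata


def zero_fraction(matrix) -> float:
    """Fraction of zero entries of a matrix (AnnData or array-like)."""
    X = matrix.X if isinstance(matrix, ad.AnnData) else np.asarray(matrix)
    if hasattr(X, "toarray") and not isinstance(X, np.ndarray):  # sparse
        total = X.shape[0] * X.shape[1]
        if total == 0:
            raise ValueError("empty matrix")
        return 1.0 - X.count_nonzero() / total
    X = np.asarray(X)
    if X.size == 0:
        raise ValueError("empty matrix")
    return float(np.count_nonzero(X == 0) / X.size)
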