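"""Cluster quality and stability metrics from the contingency table.

Quality compares a clustering K with the true classes C:

* homogeneity   eta   = 1 - H(C|K) / H(C)   (1 if H(C) = 0),
* completeness  gamma = 1 - H(K|C) / H(K)   (1 if H(K) = 0),
* v-measure     V_beta = (1 + beta) * eta * gamma / (beta * eta + gamma),

with entropies in nats computed from the classes x clusters contingency
table (the ratios make the base irrelevant). Stability compares two
partitions of the same cells by pair agreement:

* Rand index RI = (n_TP + n_TN) / n_pairs over all n(n-1)/2 cell pairs,
* adjusted Rand index ARI = (RI - E[RI]) / (max RI - E[RI]), chance-
  adjusted under the permutation model with fixed marginals.

All functions accept two label sequences over the same cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ContingencyTable",
    "pairwise_contingency",
    "homogeneity",
    "completeness",
    "v_measure",
    "rand_index",
    "adjusted_rand_index",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """Classes x clusters joint counts with marginals."""

    counts: np.ndarray
    row_labels: np.ndarray
    col_labels: np.ndarray

    @property
    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def _check_labels(a, b) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(a, pd.Series) and isinstance(b, pd.Series):
        if not a.index.equals(b.index):
            if set(a.index) != set(b.index):
                raise ValueError("label sequences cover different cell sets")
            b = b.reindex(a.index)
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label sequences must be 1-d and of equal length")
    if a.size == 0:
        raise ValueError("empty label sequences")
    return a, b


def pairwise_contingency(a, b) -> ContingencyTable:
    """Exact classes x clusters contingency table of two labelings."""
    a, b = _check_labels(a, b)
    rows, ai = np.unique(a, return_inverse=True)
    cols, bi = np.unique(b, return_inverse=True)
    counts = np.zeros((rows.size, cols.size), dtype=np.int64)
    np.add.at(counts, (ai, bi), 1)
    return ContingencyTable(counts=counts, row_labels=rows, col_labels=cols)


def _entropy(counts: np.ndarray, n: int) -> float:
    """Shannon entropy in nats; zero-count cells contribute 0."""
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def _conditional_entropy(table: np.ndarray, n: int) -> float:
    """H(row | col) = -sum_ij (n_ij/n) log(n_ij / n_.j)."""
    col = table.sum(axis=0)
    h = 0.0
    for j in range(table.shape[1]):
        if col[j] == 0:
            continue
        nz = table[:, j][table[:, j] > 0]
        h -= float((nz / n * np.log(nz / col[j])).sum())
    return h


def homogeneity(truth, pred) -> float:
    """1 - H(C|K)/H(C): 1 iff every cluster holds a single class."""
    t = pairwise_contingency(truth, pred)
    h_c = _entropy(t.row_marginals, t.n)
    if h_c == 0.0:
        return 1.0
    return 1.0 - _conditional_entropy(t.counts, t.n) / h_c


def completeness(truth, pred) -> float:
    """1 - H(K|C)/H(K): 1 iff every class sits in a single cluster."""
    return homogeneity(pred, truth)


def v_measure(truth, pred, beta: float = 1.0) -> float:
    """Weighted harmonic combination of homogeneity and completeness.

    ``beta = 1`` weighs the two equally; the value is 0 whenever either
    component is 0 (the defined limit of the ratio).
    """
    h = homogeneity(truth, pred)
    c = completeness(truth, pred)
    if h == 0.0 or c == 0.0:
        return 0.0
    return (1.0 + beta) * h * c / (beta * h + c)


def _comb2(x: np.ndarray) -> np.ndarray:
    x = x.astype(np.float64)
    return x * (x - 1.0) / 2.0


def rand_index(a, b) -> float:
    """Fraction of cell pairs on which two partitions agree."""
    t = pairwise_contingency(a, b)
    n = t.n
    if n < 2:
        raise ValueError("rand index needs at least 2 cells")
    pairs = n * (n - 1) / 2.0
    same_both = _comb2(t.counts).sum()                      # n_TP
    same_a = _comb2(t.row_marginals).sum()
    same_b = _comb2(t.col_marginals).sum()
    diff_both = pairs - same_a - same_b + same_both         # n_TN
    return float((same_both + diff_both) / pairs)


def adjusted_rand_index(a, b) -> float:
    """Chance-adjusted pair agreement between two partitions.

    Under the permutation model with the observed marginals, the expected
    pair-agreement index is subtracted and the result rescaled so that a
    random partition scores ~0 and identical partitions score 1. When both
    partitions are trivial (each a single cluster or all singletons) the
    0/0 form is defined as 1.0.
    """
    t = pairwise_contingency(a, b)
    n = t.n
    if n < 2:
        raise ValueError("adjusted rand index needs at least 2 cells")
    pairs = n * (n - 1) / 2.0
    index = _comb2(t.counts).sum()
    sum_a = _comb2(t.row_marginals).sum()
    sum_b = _comb2(t.col_marginals).sum()
    expected = sum_a * sum_b / pairs
    maximum = (sum_a + sum_b) / 2.0
    if maximum == expected:
        logger.info("degenerate partitions in ARI (max == expected); returning 1.0")
        return 1.0
    return float((index - expected) / (maximum - expected))
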