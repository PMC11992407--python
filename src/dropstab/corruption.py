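"""Corruption operators: dropout injection, depth downsampling, noise.

All operators are sklearn-style transformers over dense cells x genes
arrays, plus thin module-level functions that also accept
:class:`anndata.AnnData`. Every operator is seeded, preserves shape and
nonnegativity, and is always applied to the stored uncorrupted baseline,
never cumulatively across levels.

Dropout injection (:class:`ExpressionDropout`) is calibrated per cell type
to an exact target zero fraction ``f``: within each class, nonzero entries
are zeroed by weighted sampling without replacement, low values being more
likely to drop. Depth downsampling (:class:`DepthDownsampling`) is binomial
thinning of counts, emulating reduced sequencing depth. Three noise models
corrupt each entry independently with probability ``p``:

1. additive ``Normal(0, sigma1)`` (absolute value taken afterwards);
2. additive ``Normal(mu_g, sigma_g)`` of that gene (absolute value);
3. replacement with another expression value of the same cell.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ExpressionDropout",
    "DepthDownsampling",
    "AdditiveGaussianNoise",
    "GenewiseGaussianNoise",
    "SwapNoise",
    "add_dropouts",
    "downsample_depth",
    "add_noise",
    "DROPOUT_WEIGHTS",
]


def _weight_exp_mean(values: np.ndarray, class_mean: float) -> np.ndarray:
    """log-weight exp(-x / x_bar): low values drop preferentially."""
    return -values / class_mean


def _weight_exp_sq(values: np.ndarray, class_mean: float) -> np.ndarray:
    return -((values / class_mean) ** 2)


def _weight_rank_inverse(values: np.ndarray, class_mean: float) -> np.ndarray:
    order = np.argsort(np.argsort(values))
    return -np.log1p(order.astype(float))


#: Pluggable dropout weight functions; each returns *log* weights.
DROPOUT_WEIGHTS = {
    "exp_mean": _weight_exp_mean,
    "exp_sq": _weight_exp_sq,
    "rank_inverse": _weight_rank_inverse,
}


def _as_array(matrix):
    if isinstance(matrix, ad.AnnData):
        X = matrix.X
        return np.asarray(X.toarray() if hasattr(X, "toarray") else X)
    return np.asarray(matrix)


def _wrap_like(template, X: np.ndarray, note: str):
    if isinstance(template, ad.AnnData):
        out = template.copy()
        out.X = X
        out.uns.setdefault("provenance", [])
        out.uns["provenance"] = list(out.uns["provenance"]) + [note]
        return out
    return X


class ExpressionDropout(TransformerMixin, BaseEstimator):
    """Inject expression-weighted dropouts to reach a target sparsity.

    Within each class (cell type), nonzero entries are zeroed by weighted
    sampling without replacement until the class's zero fraction reaches
    ``target_sparsity`` (entry count rounded half-up). The default weight
    ``exp(-x / x_bar_class)``, with ``x_bar_class`` the class mean of the
    nonzero entries, drops low values preferentially. Existing zeros are
    never un-zeroed; surviving entries keep their values. A class already
    sparser than the target is left unchanged with a warning.

    Parameters
    ----------
    target_sparsity : float in [0, 1]
        Target fraction of zero entries per class.
    weight : str or callable
        One of :data:`DROPOUT_WEIGHTS` or a callable
        ``(nonzero_values, class_mean) -> log_weights``.
    random_state : int or None
        Seed for the weighted sampling.
    """

    def __init__(self, target_sparsity: float = 0.5, weight="exp_mean",
                 random_state: int | None = None):
        self.target_sparsity = target_sparsity
        self.weight = weight
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X)
        if not 0.0 <= self.target_sparsity <= 1.0:
            raise ValueError("target_sparsity must lie in [0, 1]")
        if np.any(X < 0):
            raise ValueError("expression matrix must be nonnegative")
        if y is None:
            y = np.zeros(X.shape[0], dtype=int)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("annotation must cover every cell")
        self.classes_ = np.unique(y)
        self._labels = y
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "classes_")
        X = np.asarray(X)
        if X.shape[0] != self._labels.shape[0]:
            raise ValueError("transform expects the matrix passed to fit")
        out = X.copy()
        rng = np.random.default_rng(self.random_state)
        log_w = (DROPOUT_WEIGHTS[self.weight]
                 if isinstance(self.weight, str) else self.weight)
        f = self.target_sparsity
        for cls in self.classes_:
            rows = np.flatnonzero(self._labels == cls)
            block = out[rows]
            total = block.size
            nz_r, nz_c = np.nonzero(block)
            current_zeros = total - nz_r.size
            target_zeros = int(np.floor(f * total + 0.5))
            n_drop = target_zeros - current_zeros
            if n_drop <= 0:
                if n_drop < 0:
                    warnings.warn(
                        f"class {cls!r} already has zero fraction "
                        f"{current_zeros / total:.3f} > target {f:.3f}; "
                        "left unchanged (zeros cannot be removed)",
                        stacklevel=2,
                    )
                continue
            values = block[nz_r, nz_c].astype(float)
            lw = log_w(values, float(values.mean()))
            # Gumbel top-k == weighted sampling without replacement
            keys = lw + rng.gumbel(size=lw.shape)
            drop = np.argpartition(-keys, n_drop - 1)[:n_drop]
            block[nz_r[drop], nz_c[drop]] = 0
            out[rows] = block
        return out


class DepthDownsampling(TransformerMixin, BaseEstimator):
    """Binomial thinning of counts: each count x becomes Binomial(x, q).

    Emulates reduced sequencing depth; the expected total count is
    ``depth_factor`` times the original. Requires an integer-valued matrix.
    """

    def __init__(self, depth_factor: float = 1.0, random_state: int | None = None):
        self.depth_factor = depth_factor
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X)
        if not 0.0 < self.depth_factor <= 1.0:
            raise ValueError("depth_factor must lie in (0, 1]")
        if np.any(X < 0):
            raise ValueError("expression matrix must be nonnegative")
        if not np.allclose(X, np.round(X)):
            raise ValueError("binomial thinning is defined on integer counts")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = np.asarray(X)
        if self.depth_factor == 1.0:
            return X.copy()
        rng = np.random.default_rng(self.random_state)
        return rng.binomial(np.round(X).astype(np.int64), self.depth_factor)


class _NoiseBase(TransformerMixin, BaseEstimator):
    def __init__(self, p: float = 0.1, random_state: int | None = None):
        self.p = p
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X)
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        self._fit_stats(X)
        self.n_features_in_ = X.shape[1]
        return self

    def _fit_stats(self, X):  # pragma: no cover - overridden
        pass

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = np.asarray(X)
        if self.p == 0.0:
            return X.copy()
        rng = np.random.default_rng(self.random_state)
        mask = rng.random(X.shape) < self.p
        return self._apply(X, mask, rng)


class AdditiveGaussianNoise(_NoiseBase):
    """Noise model 1: add Normal(0, sigma1), then take the absolute value.

    ``sigma1`` defaults to 0.1 times the standard deviation of the nonzero
    entries of the matrix seen at fit time, a deliberately light systematic
    perturbation.
    """

    def __init__(self, p: float = 0.1, sigma1: float | None = None,
                 random_state: int | None = None):
        super().__init__(p=p, random_state=random_state)
        self.sigma1 = sigma1

    def _fit_stats(self, X):
        if self.sigma1 is not None:
            self.sigma1_ = float(self.sigma1)
        else:
            nz = X[X != 0]
            self.sigma1_ = 0.1 * float(nz.std()) if nz.size else 0.0

    def _apply(self, X, mask, rng):
        out = X.astype(float, copy=True)
        noise = rng.normal(0.0, self.sigma1_, int(mask.sum()))
        out[mask] = np.abs(out[mask] + noise)
        return out


class GenewiseGaussianNoise(_NoiseBase):
    """Noise model 2: add Normal(mu_g, sigma_g) of the entry's gene, abs value.

    The per-gene mean and standard deviation are computed on the matrix
    seen at fit time (the uncorrupted input).
    """

    def _fit_stats(self, X):
        self.gene_mean_ = X.mean(axis=0)
        self.gene_std_ = X.std(axis=0)

    def _apply(self, X, mask, rng):
        out = X.astype(float, copy=True)
        rows, cols = np.nonzero(mask)
        noise = rng.normal(self.gene_mean_[cols], self.gene_std_[cols])
        out[rows, cols] = np.abs(out[rows, cols] + noise)
        return out


class SwapNoise(_NoiseBase):
    """Noise model 3: replace an entry with another value of the same cell.

    Each selected entry is replaced by the value at a uniformly chosen
    *other* position of the same cell (row), read from the original matrix.
    Random, expression-agnostic noise.
    """

    def _fit_stats(self, X):
        pass

    def _apply(self, X, mask, rng):
        out = X.copy()
        rows, cols = np.nonzero(mask)
        n_genes = X.shape[1]
        other = rng.integers(0, n_genes - 1, size=rows.size)
        other += other >= cols  # skip the entry's own column
        out[rows, cols] = X[rows, other]
        return out


_NOISE_MODELS = {1: AdditiveGaussianNoise, 2: GenewiseGaussianNoise, 3: SwapNoise}


def add_dropouts(matrix, annotation=None, f: float = 0.5,
                 seed: int | None = None, weight="exp_mean"):
    """Expression-weighted dropout injection calibrated to sparsity ``f``.

    ``matrix`` may be an AnnData (labels read from ``obs["cell_type"]``
    unless ``annotation`` is given) or an array with ``annotation`` the
    per-cell class labels.
    """
    X = _as_array(matrix)
    if annotation is None and isinstance(matrix, ad.AnnData):
        annotation = matrix.obs["cell_type"].to_numpy()
    tr = ExpressionDropout(target_sparsity=f, weight=weight, random_state=seed)
    out = tr.fit(X, annotation).transform(X)
    return _wrap_like(matrix, out, f"add_dropouts(f={f}, seed={seed})")


def downsample_depth(matrix, depth_factor: float, seed: int | None = None):
    """Binomial thinning of every count with success probability ``depth_factor``."""
    X = _as_array(matrix)
    tr = DepthDownsampling(depth_factor=depth_factor, random_state=seed)
    out = tr.fit(X).transform(X)
    return _wrap_like(matrix, out,
                      f"downsample_depth(depth_factor={depth_factor}, seed={seed})")


def add_noise(matrix, model: int, p: float, seed: int | None = None, **kwargs):
    """Apply noise model 1, 2 or 3 with per-entry corruption probability ``p``."""
    if model not in _NOISE_MODELS:
        raise ValueError(f"unknown noise model {model!r}; choose from 1, 2, 3")
    X = _as_array(matrix)
    tr = _NOISE_MODELS[model](p=p, random_state=seed, **kwargs)
    out = tr.fit(X).transform(X)
    return _wrap_like(matrix, out, f"add_noise(model={model}, p={p}, seed={seed})")
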