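"""Readers and writers for count matrices, labels and trees.

Matrices go to MatrixMarket (``matrix.mtx``) with sidecar ``cells.txt`` /
``genes.txt`` identifier lists, or to dense CSV for small fixtures; cell
annotations to 2-column TSV (cell_id, label); trees to Newick. A small
manifest type lets real datasets (e.g. exported 10x / Drop-seq count
tables with a cell-line label column) flow through the same evaluation
path as simulated data. No downloading is ever performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .simulate import zero_fraction

logger = logging.getLogger(__name__)

__all__ = [
    "write_expression", "read_expression",
    "write_labels", "read_labels",
    "write_expression_csv", "read_expression_csv",
    "DatasetManifest", "load_counts",
]


def write_expression(adata: ad.AnnData, directory) -> None:
    """Write an AnnData's matrix as MTX plus cell/gene id sidecars and labels."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    X = adata.X
    mat = sp.csr_matrix(X) if not sp.issparse(X) else X
    if np.allclose(mat.data, np.round(mat.data)):
        mat = mat.astype(np.int64)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), mat)
    (directory / "cells.txt").write_text("\n".join(adata.obs_names) + "\n")
    (directory / "genes.txt").write_text("\n".join(adata.var_names) + "\n")
    if "cell_type" in adata.obs:
        write_labels(adata.obs["cell_type"], directory / "labels.tsv")


def read_expression(directory) -> ad.AnnData:
    """Read the MTX + sidecar layout written by :func:`write_expression`."""
    directory = Path(directory)
    mat = sp.csr_matrix(scipy.io.mmread(str(directory / "matrix.mtx")))
    cells = (directory / "cells.txt").read_text().splitlines()
    genes = (directory / "genes.txt").read_text().splitlines()
    X = np.asarray(mat.todense())
    if X.shape != (len(cells), len(genes)):
        raise ValueError("matrix shape does not match identifier sidecars")
    adata = ad.AnnData(X=X, obs=pd.DataFrame(index=cells),
                       var=pd.DataFrame(index=genes))
    labels_path = directory / "labels.tsv"
    if labels_path.exists():
        labels = read_labels(labels_path)
        adata.obs["cell_type"] = pd.Categorical(labels.reindex(cells))
    return adata


def write_labels(labels: pd.Series, path) -> None:
    """2-column TSV: cell_id, label."""
    df = pd.DataFrame({"cell_id": labels.index, "label": np.asarray(labels)})
    df.to_csv(path, sep="\t", index=False)


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"cell_id", "label"} <= set(df.columns):
        raise ValueError("label file must have cell_id and label columns")
    return pd.Series(df["label"].to_numpy(), index=df["cell_id"].to_numpy(),
                     name="label")


def write_expression_csv(adata: ad.AnnData, path) -> None:
    """Dense CSV (cells as rows), for small fixtures only."""
    X = adata.X
    X = np.asarray(X.todense() if sp.issparse(X) else X)
    pd.DataFrame(X, index=adata.obs_names,
                 columns=adata.var_names).to_csv(path)


def read_expression_csv(path, label_series: pd.Series | None = None) -> ad.AnnData:
    df = pd.read_csv(path, index_col=0)
    adata = ad.AnnData(X=df.to_numpy(),
                       obs=pd.DataFrame(index=df.index.astype(str)),
                       var=pd.DataFrame(index=df.columns.astype(str)))
    if label_series is not None:
        adata.obs["cell_type"] = pd.Categorical(
            label_series.reindex(adata.obs_names))
    return adata


@dataclass
class DatasetManifest:
    """Description of a locally available real count dataset.

    ``path`` points at an MTX sidecar directory (format ``mtx``) or a
    dense CSV (format ``csv``); ``labels_path`` at the cell-label TSV.
    ``expected_zero_fraction``, when given, is validated against the
    loaded matrix within +/- 0.005 — a checksum-style sanity check against
    loading the wrong export.
    """

    path: str | Path
    format: str = "mtx"
    labels_path: str | Path | None = None
    label_column: str = "label"
    expected_zero_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.format not in ("mtx", "csv"):
            raise ValueError(f"unsupported format {self.format!r}")


def load_counts(manifest: DatasetManifest) -> ad.AnnData:
    """Load a real count matrix plus labels through the common path.

    The matrix must be nonnegative; its zero fraction is logged (real
    datasets carry their native sparsity as the corruption baseline, so a
    dropout target below it is a warned no-op downstream).
    """
    path = Path(manifest.path)
    if not path.exists():
        raise FileNotFoundError(f"dataset path {path} does not exist")
    if manifest.format == "mtx":
        adata = read_expression(path)
    else:
        adata = read_expression_csv(path)
    if manifest.labels_path is not None:
        labels = read_labels(manifest.labels_path)
        missing = set(adata.obs_names) - set(labels.index)
        if missing:
            raise ValueError(f"{len(missing)} cells lack labels")
        adata.obs["cell_type"] = pd.Categorical(labels.reindex(adata.obs_names))
    if "cell_type" not in adata.obs or adata.obs["cell_type"].isna().any():
        raise ValueError("loaded dataset has no complete cell labels")
    if np.any(adata.X < 0):
        raise ValueError("count matrix contains negative entries")
    zf = zero_fraction(adata)
    logger.info("loaded %s: %d cells x %d genes, zero fraction %.3f",
                path, *adata.shape, zf)
    if manifest.expected_zero_fraction is not None:
        if abs(zf - manifest.expected_zero_fraction) > 0.005:
            raise ValueError(
                f"zero fraction {zf:.3f} deviates from expected "
                f"{manifest.expected_zero_fraction:.3f} by more than 0.005")
    adata.uns["native_zero_fraction"] = zf
    return adata
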