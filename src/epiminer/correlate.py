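"""Pairwise correlation matrices over quantification matrices and the
PCA correlation-circle view of dataset relationships.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantify import QuantMatrix

__all__ = ["CorrelationResult", "VariablePlot", "correlation_matrix", "pca_variables"]

_METHODS = ("pearson", "spearman", "kendall")


@dataclass
class CorrelationResult:
    matrix: pd.DataFrame  # dataset x dataset, symmetric, unit diagonal
    method: str

    def to_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t", index_label="dataset")


@dataclass
class VariablePlot:
    """Dataset coordinates on the first two PCs of the correlation circle.

    Coordinates are the correlations of each dataset with PC1/PC2, so
    every arrow has length <= 1. The angle between two arrows shrinks with
    increasing correlation; 90 deg means none, >90 deg anti-correlation.
    """

    coords: pd.DataFrame          # columns PC1, PC2
    lengths: pd.Series
    angles: pd.DataFrame          # pairwise angles, degrees
    variance_explained: tuple[float, float]

    def to_tsv(self, path) -> None:
        out = self.coords.copy()
        out["length"] = self.lengths
        out.to_csv(path, sep="\t", index_label="dataset")


def _as_df(qm) -> pd.DataFrame:
    return qm.df if isinstance(qm, QuantMatrix) else pd.DataFrame(qm)


def correlation_matrix(qm, method: str = "pearson") -> CorrelationResult:
    """Correlation between all dataset pairs (Pearson, Spearman or Kendall).

    Constant columns have undefined correlation; those entries are reported
    as 0 with a warning so the matrix shape is preserved for heatmaps.
    """
    df = _as_df(qm)
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}")
    if len(df) < 2:
        raise ValueError("need >= 2 rows to correlate")
    mat = df.corr(method=method)
    if mat.isna().any().any():
        warnings.warn("constant column(s): undefined correlations reported as 0")
        mat = mat.fillna(0.0)
    np.fill_diagonal(mat.values, 1.0)
    return CorrelationResult(mat, method)


def pca_variables(qm) -> VariablePlot:
    """PCA on column-standardised data; datasets as correlation-circle arrows.

    Arrow coordinates are the correlations of each dataset with the first
    two principal components; arrow length measures how much of the dataset
    the 2-PC plane captures.
    """
    df = _as_df(qm)
    if len(df) < 3 or df.shape[1] < 2:
        raise ValueError("need >= 3 rows and >= 2 columns for PCA")
    X = df.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if (sd > 0).sum() < 2:
        raise ValueError("need >= 2 non-constant columns for PCA")
    Xs = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    # SVD of the standardised matrix == eigendecomposition of the correlation matrix
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    n = len(df)
    eigvals = S**2 / (n - 1)
    total_var = eigvals.sum()
    scores = U[:, :2] * S[:2]
    coords = np.zeros((df.shape[1], 2))
    for j in range(df.shape[1]):
        for k in range(2):
            if sd[j] > 0 and scores[:, k].std() > 0:
                coords[j, k] = np.corrcoef(Xs[:, j], scores[:, k])[0, 1]
    coords_df = pd.DataFrame(coords, index=df.columns, columns=["PC1", "PC2"])
    lengths = pd.Series(np.linalg.norm(coords, axis=1), index=df.columns)
    unit = coords / np.where(lengths.to_numpy()[:, None] > 0,
                             lengths.to_numpy()[:, None], 1.0)
    cosines = np.clip(unit @ unit.T, -1.0, 1.0)
    angles = pd.DataFrame(np.degrees(np.arccos(cosines)),
                          index=df.columns, columns=df.columns)
    np.fill_diagonal(angles.values, 0.0)
    ve = (float(eigvals[0] / total_var), float(eigvals[1] / total_var))
    return VariablePlot(coords_df, lengths, angles, ve)
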