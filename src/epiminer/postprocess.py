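"""Clustering of quantification matrices, expression linkage, quantile
normalisation, and re-rendering of saved result matrices (MatHM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .io_regions import GeneAnnotation, RegionSet, closest_feature

__all__ = [
    "ClusterAssignment",
    "read_expression",
    "kmeans_rows",
    "hcluster_rows",
    "link_expression",
    "quantile_normalize",
    "rerender",
]


@dataclass
class ClusterAssignment:
    labels: pd.Series   # row id -> cluster id in 1..k
    k: int
    method: str
    seed: int | None = None

    def row_order(self) -> list[str]:
        """Row ids grouped by cluster, preserving within-cluster input order."""
        return list(self.labels.sort_values(kind="stable").index)


def read_expression(path) -> pd.DataFrame:
    """Gene-id-indexed expression table (TSV, log2-scale values as-is)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression table")
    return df


def kmeans_rows(matrix, k: int, seed: int | None = None,
                restarts: int = 10) -> ClusterAssignment:
    """Lloyd k-means with k-means++ init, best of `restarts` by within-SS."""
    df = matrix.df if hasattr(matrix, "df") else pd.DataFrame(matrix)
    if k < 1 or k > len(df):
        raise ValueError(f"k={k} out of range for {len(df)} rows")
    if k == 1:
        labels = pd.Series(1, index=df.index)
        return ClusterAssignment(labels, 1, "kmeans", seed)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = pd.Series(km.fit_predict(df.to_numpy(dtype=float)) + 1, index=df.index)
    return ClusterAssignment(labels, k, "kmeans", seed)


def hcluster_rows(matrix, metric: str = "euclidean", linkage: str = "average"
                  ) -> tuple[list[str], np.ndarray]:
    """Agglomerative row clustering; returns (leaf order, merge tree)."""
    df = matrix.df if hasattr(matrix, "df") else pd.DataFrame(matrix)
    if len(df) < 2:
        raise ValueError("need >= 2 rows")
    Z = hierarchy.linkage(pdist(df.to_numpy(dtype=float), metric=metric),
                          method=linkage)
    order = hierarchy.leaves_list(Z)
    return [str(df.index[i]) for i in order], Z


def link_expression(clusters: ClusterAssignment, rois: RegionSet,
                    genes: GeneAnnotation, expression: pd.DataFrame | pd.Series,
                    sample: str | None = None, strip_version: bool = False
                    ) -> dict[int, pd.Series]:
    """Per-cluster expression distributions of closest-gene targets.

    Each ROI is assigned to its closest gene (TSS distance); the expression
    values of those target genes are collected per cluster. Genes missing
    from the table are dropped with a count warning.
    """
    if isinstance(expression, pd.DataFrame):
        col = sample if sample is not None else expression.columns[0]
        expr = expression[col]
    else:
        expr = expression
    if strip_version:
        expr = expr.copy()
        expr.index = [str(g).rsplit(".", 1)[0] for g in expr.index]
    names, _dist = closest_feature(rois, genes, mode="tss")
    roi_ids = rois.ids()
    gene_of = dict(zip(roi_ids, names))
    missing = 0
    out: dict[int, list[float]] = {c: [] for c in sorted(clusters.labels.unique())}
    for roi_id, cluster in clusters.labels.items():
        gene = gene_of.get(str(roi_id))
        if gene is None or gene not in expr.index:
            missing += 1
            continue
        out[cluster].append(float(expr.loc[gene]))
    if missing:
        warnings.warn(f"{missing} ROI(s) had no expression-mapped target gene")
    if all(len(v) == 0 for v in out.values()):
        raise ValueError("no ROI could be linked to an expressed gene")
    return {c: pd.Series(v) for c, v in out.items()}


def five_number(values: pd.Series) -> dict[str, float]:
    q = values.quantile([0, 0.25, 0.5, 0.75, 1.0])
    return {"min": q[0], "q1": q[0.25], "median": q[0.5], "q3": q[0.75], "max": q[1.0]}


def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Classic rank-mean quantile normalisation across samples.

    Each sample is sorted, values are averaged across samples at every rank
    and assigned back by rank; tied entries receive the mean of the values
    their ranks span. Idempotent.
    """
    if expr.isna().any().any():
        raise ValueError("expression table contains missing values")
    values = expr.to_numpy(dtype=float)
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = pd.Series(values[:, j]).rank(method="average").to_numpy()
        lower = np.floor(ranks).astype(int) - 1
        upper = np.ceil(ranks).astype(int) - 1
        out[:, j] = (ref[lower] + ref[upper]) / 2.0
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def rerender(matrix_path, out_path, kind: str = "heatmap", *,
             transpose: bool = False, row_order_path=None,
             cmap: str = "viridis") -> pd.DataFrame:
    """Re-render a saved result matrix TSV as a heatmap or boxplot image.

    The render reflects the matrix exactly (no re-scaling). Returns the
    data layer actually drawn, so renders are reproducible and testable.
    """
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if df.empty or df.shape[1] == 0:
        raise ValueError(f"malformed or empty matrix file {matrix_path}")
    if row_order_path is not None:
        with open(row_order_path) as fh:
            order = [line.strip() for line in fh if line.strip()]
        unknown = [r for r in order if r not in df.index]
        if unknown:
            raise ValueError(f"row-order ids not in matrix: {unknown}")
        df = df.loc[order]
    if transpose:
        df = df.T

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    if kind == "heatmap":
        im = ax.imshow(df.to_numpy(dtype=float), aspect="auto", cmap=cmap,
                       interpolation="nearest")
        fig.colorbar(im, ax=ax)
        ax.set_xticks(range(len(df.columns)))
        ax.set_xticklabels(df.columns, rotation=90, fontsize=6)
    elif kind == "boxplot":
        ax.boxplot([df[c].to_numpy(dtype=float) for c in df.columns],
                   tick_labels=list(df.columns))
    else:
        raise ValueError("kind must be 'heatmap' or 'boxplot'")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return df
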