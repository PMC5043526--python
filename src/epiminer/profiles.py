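"""Position-resolved quantification: around-center matrices, fixed-block
metagene profiles and composite average profiles, all strand-aware.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_regions import GenomeTable, RegionSet
from .quantify import resolve_reads

__all__ = [
    "ProfileMatrix",
    "around_center",
    "metagene",
    "average_profile",
    "expression_quartiles",
    "smooth_profile",
]


@dataclass
class ProfileMatrix:
    """ROIs x ordered position bins (or blocks) of normalised signal.

    For a minus-strand ROI with strand information used, columns run
    5'->3' of the feature (genomic order reversed).
    """

    df: pd.DataFrame
    mode: str                 # "center" | "blocks"
    flank: int | None = None
    bin_size: int | None = None
    n_blocks: int | None = None
    strand_used: bool = False

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index_label="id")


def _minus_mask(rois: RegionSet, use_strand: bool) -> np.ndarray:
    if use_strand and rois.strands is not None:
        return np.array([s == "-" for s in rois.strands])
    return np.zeros(len(rois), dtype=bool)


def around_center(datasets: dict, rois: RegionSet, genome: GenomeTable, *,
                  flank: int = 5000, bin_size: int = 50,
                  use_strand: bool = True, smooth: int = 0
                  ) -> dict[str, ProfileMatrix]:
    """Signal in consecutive bins over [center - flank, center + flank).

    center = floor((start + end) / 2). Bins that fall outside the chromosome
    simply receive zero signal, keeping the matrix rectangular. Values are
    reads-per-million per bin.
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin size")
    rois.validate_against(genome)
    n_cols = 2 * flank // bin_size
    col_offsets = -flank + bin_size * np.arange(n_cols)
    columns = [f"{o:+d}" for o in col_offsets]
    minus = _minus_mask(rois, use_strand)
    centers = (rois.starts + rois.ends) // 2
    ids = rois.ids()

    out = {}
    for name, src in datasets.items():
        store = resolve_reads(src)
        lib = store.n_reads
        values = np.zeros((len(rois), n_cols))
        for chrom in set(rois.chroms):
            pos = store.chroms.get(chrom, (np.array([], dtype=np.int64), None))[0]
            for i in np.flatnonzero(rois.chroms == chrom):
                edges = centers[i] + np.concatenate([col_offsets,
                                                     [flank]])
                cut = np.searchsorted(pos, edges, side="left")
                values[i] = np.diff(cut)
        values *= 1e6 / max(lib, 1)
        values[minus] = values[minus, ::-1]
        if smooth:
            values = np.apply_along_axis(_moving_average, 1, values, smooth)
        df = pd.DataFrame(values, index=pd.Index(ids, name="id"), columns=columns)
        out[name] = ProfileMatrix(df, "center", flank=flank, bin_size=bin_size,
                                  strand_used=use_strand)
    return out


def metagene(datasets: dict, rois: RegionSet, genome: GenomeTable, *,
             n_blocks: int = 20, use_strand: bool = True
             ) -> dict[str, ProfileMatrix]:
    """Per-ROI signal in n_blocks contiguous blocks of equal proportion.

    Block size is length // n_blocks; remainder bases go to the last block.
    Values are reads-per-million per base pair (density), so blocks of
    unequal length stay comparable. ROIs shorter than n_blocks are skipped
    with a warning.
    """
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    rois.validate_against(genome)
    keep = rois.lengths >= n_blocks
    if not keep.all():
        warnings.warn(f"skipping {int((~keep).sum())} ROI(s) shorter than {n_blocks} bp")
    rois = rois.subset(np.flatnonzero(keep))
    minus = _minus_mask(rois, use_strand)
    ids = rois.ids()
    columns = [f"block{b + 1}" for b in range(n_blocks)]

    # per-ROI block edges
    edges = np.zeros((len(rois), n_blocks + 1), dtype=np.int64)
    for i in range(len(rois)):
        s, e = int(rois.starts[i]), int(rois.ends[i])
        size = (e - s) // n_blocks
        edges[i, :-1] = s + size * np.arange(n_blocks)
        edges[i, -1] = e

    out = {}
    for name, src in datasets.items():
        store = resolve_reads(src)
        lib = store.n_reads
        values = np.zeros((len(rois), n_blocks))
        for chrom in set(rois.chroms):
            pos = store.chroms.get(chrom, (np.array([], dtype=np.int64), None))[0]
            for i in np.flatnonzero(rois.chroms == chrom):
                cut = np.searchsorted(pos, edges[i], side="left")
                values[i] = np.diff(cut) / np.diff(edges[i])
        values *= 1e6 / max(lib, 1)
        values[minus] = values[minus, ::-1]
        df = pd.DataFrame(values, index=pd.Index(ids, name="id"), columns=columns)
        out[name] = ProfileMatrix(df, "blocks", n_blocks=n_blocks,
                                  strand_used=use_strand)
    return out


def average_profile(matrix: ProfileMatrix,
                    groups: dict[str, list] | None = None) -> pd.DataFrame:
    """Column-wise mean profile, overall or per ROI group.

    groups maps group name -> row ids; groups must partition (a subset of)
    the rows and may not be empty.
    """
    if groups is None:
        return matrix.df.mean(axis=0).to_frame("all").T
    rows = {}
    for gname, ids in groups.items():
        ids = [str(i) for i in ids]
        sub = matrix.df.loc[matrix.df.index.isin(ids)]
        if sub.empty:
            raise ValueError(f"group {gname!r} matches no profile rows")
        rows[gname] = sub.mean(axis=0)
    return pd.DataFrame(rows).T


def expression_quartiles(expression: pd.Series) -> dict[str, list[str]]:
    """Partition genes into quarters by descending expression.

    Q1 holds the most expressed genes; group sizes differ by at most one;
    ties keep input order.
    """
    values = expression.to_numpy(dtype=float)
    order = np.argsort(-values, kind="stable")
    parts = np.array_split(order, 4)
    return {f"Q{q + 1}": [str(expression.index[i]) for i in part]
            for q, part in enumerate(parts)}


def _moving_average(row: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return row
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(row, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad:pad + len(row)]
    return out


def smooth_profile(matrix: ProfileMatrix, window: int) -> ProfileMatrix:
    """Centered moving average over columns (window in bins)."""
    values = np.apply_along_axis(_moving_average, 1, matrix.df.to_numpy(), window)
    df = pd.DataFrame(values, index=matrix.df.index, columns=matrix.df.columns)
    return ProfileMatrix(df, matrix.mode, matrix.flank, matrix.bin_size,
                         matrix.n_blocks, matrix.strand_used)
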