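"""Preferential-enrichment fractions (ENRICH) and presence/absence
coexistence matrices around a reference factor (CoREG).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io_regions import GenomeTable, RegionSet, overlaps, random_regions

__all__ = ["BinaryOccupancyMatrix", "enrichment_proportions", "coexistence"]


@dataclass
class BinaryOccupancyMatrix:
    """ROIs x factors presence/absence; substrate for CoREG and network
    learning."""

    df: pd.DataFrame  # 0/1 cells
    reference: str | None = None

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index_label="id")


def enrichment_proportions(roi_sets: dict[str, RegionSet],
                           factor_beds: dict[str, RegionSet],
                           with_random: bool = False,
                           genome: GenomeTable | None = None,
                           seed: int | None = None,
                           min_bp: int = 1) -> pd.DataFrame:
    """Fraction of each ROI set bound by >= 1 peak of each factor.

    With with_random, a matched random ROI set (same sizes, shuffled
    placement) is appended per input set, giving the expected fraction
    under random occurrence.
    """
    if not roi_sets or not factor_beds:
        raise ValueError("need at least one ROI set and one factor")
    for name, rs in roi_sets.items():
        if len(rs) == 0:
            raise ValueError(f"ROI set {name!r} is empty")
    sets = dict(roi_sets)
    if with_random:
        if genome is None:
            raise ValueError("random baseline requires a genome table")
        rng = np.random.default_rng(seed)
        for name, rs in roi_sets.items():
            sets[f"{name}_random"] = random_regions(rs, genome, rng)
    table = {
        set_name: {
            f: float(overlaps(rs, peaks, min_bp).mean())
            for f, peaks in factor_beds.items()
        }
        for set_name, rs in sets.items()
    }
    return pd.DataFrame(table)  # rows = factors, columns = roi sets


def coexistence(reference: RegionSet, factor_beds: dict[str, RegionSet],
                min_bp: int = 1, reference_name: str = "reference"
                ) -> BinaryOccupancyMatrix:
    """Presence/absence of each factor over the reference ROIs.

    The reference itself appears as an all-ones first column; factor
    columns are ordered by average-linkage clustering on Jaccard distance,
    oriented so the most reference-co-occurring factors sit next to the
    reference column and identical columns are adjacent.
    """
    if len(reference) == 0:
        raise ValueError("empty reference set")
    cols = {reference_name: np.ones(len(reference), dtype=np.int64)}
    for name, peaks in factor_beds.items():
        cols[name] = overlaps(reference, peaks, min_bp).astype(np.int64)
    df = pd.DataFrame(cols, index=pd.Index(reference.ids(), name="id"))

    factors = [c for c in df.columns if c != reference_name]
    if len(factors) > 1:
        occ = df[factors].to_numpy(dtype=bool).T  # factors x ROIs
        dist = pdist(occ, metric="jaccard")
        Z = hierarchy.linkage(dist, method="average")
        ref_dist = (~occ).mean(axis=1)  # Jaccard distance to the all-ones column
        order = _anchored_leaf_order(Z, ref_dist, len(factors))
        df = df[[reference_name] + [factors[i] for i in order]]
    return BinaryOccupancyMatrix(df, reference_name)


def _anchored_leaf_order(Z: np.ndarray, anchor_dist: np.ndarray,
                         n_leaves: int) -> list[int]:
    """Dendrogram leaf order with, at every merge, the subtree whose leaves
    are on average closer to the anchor placed first. Keeps identical
    columns adjacent while pulling anchor-like columns to the front."""

    def leaves(node: int) -> list[int]:
        if node < n_leaves:
            return [node]
        left, right = int(Z[node - n_leaves, 0]), int(Z[node - n_leaves, 1])
        a, b = leaves(left), leaves(right)
        if anchor_dist[a].mean() > anchor_dist[b].mean():
            a, b = b, a
        return a + b

    return leaves(n_leaves + len(Z) - 1)
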