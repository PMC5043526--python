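"""Differential enrichment testing.

Two-condition testing builds one 2x2 table per ROI — normalised read
intensities inside vs outside the ROI, one column per condition — and
applies a two-sided Fisher exact test. Multi-condition testing applies
one-way Kruskal-Wallis or ANOVA per ROI. Raw p values are adjusted by the
Benjamini-Hochberg step-up procedure; significant rows can be converted to
per-row standard z-scores for heatmaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_regions import GenomeTable, RegionSet
from .quantify import QuantMatrix, count_reads_in_regions, resolve_reads

__all__ = [
    "DifferentialResult",
    "fisher_two_sided_margins",
    "fisher_differential",
    "two_condition_differential",
    "multigroup_differential",
    "bh_adjust",
    "zscore_rows",
]

_REL_EPS = 1.0 + 1e-7  # relative guard when comparing table probabilities


def fisher_two_sided_margins(r1: int, r2: int, c1: int
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Fisher p for every table with fixed margins.

    Returns (support, pvals): support are the admissible values of cell a,
    and pvals[i] is the two-sided p of the table with a = support[i] — the
    sum of the probabilities of all tables (under the hypergeometric null)
    no more probable than the observed one.
    """
    n = r1 + r2
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    if n == 0 or c1 == 0 or c1 == n or r1 == 0 or r2 == 0:
        return support, np.ones(len(support))  # degenerate margin: only one table
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    order = np.argsort(pmf, kind="stable")
    csum = np.cumsum(pmf[order])
    # for each observed pmf, sum all pmf <= observed * (1 + eps)
    pos = np.searchsorted(pmf[order], pmf * _REL_EPS, side="right")
    pvals = np.minimum(csum[np.maximum(pos, 1) - 1], 1.0)
    return support, pvals


def fisher_differential(a, b, c, d) -> tuple[np.ndarray, np.ndarray]:
    """Per-ROI two-sided Fisher exact test on tables [[a, b], [c, d]].

    Columns are the two conditions; rows are intensities inside (a, b) and
    outside (c, d) the ROI. Returns (odds_ratio, p). Odds ratios use the
    0.5 Haldane correction when any cell is zero.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    if np.any((a < 0) | (b < 0) | (c < 0) | (d < 0)):
        raise ValueError("negative cell in contingency table")
    p = np.ones(len(a))
    cache: dict[tuple[int, int, int], np.ndarray] = {}
    for i in range(len(a)):
        key = (int(a[i] + b[i]), int(c[i] + d[i]), int(a[i] + c[i]))
        pv = cache.get(key)
        if pv is None:
            _, pv = fisher_two_sided_margins(*key)
            cache[key] = pv
        lo = max(0, key[2] - key[1])  # support lower bound: max(0, c1 - r2)
        p[i] = pv[int(a[i]) - lo]
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    af = a + 0.5 * zero
    bf = b + 0.5 * zero
    cf = c + 0.5 * zero
    df_ = d + 0.5 * zero
    odds = (af * df_) / (bf * cf)
    return odds, p


@dataclass
class DifferentialResult:
    """Per-ROI test results plus the group intensities that produced them."""

    table: pd.DataFrame           # intensities, statistic, p, adjusted p, ...
    alpha: float
    test: str
    zscores: pd.DataFrame | None = None

    @property
    def significant(self) -> pd.Series:
        return self.table["p_adjusted"] < self.alpha

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="id")


def two_condition_differential(reads_a, reads_b, rois: RegionSet,
                               genome: GenomeTable, *,
                               names: tuple[str, str] = ("A", "B"),
                               alpha: float = 0.05) -> DifferentialResult:
    """Fisher-based two-condition differential enrichment over ROIs.

    reads_a / reads_b may be a single read source or a list of replicates;
    replicates are summed within condition before table construction. The
    'outside' count of each condition is its normalised genome-wide total
    (one million) minus the in-ROI intensity, both rounded to integers.
    """
    rois.validate_against(genome)

    def _pooled(sources) -> np.ndarray:
        if not isinstance(sources, (list, tuple)):
            sources = [sources]
        in_rpm = np.zeros(len(rois))
        for src in sources:
            store = resolve_reads(src)
            in_rpm += count_reads_in_regions(store, rois) * 1e6 / store.n_reads
        return in_rpm / len(sources)

    in_a = np.floor(_pooled(reads_a) + 0.5).astype(np.int64)
    in_b = np.floor(_pooled(reads_b) + 0.5).astype(np.int64)
    out_a = 10**6 - in_a
    out_b = 10**6 - in_b
    odds, p = fisher_differential(in_a, in_b, out_a, out_b)
    p_adj = bh_adjust(p)
    direction = np.where(in_a >= in_b, names[0], names[1])
    table = pd.DataFrame(
        {
            f"in_{names[0]}": in_a,
            f"in_{names[1]}": in_b,
            "odds_ratio": odds,
            "p": p,
            "p_adjusted": p_adj,
            "direction": direction,
        },
        index=pd.Index(rois.ids(), name="id"),
    )
    table["significant"] = table["p_adjusted"] < alpha
    return DifferentialResult(table, alpha, "fisher")


def _kruskal_rows(values: np.ndarray, group_ix: list[np.ndarray]
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Kruskal-Wallis H and p per row, with tie correction."""
    n = values.shape[1]
    ranks = stats.rankdata(values, axis=1)
    h = np.zeros(len(values))
    for ix in group_ix:
        rbar = ranks[:, ix].mean(axis=1)
        h += len(ix) * (rbar - (n + 1) / 2) ** 2
    h *= 12.0 / (n * (n + 1))
    # tie correction per row
    tie_term = np.zeros(len(values))
    for r in range(len(values)):
        _, counts = np.unique(values[r], return_counts=True)
        tie_term[r] = ((counts**3 - counts).sum())
    denom = 1.0 - tie_term / (n**3 - n)
    all_tied = denom <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(all_tied, 0.0, h / np.where(denom > 0, denom, 1.0))
    p = stats.chi2.sf(h, df=len(group_ix) - 1)
    p = np.where(all_tied, 1.0, p)
    if all_tied.any():
        warnings.warn(f"{int(all_tied.sum())} all-tied row(s) under Kruskal-Wallis: p = 1")
    return h, p


def multigroup_differential(qm, groups: dict[str, str],
                            test: str = "kruskal", *, alpha: float = 0.05
                            ) -> DifferentialResult:
    """Per-ROI one-way test across >= 2 conditions.

    groups maps column name -> condition label. 'kruskal' is rank-based;
    'anova' is the classic F test and wants >= 2 replicate columns per
    condition.
    """
    df = qm.df if isinstance(qm, QuantMatrix) else pd.DataFrame(qm)
    conditions: dict[str, list[str]] = {}
    for col, cond in groups.items():
        conditions.setdefault(cond, []).append(col)
    if len(conditions) < 2:
        raise ValueError("need >= 2 conditions")
    values = df[list(groups)].to_numpy(dtype=float)
    col_pos = {c: i for i, c in enumerate(groups)}
    group_ix = [np.array([col_pos[c] for c in cols]) for cols in conditions.values()]

    if test == "kruskal":
        stat, p = _kruskal_rows(values, group_ix)
    elif test == "anova":
        if any(len(ix) < 2 for ix in group_ix):
            raise ValueError("anova requires >= 2 replicate columns per condition")
        res = stats.f_oneway(*[values[:, ix] for ix in group_ix], axis=1)
        stat, p = np.asarray(res.statistic), np.asarray(res.pvalue)
        bad = ~np.isfinite(p)
        stat = np.where(bad, 0.0, stat)
        p = np.where(bad, 1.0, p)
    else:
        raise ValueError("test must be 'kruskal' or 'anova'")

    p_adj = bh_adjust(p)
    cond_means = {f"mean_{cond}": values[:, ix].mean(axis=1)
                  for cond, ix in zip(conditions, group_ix)}
    table = pd.DataFrame({**cond_means, "statistic": stat, "p": p,
                          "p_adjusted": p_adj}, index=df.index)
    table["significant"] = table["p_adjusted"] < alpha
    zs = zscore_rows(df.loc[table["significant"]])
    return DifferentialResult(table, alpha, test, zscores=zs)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def zscore_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Per-row standard z-scores (sample SD, n-1); constant rows -> zeros."""
    values = df.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z = np.where(sd > 0, z, 0.0)
    return pd.DataFrame(z, index=df.index, columns=df.columns)
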