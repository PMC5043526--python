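import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from epiminer import fixtures
from epiminer.differential import (bh_adjust, fisher_differential,
                                   fisher_two_sided_margins,
                                   multigroup_differential,
                                   two_condition_differential, zscore_rows)
from epiminer.io_regions import RegionSet


class TestFisher:
    def test_symmetric_table(self):
        _, p = fisher_differential([5], [5], [5], [5])
        assert p[0] == pytest.approx(1.0)

    def test_against_exhaustive_enumeration(self):
        """p equals the sum over same-margin tables no more probable than
        the observed one (direct integer enumeration)."""
        import math

        a, b, c, d = 20, 10, 80, 90
        _, p = fisher_differential([a], [b], [c], [d])
        r1, r2, c1 = a + b, c + d, a + c
        denom = math.comb(r1 + r2, c1)
        nums = [math.comb(r1, k) * math.comb(r2, c1 - k)
                for k in range(max(0, c1 - r2), min(r1, c1) + 1)]
        obs = math.comb(r1, a) * math.comb(r2, c1 - a)
        expect = sum(m for m in nums if m <= obs) / denom
        assert p[0] == pytest.approx(expect, rel=1e-12)

    def test_extreme_table_direction(self):
        odds, p = fisher_differential([0], [50], [100], [50])
        assert p[0] < 1e-10 and odds[0] < 1

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(9)
        tables = rng.integers(0, 40, size=(200, 4))
        odds, p = fisher_differential(*tables.T)
        for (a, b, c, d), mine in zip(tables, p):
            ref = stats.fisher_exact([[a, b], [c, d]]).pvalue
            assert mine == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_negative_cell_error(self):
        with pytest.raises(ValueError):
            fisher_differential([-1], [1], [1], [1])

    def test_margins_helper_consistency(self):
        support, pv = fisher_two_sided_margins(6, 8, 5)
        assert len(support) == len(pv)
        assert np.all((pv > 0) & (pv <= 1))


class TestBH:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.005, 0.01, 0.03, 0.04]),
                                   [0.02, 0.02, 0.04, 0.04])

    def test_degenerate_inputs(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
        with pytest.raises(ValueError):
            bh_adjust([1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, pvals):
        p = np.array(pvals)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15) and np.all(q <= 1)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.random(rng.integers(2, 50))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)

    def test_empirical_fdr_controlled(self):
        """Mixed null/alternative simulation: empirical FDR <= q + 3 SE."""
        rng = np.random.default_rng(4)
        q = 0.1
        fdrs = []
        for _ in range(200):
            p_null = rng.random(80)
            p_alt = rng.beta(0.05, 10, size=20)
            p = np.concatenate([p_null, p_alt])
            adj = bh_adjust(p)
            rejected = adj < q
            if rejected.any():
                fdrs.append(rejected[:80].sum() / rejected.sum())
            else:
                fdrs.append(0.0)
        se = np.std(fdrs, ddof=1) / np.sqrt(len(fdrs))
        assert np.mean(fdrs) <= q + 3 * se


class TestMultigroup:
    def test_identical_groups_h_zero(self):
        df = pd.DataFrame({"a1": [1.0, 2], "a2": [2.0, 3], "b1": [1.0, 2],
                           "b2": [2.0, 3]})
        res = multigroup_differential(df, {"a1": "A", "a2": "A",
                                           "b1": "B", "b2": "B"}, "kruskal")
        assert res.table["statistic"].iloc[0] == pytest.approx(0.0)

    def test_kruskal_matches_scipy(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.normal(size=(50, 9)),
                          columns=[f"c{g}_{r}" for g in range(3) for r in range(3)])
        groups = {c: c.split("_")[0] for c in df.columns}
        res = multigroup_differential(df, groups, "kruskal")
        for i in range(50):
            samples = [df.iloc[i, 3 * g:3 * g + 3] for g in range(3)]
            ref = stats.kruskal(*samples)
            assert res.table["statistic"].iloc[i] == pytest.approx(ref.statistic)
            assert res.table["p"].iloc[i] == pytest.approx(ref.pvalue)

    def test_all_tied_row_warns_p_one(self):
        df = pd.DataFrame({"a1": [1.0], "a2": [1.0], "b1": [1.0], "b2": [1.0]})
        with pytest.warns(UserWarning, match="all-tied"):
            res = multigroup_differential(df, {"a1": "A", "a2": "A",
                                               "b1": "B", "b2": "B"}, "kruskal")
        assert res.table["p"].iloc[0] == 1.0

    def test_power_and_null_uniformity(self):
        """One condition shifted by 3 SD: planted rows significant, null
        rows' p values uniform (KS test)."""
        rng = np.random.default_rng(8)
        n_null, n_alt = 2000, 100
        cols = {f"c{g}_{r}": rng.normal(size=n_null + n_alt)
                for g in range(3) for r in range(5)}
        df = pd.DataFrame(cols)
        for r in range(5):
            df.loc[n_null:, f"c0_{r}"] += 3.0
        groups = {c: c.split("_")[0] for c in df.columns}
        res_f = multigroup_differential(df, groups, "anova")
        # F-test power at this noncentrality is ~0.95; bound at 0.90
        assert (res_f.table["p"].iloc[n_null:] < 0.01).mean() > 0.90
        # the rank test has a discrete p floor (~2e-3 at n=5 per group),
        # so its power criterion is read at the 0.05 level
        res_k = multigroup_differential(df, groups, "kruskal")
        assert (res_k.table["p"].iloc[n_null:] < 0.05).mean() > 0.95
        ks = stats.kstest(res_k.table["p"].iloc[:n_null], "uniform")
        assert ks.pvalue > 0.001

    def test_anova_requires_replicates(self):
        df = pd.DataFrame({"a": [1.0, 2], "b": [2.0, 1], "c": [0.0, 1]})
        with pytest.raises(ValueError, match="replicate"):
            multigroup_differential(df, {"a": "A", "b": "B", "c": "C"}, "anova")


class TestZScores:
    def test_basic_row(self):
        z = zscore_rows(pd.DataFrame([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(z.to_numpy()[0], [-1, 0, 1])

    def test_constant_row_zeros(self):
        z = zscore_rows(pd.DataFrame([[4.0, 4.0, 4.0]]))
        np.testing.assert_allclose(z.to_numpy()[0], 0)

    def test_rows_standardised(self):
        rng = np.random.default_rng(2)
        z = zscore_rows(pd.DataFrame(rng.random((20, 6))))
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1, atol=1e-12)


class TestTwoConditionPipeline:
    def test_planted_direction_on_reads(self):
        rng = np.random.default_rng(11)
        genome = fixtures.make_genome(1, [200_000])
        starts = np.arange(40) * 5_000
        rois = RegionSet(np.array(["chr1"] * 40, dtype=object), starts,
                         starts + 1_000,
                         np.array([f"p{i}" for i in range(40)], dtype=object))
        fold_a = np.full(40, 3.0)
        fold_a[:5] = 15.0
        reads_a = fixtures.simulate_chip_reads(
            fixtures.EnrichmentSpec(rois, fold=fold_a, background_rate=0.3),
            genome, rng)
        reads_b = fixtures.simulate_chip_reads(
            fixtures.EnrichmentSpec(rois, fold=3.0, background_rate=0.3),
            genome, rng)
        res = two_condition_differential(reads_a, reads_b, rois, genome,
                                         names=("A", "B"))
        planted = res.table.iloc[:5]
        assert planted["significant"].all()
        assert (planted["direction"] == "A").all()
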