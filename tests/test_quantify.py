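import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiminer import fixtures
from epiminer.io_regions import ReadStore, RegionSet
from epiminer.quantify import (QuantMatrix, aggregate_to_roi, bin_genome,
                               count_reads, log_transform, normalize_depth,
                               quantify_datasets, scale, scale_values,
                               spike_normalize, subtract_input)


class TestBinGrid:
    @pytest.mark.parametrize("length,bin_size,n_bins,last_len", [
        (1000, 200, 5, 200),
        (1050, 200, 6, 50),
    ])
    def test_bin_counts_and_partial_last_bin(self, length, bin_size, n_bins, last_len):
        grid = bin_genome(fixtures.make_genome(1, [length]), bin_size)
        assert grid.n_bins == n_bins
        last = grid.bin_ids()[-1]
        s, e = last.split(":")[1].split("-")
        assert int(e) - int(s) == last_len

    def test_invalid_bin_size(self):
        with pytest.raises(ValueError):
            bin_genome(fixtures.make_genome(1, [100]), 0)


class TestCounting:
    def test_empty_store_all_zero(self, toy_genome):
        grid = bin_genome(toy_genome, 50)
        counts = count_reads(ReadStore.from_arrays({}), grid)
        assert counts.sum() == 0 and len(counts) == grid.n_bins

    def test_five_prime_bin_assignment(self, toy_genome):
        grid = bin_genome(toy_genome, 50)
        store = ReadStore.from_arrays({"chr1": (np.array([75]), np.array([1]))})
        counts = count_reads(store, grid)
        assert counts[1] == 1 and counts.sum() == 1  # 75 in [50, 100)

    def test_conservation_of_simulated_reads(self, toy_genome):
        spec = fixtures.EnrichmentSpec(
            RegionSet.from_records([("chr1", 0, 1000)]), fold=3.0,
            background_rate=0.01, library_size=1000, seed=0)
        reads = fixtures.simulate_chip_reads(spec, toy_genome)
        counts = count_reads(reads, bin_genome(toy_genome, 128))
        assert counts.sum() == 1000

    def test_chromosome_mismatch_warns(self, toy_genome):
        grid = bin_genome(toy_genome, 100)
        store = ReadStore.from_arrays({"chrZ": (np.array([5]), np.array([1]))})
        with pytest.warns(UserWarning, match="chrZ"):
            counts = count_reads(store, grid)
        assert counts.sum() == 0


class TestNormalisation:
    def test_rpm_arithmetic(self):
        assert normalize_depth([7], 2_000_000)[0] == pytest.approx(3.5)
        assert normalize_depth(np.zeros(4), 10).sum() == 0
        np.testing.assert_allclose(normalize_depth([4, 8], 1000),
                                   2 * normalize_depth([4, 8], 2000))
        with pytest.raises(ValueError):
            normalize_depth([1], 0)

    def test_spike_scaling_law(self):
        assert spike_normalize([10], 500_000)[0] == pytest.approx(20.0)
        np.testing.assert_allclose(spike_normalize([3, 6], 500_000),
                                   2 * spike_normalize([3, 6], 1_000_000))
        with pytest.raises(ValueError):
            spike_normalize([1], 0)

    def test_input_subtraction_floor(self):
        np.testing.assert_allclose(subtract_input([5.0, 1.0], [2.0, 2.0]), [3.0, 0.0])
        np.testing.assert_allclose(subtract_input([4.0], [0.0]), [4.0])
        with pytest.raises(ValueError):
            subtract_input([1.0], [1.0, 2.0])

    def test_log_transform(self):
        np.testing.assert_allclose(log_transform([0, 3]), [0.0, 2.0])
        a = log_transform([1.5, 7.2, 0.1])
        assert np.all(np.diff(a[np.argsort([1.5, 7.2, 0.1])]) > 0)
        with pytest.raises(ValueError):
            log_transform([-1])


class TestScaling:
    def test_global_vs_per_column(self):
        m = np.array([[0.0, 10.0], [5.0, 20.0]])
        np.testing.assert_allclose(scale_values(m, per_column=False),
                                   [[0, 0.5], [0.25, 1.0]])
        np.testing.assert_allclose(scale_values(m, per_column=True),
                                   [[0, 0], [1, 1]])

    def test_constant_column_zeroed(self):
        m = np.array([[3.0, 1.0], [3.0, 2.0], [3.0, 3.0]])
        out = scale_values(m, per_column=True)
        np.testing.assert_allclose(out[:, 0], 0)
        np.testing.assert_allclose(out[:, 1], [0, 0.5, 1])

    @given(st.lists(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=3),
                    min_size=2, max_size=8),
           st.booleans())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_idempotence(self, rows, per_column):
        m = np.array(rows)
        once = scale_values(m, per_column)
        np.testing.assert_allclose(scale_values(once, per_column), once,
                                   atol=1e-12)


class TestAggregation:
    def test_mean_over_bins(self, toy_genome):
        grid = bin_genome(toy_genome, 100)
        values = np.zeros(grid.n_bins)
        values[:3] = [2, 4, 6]
        roi = RegionSet.from_records([("chr1", 0, 300)])
        assert aggregate_to_roi(values, grid, roi)[0] == pytest.approx(4.0)

    def test_roi_inside_single_bin(self, toy_genome):
        grid = bin_genome(toy_genome, 100)
        values = np.zeros(grid.n_bins)
        values[0] = 7
        roi = RegionSet.from_records([("chr1", 20, 60)])
        assert aggregate_to_roi(values, grid, roi)[0] == pytest.approx(7.0)

    def test_per_base_oracle_on_aligned_rois(self):
        """Bin-aligned ROI mean equals the brute-force per-base mean."""
        genome = fixtures.make_genome(1, [10_000])
        grid = bin_genome(genome, 100)
        rng = np.random.default_rng(8)
        values = rng.random(grid.n_bins)
        per_base = np.repeat(values, 100)
        rois = RegionSet.from_records([("chr1", 300, 900), ("chr1", 0, 10_000)])
        got = aggregate_to_roi(values, grid, rois)
        expect = [per_base[300:900].mean(), per_base.mean()]
        np.testing.assert_allclose(got, expect)

    def test_unknown_chromosome_error(self, toy_genome):
        grid = bin_genome(toy_genome, 100)
        roi = RegionSet.from_records([("chrZ", 0, 10)])
        with pytest.raises(ValueError, match="unknown"):
            aggregate_to_roi(np.zeros(grid.n_bins), grid, roi)


class TestPipeline:
    def test_uniform_reads_constant_roi_scales_to_zero(self):
        genome = fixtures.make_genome(1, [10_000])
        spec = fixtures.EnrichmentSpec(
            RegionSet.from_records([("chr1", 0, 10_000)]), fold=1.0,
            background_rate=0.1, library_size=5_000, seed=1)
        reads = fixtures.simulate_chip_reads(spec, genome)
        roi = RegionSet.from_records([("chr1", 0, 10_000, "all")])
        qm = quantify_datasets({"d": reads}, genome, rois=roi, bin_size=10_000)
        assert qm.df.loc["all", "d"] == 0.0  # single value, constant column

    def test_enriched_roi_is_column_maximum(self):
        genome = fixtures.make_genome(1, [50_000])
        hot = RegionSet.from_records([("chr1", 20_000, 21_000)])
        spec = fixtures.EnrichmentSpec(hot, fold=10.0, background_rate=0.05,
                                       library_size=40_000, seed=2)
        reads = fixtures.simulate_chip_reads(spec, genome)
        rois = RegionSet.from_records(
            [("chr1", 20_000, 21_000, "hot"), ("chr1", 5_000, 6_000, "cold"),
             ("chr1", 40_000, 41_000, "cold2")])
        qm = quantify_datasets({"d": reads}, genome, rois=rois, bin_size=200)
        # genome-wide scaling: the enriched ROI averages the top-scaled bins
        assert qm.df["d"].idxmax() == "hot"
        assert qm.df.loc["hot", "d"] > 2 * qm.df.loc["cold", "d"]
        rr = quantify_datasets({"d": reads}, genome, rois=rois, bin_size=200,
                               mode="roi")
        assert rr.df.loc["hot", "d"] == pytest.approx(1.0)  # restricted frame

    def test_genome_wide_vs_roi_restricted_scaling_differ(self):
        """When the ROI set excludes the global maximum, restricted scaling
        inflates the ROI signal relative to genome-wide scaling."""
        genome = fixtures.make_genome(1, [50_000])
        hot = RegionSet.from_records([("chr1", 20_000, 21_000)])
        spec = fixtures.EnrichmentSpec(hot, fold=20.0, background_rate=0.05,
                                       library_size=40_000, seed=3)
        reads = fixtures.simulate_chip_reads(spec, genome)
        rois = RegionSet.from_records(
            [("chr1", 5_000, 6_000, "a"), ("chr1", 40_000, 41_000, "b")])
        gw = quantify_datasets({"d": reads}, genome, rois=rois, mode="genome")
        rr = quantify_datasets({"d": reads}, genome, rois=rois, mode="roi")
        assert rr.df["d"].max() == pytest.approx(1.0)
        assert gw.df["d"].max() < 1.0

    def test_provenance_flags(self):
        genome = fixtures.make_genome(1, [5_000])
        store = ReadStore.from_arrays(
            {"chr1": (np.arange(0, 5000, 10), np.ones(500, dtype=np.int8))})
        roi = RegionSet.from_records([("chr1", 0, 1000, "r")])
        qm = quantify_datasets({"d": store}, genome, rois=roi,
                               spikes={"d": 1000}, scaling=False)
        assert qm.spike_normalized and qm.depth_normalized
        assert qm.log_transformed and qm.scaling == "none"

    def test_scale_wrapper_sets_flag(self):
        qm = QuantMatrix(pd.DataFrame({"a": [0.0, 1.0], "b": [1.0, 3.0]}))
        assert scale(qm, shared_antibody=True).scaling == "global"
        assert scale(qm, shared_antibody=False).scaling == "per_dataset"
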