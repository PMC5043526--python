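"""Genome-wide quantification: binning, counting, normalisation, scaling.

The pipeline order is bin -> count -> (spike | depth) normalise ->
input-subtract -> log2 -> aggregate-to-ROI -> 0-1 scale. Reads are assigned
to exactly one bin by their 5' position, which keeps count conservation
exact (sum of bin counts == number of counted reads).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_regions import GenomeTable, ReadStore, RegionSet

__all__ = [
    "BinGrid",
    "QuantMatrix",
    "bin_genome",
    "count_reads",
    "count_reads_in_regions",
    "normalize_depth",
    "subtract_input",
    "spike_normalize",
    "log_transform",
    "scale_values",
    "scale",
    "aggregate_to_roi",
    "quantify_datasets",
    "resolve_reads",
]


@dataclass
class BinGrid:
    """Fixed-width bins tiling every chromosome; last bin may be partial."""

    genome: GenomeTable
    bin_size: int
    offsets: dict[str, int] = field(init=False)
    n_bins_per_chrom: dict[str, int] = field(init=False)
    n_bins: int = field(init=False)

    def __post_init__(self):
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        self.offsets, self.n_bins_per_chrom = {}, {}
        total = 0
        for chrom, L in self.genome.entries:
            n = -(-L // self.bin_size)  # ceil division
            self.offsets[chrom] = total
            self.n_bins_per_chrom[chrom] = n
            total += n
        self.n_bins = total

    def bin_span(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Global [lo, hi) bin indices of all bins overlapping [start, end)."""
        if chrom not in self.offsets:
            raise ValueError(f"unknown chromosome {chrom!r}")
        off = self.offsets[chrom]
        return off + start // self.bin_size, off + (end - 1) // self.bin_size + 1

    def bin_ids(self) -> list[str]:
        ids = []
        for chrom, L in self.genome.entries:
            for b in range(self.n_bins_per_chrom[chrom]):
                s = b * self.bin_size
                ids.append(f"{chrom}:{s}-{min(s + self.bin_size, L)}")
        return ids


def bin_genome(genome: GenomeTable, bin_size: int) -> BinGrid:
    return BinGrid(genome, bin_size)


def resolve_reads(source) -> ReadStore:
    """Accept a ReadStore or a SAM/BAM path."""
    if isinstance(source, ReadStore):
        return source
    return ReadStore.from_alignments(source)


def count_reads(reads, grid: BinGrid) -> np.ndarray:
    """Per-bin read counts by 5' position. Returns an int64 vector."""
    store = resolve_reads(reads)
    counts = np.zeros(grid.n_bins, dtype=np.int64)
    missing = [c for c in store.chroms if c not in grid.offsets]
    if missing:
        warnings.warn(f"reads on chromosomes absent from grid ignored: {missing}")
    for chrom, (pos, _strand) in store.chroms.items():
        if chrom not in grid.offsets:
            continue
        idx = grid.offsets[chrom] + pos // grid.bin_size
        counts += np.bincount(idx, minlength=grid.n_bins)
    return counts


def count_reads_in_regions(reads, regions: RegionSet) -> np.ndarray:
    """Reads whose 5' position falls inside each region (positions sorted)."""
    store = resolve_reads(reads)
    out = np.zeros(len(regions), dtype=np.int64)
    for chrom, (pos, _strand) in store.chroms.items():
        mask = regions.chroms == chrom
        if not mask.any():
            continue
        idx = np.flatnonzero(mask)
        lo = np.searchsorted(pos, regions.starts[idx], side="left")
        hi = np.searchsorted(pos, regions.ends[idx], side="left")
        out[idx] = hi - lo
    return out


def normalize_depth(counts, library_size: int) -> np.ndarray:
    """Reads-per-million: count * 1e6 / library_size."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return np.asarray(counts, dtype=float) * 1e6 / library_size


def spike_normalize(counts, reference_read_count: int) -> np.ndarray:
    """Reference-adjusted reads-per-million: count * 1e6 / spike-in reads.

    Replaces depth normalisation when an exogenous reference genome
    alignment is available; a global loss of signal shrinks target counts
    but not the reference count, so the scale is preserved across samples.
    """
    if reference_read_count <= 0:
        raise ValueError("reference read count must be positive")
    return np.asarray(counts, dtype=float) * 1e6 / reference_read_count


def subtract_input(target_rpm, input_rpm) -> np.ndarray:
    """target - input, floored at 0 (negative signal is meaningless downstream)."""
    target_rpm = np.asarray(target_rpm, dtype=float)
    input_rpm = np.asarray(input_rpm, dtype=float)
    if target_rpm.shape != input_rpm.shape:
        raise ValueError("target/input length mismatch")
    return np.maximum(target_rpm - input_rpm, 0.0)


def log_transform(values, pseudocount: float = 1.0) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("negative input to log transform")
    return np.log2(values + pseudocount)


def scale_values(values: np.ndarray, per_column: bool) -> np.ndarray:
    """Min-max scale to [0, 1]; constant column (or matrix) maps to zeros."""
    values = np.asarray(values, dtype=float)
    if per_column:
        lo = values.min(axis=0, keepdims=True)
        hi = values.max(axis=0, keepdims=True)
    else:
        lo = values.min()
        hi = values.max()
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (values - lo) / span
    return np.where(np.broadcast_to(span, values.shape) > 0, out, 0.0)


@dataclass
class QuantMatrix:
    """ROIs (or bins) x datasets signal matrix with provenance flags."""

    df: pd.DataFrame
    depth_normalized: bool = False
    input_subtracted: bool = False
    spike_normalized: bool = False
    log_transformed: bool = False
    scaling: str = "none"  # none | global | per_dataset

    @property
    def flags(self) -> dict:
        return {
            "depth_normalized": self.depth_normalized,
            "input_subtracted": self.input_subtracted,
            "spike_normalized": self.spike_normalized,
            "log_transformed": self.log_transformed,
            "scaling": self.scaling,
        }

    def to_tsv(self, path, sidecar: bool = True) -> None:
        self.df.to_csv(path, sep="\t", index_label="id")
        if sidecar:
            import json

            with open(str(path) + ".json", "w") as fh:
                json.dump(self.flags, fh, indent=1)


def scale(matrix: QuantMatrix, shared_antibody: bool) -> QuantMatrix:
    """0-1 scaling; one global min-max when all datasets share an antibody,
    otherwise per-dataset (per-column)."""
    values = scale_values(matrix.df.to_numpy(), per_column=not shared_antibody)
    df = pd.DataFrame(values, index=matrix.df.index, columns=matrix.df.columns)
    out = QuantMatrix(df, matrix.depth_normalized, matrix.input_subtracted,
                      matrix.spike_normalized, matrix.log_transformed,
                      "global" if shared_antibody else "per_dataset")
    return out


def aggregate_to_roi(bin_values, grid: BinGrid, rois: RegionSet) -> np.ndarray:
    """Mean over all bins overlapping each ROI by >= 1 bp."""
    bin_values = np.asarray(bin_values, dtype=float)
    out = np.zeros(len(rois), dtype=float)
    for i in range(len(rois)):
        lo, hi = grid.bin_span(rois.chroms[i], int(rois.starts[i]), int(rois.ends[i]))
        out[i] = bin_values[lo:hi].mean()
    return out


def _roi_territory_bins(rois: RegionSet, bin_size: int) -> tuple[RegionSet, np.ndarray]:
    """Bin each ROI from its own start; returns sub-bins + owning ROI index."""
    chroms, starts, ends, owner = [], [], [], []
    for i in range(len(rois)):
        s, e = int(rois.starts[i]), int(rois.ends[i])
        for b in range(s, e, bin_size):
            chroms.append(rois.chroms[i])
            starts.append(b)
            ends.append(min(b + bin_size, e))
            owner.append(i)
    return (RegionSet(np.array(chroms, dtype=object), np.array(starts),
                      np.array(ends)),
            np.array(owner, dtype=np.int64))


def _normalizer(store: ReadStore, spike) -> tuple[float, bool]:
    """Return (denominator, is_spike)."""
    if spike is None:
        return float(store.n_reads), False
    if isinstance(spike, (int, np.integer)):
        ref = int(spike)
    else:
        ref = resolve_reads(spike).n_reads
    if ref <= 0:
        raise ValueError("zero spike-in reference reads")
    return float(ref), True


def quantify_datasets(datasets: dict, genome: GenomeTable, *,
                      inputs: dict | None = None, spikes: dict | None = None,
                      rois: RegionSet | None = None, bin_size: int = 200,
                      mode: str = "genome", log: bool = True,
                      pseudocount: float = 1.0, scaling: bool = True,
                      shared_antibody: bool = False) -> QuantMatrix:
    """Full quantification flow over named datasets (ReadStores or paths).

    mode='genome' bins the whole genome, normalises there, then restricts to
    ROIs — the advisable default, since restricted quantification can over-
    or under-represent intensities relative to the genome-wide signal range.
    mode='roi' bins only ROI territory.
    """
    inputs = inputs or {}
    spikes = spikes or {}
    stores = {name: resolve_reads(src) for name, src in datasets.items()}

    if mode not in ("genome", "roi"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "roi" and rois is None:
        raise ValueError("mode='roi' requires rois")
    if rois is not None:
        rois.validate_against(genome)

    any_spike = False
    columns = {}
    if mode == "genome":
        # quantify, normalise and scale along the entire genome, then merge
        # the bins of each ROI — restricted scaling can over- or under-
        # represent intensities relative to the full genome-wide signal range
        grid = bin_genome(genome, bin_size)
        for name, store in stores.items():
            counts = count_reads(store, grid)
            denom, is_spike = _normalizer(store, spikes.get(name))
            any_spike = any_spike or is_spike
            vec = counts * 1e6 / denom
            if name in inputs:
                inp = resolve_reads(inputs[name])
                inp_vec = normalize_depth(count_reads(inp, grid), inp.n_reads)
                vec = subtract_input(vec, inp_vec)
            if log:
                vec = log_transform(vec, pseudocount)
            columns[name] = vec
        if scaling:
            bin_matrix = np.column_stack(list(columns.values()))
            bin_matrix = scale_values(bin_matrix, per_column=not shared_antibody)
            columns = dict(zip(columns, bin_matrix.T))
        if rois is not None:
            columns = {name: aggregate_to_roi(vec, grid, rois)
                       for name, vec in columns.items()}
        index = rois.ids() if rois is not None else grid.bin_ids()
        df = pd.DataFrame(columns, index=pd.Index(index, name="id"))
        return QuantMatrix(
            df, depth_normalized=True, input_subtracted=bool(inputs),
            spike_normalized=any_spike, log_transformed=log,
            scaling=("global" if shared_antibody else "per_dataset")
            if scaling else "none")
    else:  # ROI-restricted: bin, normalise and scale only ROI territory
        sub_bins, owner = _roi_territory_bins(rois, bin_size)
        for name, store in stores.items():
            counts = count_reads_in_regions(store, sub_bins)
            denom, is_spike = _normalizer(store, spikes.get(name))
            any_spike = any_spike or is_spike
            vec = counts * 1e6 / denom
            if name in inputs:
                inp = resolve_reads(inputs[name])
                inp_vec = normalize_depth(count_reads_in_regions(inp, sub_bins),
                                          inp.n_reads)
                vec = subtract_input(vec, inp_vec)
            if log:
                vec = log_transform(vec, pseudocount)
            roi_means = np.zeros(len(rois))
            np.add.at(roi_means, owner, vec)
            roi_means /= np.bincount(owner, minlength=len(rois))
            columns[name] = roi_means
        index = rois.ids()

    df = pd.DataFrame(columns, index=pd.Index(index, name="id"))
    qm = QuantMatrix(df, depth_normalized=True, input_subtracted=bool(inputs),
                     spike_normalized=any_spike, log_transformed=log)
    if scaling:
        qm = scale(qm, shared_antibody)
    return qm
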