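"""Synthetic genomes, annotations, ChIP read sets and expression tables.

Everything here is seeded and deterministic. Reads are placed by a
two-component model: a uniform background over the genome plus a Poisson
boost inside enriched regions, the simplest model consistent with
depth-normalised counting statistics. No GC or mappability bias is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_regions import GeneAnnotation, GenomeTable, ReadStore, RegionSet

__all__ = [
    "EnrichmentSpec",
    "make_genome",
    "make_genes",
    "simulate_chip_reads",
    "simulate_spikein_pair",
    "simulate_expression",
    "write_expression",
]


@dataclass
class EnrichmentSpec:
    """Parameters of one simulated ChIP experiment.

    fold is the coverage multiplier inside each enriched region (scalar or
    per-region array, >= 1). global_fraction in [0, 1] multiplies all
    enrichment above background — it models a global loss of the mark, the
    quantity spike-in normalisation is designed to recover.
    """

    regions: RegionSet
    fold: float | np.ndarray = 10.0
    background_rate: float = 0.01  # reads per bp
    library_size: int | None = None
    read_length: int = 36
    global_fraction: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        fold = np.broadcast_to(np.asarray(self.fold, dtype=float),
                               (len(self.regions),)).copy()
        if np.any(fold < 1):
            raise ValueError("fold must be >= 1")
        self.fold = fold
        if not 0 <= self.global_fraction <= 1:
            raise ValueError("global_fraction must be in [0, 1]")


def make_genome(n_chroms: int, lengths, seed: int | None = None) -> GenomeTable:
    """Deterministic toy genome named chr1..chrN (seed kept for API symmetry)."""
    lengths = list(lengths)
    if len(lengths) != n_chroms:
        raise ValueError("need one length per chromosome")
    if any(l < 1 for l in lengths):
        raise ValueError("chromosome lengths must be positive")
    return GenomeTable(tuple((f"chr{i + 1}", int(l)) for i, l in enumerate(lengths)))


def make_genes(genome: GenomeTable, n_genes: int, gene_length: int = 2000,
               spacing: int = 8000, seed: int | None = None) -> GeneAnnotation:
    """Non-overlapping genes on a regular grid with random strands."""
    rng = np.random.default_rng(seed)
    chroms, starts, names, strands = [], [], [], []
    slots = []
    for chrom, L in genome.entries:
        pos = spacing // 2
        while pos + gene_length <= L:
            slots.append((chrom, pos))
            pos += spacing
    if len(slots) < n_genes:
        raise ValueError(f"genome too small for {n_genes} genes at spacing {spacing}")
    for i, (chrom, pos) in enumerate(slots[:n_genes]):
        chroms.append(chrom)
        starts.append(pos)
        names.append(f"gene{i}")
        strands.append("+" if rng.random() < 0.5 else "-")
    starts = np.array(starts, dtype=np.int64)
    return GeneAnnotation(np.array(chroms, dtype=object), starts,
                          starts + gene_length, np.array(names, dtype=object),
                          None, np.array(strands, dtype=object), genome)


def _uniform_reads(genome: GenomeTable, n_per_chrom: dict[str, int],
                   rng: np.random.Generator,
                   extra: dict[str, list[tuple[int, int, int]]] | None = None,
                   read_length: int = 36) -> ReadStore:
    """Place reads uniformly per chromosome plus optional (start, end, n) boosts."""
    chroms: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, L in genome.entries:
        pos_parts = []
        n_bg = n_per_chrom.get(chrom, 0)
        if n_bg:
            pos_parts.append(rng.integers(0, L, size=n_bg))
        for start, end, n in (extra or {}).get(chrom, []):
            if n:
                pos_parts.append(rng.integers(start, end, size=n))
        if not pos_parts:
            continue
        pos = np.concatenate(pos_parts)
        strand = rng.choice(np.array([1, -1], dtype=np.int8), size=len(pos))
        chroms[chrom] = (pos, strand)
    return ReadStore.from_arrays(chroms, read_length)


def simulate_chip_reads(spec: EnrichmentSpec, genome: GenomeTable,
                        rng: np.random.Generator | None = None) -> ReadStore:
    """Simulate a ChIP read set under the background + enrichment model.

    Expected background reads per chromosome are background_rate * length;
    each enriched region contributes an extra expectation of
    length * (fold - 1) * global_fraction * background_rate, so in-region
    coverage is fold-times background when global_fraction is 1. When
    library_size is set, the total is held exactly at library_size by a
    multinomial draw over these expectations.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    spec.regions.validate_against(genome)

    seg_chrom: list[str] = []
    seg_bounds: list[tuple[int, int]] = []
    weights: list[float] = []
    for chrom, L in genome.entries:
        seg_chrom.append(chrom)
        seg_bounds.append((0, L))
        weights.append(spec.background_rate * L)
    for i in range(len(spec.regions)):
        c = spec.regions.chroms[i]
        s, e = int(spec.regions.starts[i]), int(spec.regions.ends[i])
        seg_chrom.append(c)
        seg_bounds.append((s, e))
        weights.append(spec.background_rate * (e - s)
                       * (spec.fold[i] - 1.0) * spec.global_fraction)
    weights = np.asarray(weights, dtype=float)

    if spec.library_size is not None:
        if spec.library_size == 0:
            return ReadStore.from_arrays({}, spec.read_length)
        total = weights.sum()
        if total <= 0:
            raise ValueError("zero total placement weight")
        counts = rng.multinomial(spec.library_size, weights / total)
    else:
        counts = rng.poisson(weights)

    n_bg = {c: 0 for c in genome.names}
    extra: dict[str, list[tuple[int, int, int]]] = {}
    for chrom, (s, e), n in zip(seg_chrom, seg_bounds, counts):
        if s == 0 and e == genome[chrom]:
            n_bg[chrom] += int(n)
        else:
            extra.setdefault(chrom, []).append((s, e, int(n)))
    return _uniform_reads(genome, n_bg, rng, extra, spec.read_length)


def simulate_spikein_pair(spec: EnrichmentSpec, spike_library: int,
                          genome_target: GenomeTable,
                          genome_reference: GenomeTable,
                          rng: np.random.Generator | None = None
                          ) -> tuple[ReadStore, ReadStore]:
    """One condition of a spike-in experiment.

    The target read set scales its enriched signal with spec.global_fraction
    (the simulated retention level); the exogenous reference read count is
    held constant at spike_library across conditions, mimicking an equal
    chromatin spike added to every sample.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    target = simulate_chip_reads(spec, genome_target, rng)
    per_chrom_w = np.array([l for _, l in genome_reference.entries], dtype=float)
    counts = rng.multinomial(spike_library, per_chrom_w / per_chrom_w.sum())
    reference = _uniform_reads(
        genome_reference,
        {c: int(n) for (c, _), n in zip(genome_reference.entries, counts)},
        rng, read_length=spec.read_length)
    return target, reference


def simulate_expression(genes: GeneAnnotation, groups,
                        effect_pattern: dict | None = None,
                        seed: int | None = None,
                        base_mean: float = 5.0, base_sd: float = 2.0,
                        noise_sd: float = 0.5) -> pd.DataFrame:
    """log2-scale expression table, genes x groups.

    Each gene draws a baseline ~ N(base_mean, base_sd) shared across groups,
    plus per-group noise ~ N(0, noise_sd). effect_pattern maps a group name
    to (gene_names, shift): those genes gain `shift` log2 units in that group.
    """
    rng = np.random.default_rng(seed)
    names = [str(n) for n in genes.names]
    groups = list(groups)
    base = rng.normal(base_mean, base_sd, size=len(names))
    data = {}
    for g in groups:
        data[g] = base + rng.normal(0.0, noise_sd, size=len(names))
    df = pd.DataFrame(data, index=pd.Index(names, name="gene"))
    for g, (gene_set, shift) in (effect_pattern or {}).items():
        gene_set = [str(x) for x in gene_set]
        df.loc[df.index.isin(gene_set), g] += shift
    return df


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")
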