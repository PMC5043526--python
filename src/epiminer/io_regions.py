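"""Genomic interval containers, BED/genome-file IO, interval arithmetic and
alignment-file utilities.

All coordinates are 0-based half-open (BED convention) internally; conversion
to 1-based happens only in user-facing reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomeTable",
    "RegionSet",
    "GeneAnnotation",
    "ReadStore",
    "read_genome",
    "read_regions",
    "write_regions",
    "derive_promoters",
    "overlaps",
    "closest_feature",
    "random_regions",
    "extend_reads",
]


@dataclass(frozen=True)
class GenomeTable:
    """Chromosome name -> length table (two-column TSV on disk)."""

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome table")
        for name, length in self.entries:
            if not isinstance(length, (int, np.integer)) or length < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.entries)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.entries)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]

    @classmethod
    def from_tsv(cls, path) -> "GenomeTable":
        entries = []
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}:{i}: expected 2 tab-separated columns")
                entries.append((parts[0], int(parts[1])))
        return cls(tuple(entries))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self.entries:
                fh.write(f"{name}\t{length}\n")


def read_genome(path) -> GenomeTable:
    return GenomeTable.from_tsv(path)


# Track/browser lines that BED files may carry and we skip.
_BED_SKIP = ("track", "browser", "#")


@dataclass
class RegionSet:
    """Ordered genomic intervals with optional names/scores/strands.

    starts are 0-based inclusive, ends exclusive. Order is preserved as read.
    """

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    names: np.ndarray | None = None
    scores: np.ndarray | None = None
    strands: np.ndarray | None = None
    genome: GenomeTable | None = field(default=None, repr=False)

    def __post_init__(self):
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        for attr in ("names", "scores", "strands"):
            v = getattr(self, attr)
            if v is not None:
                setattr(self, attr, np.asarray(v, dtype=object))
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise ValueError("field length mismatch")
        if np.any(self.starts < 0):
            raise ValueError("negative start coordinate")
        if np.any(self.starts >= self.ends):
            bad = int(np.argmax(self.starts >= self.ends))
            raise ValueError(
                f"record {bad}: empty or inverted interval "
                f"{self.chroms[bad]}:{self.starts[bad]}-{self.ends[bad]}"
            )
        if self.genome is not None:
            self.validate_against(self.genome)

    def validate_against(self, genome: GenomeTable) -> None:
        lengths = genome.lengths
        for i in range(len(self)):
            c = self.chroms[i]
            if c not in lengths:
                raise ValueError(f"record {i}: unknown chromosome {c!r}")
            if self.ends[i] > lengths[c]:
                raise ValueError(
                    f"record {i}: {c}:{self.starts[i]}-{self.ends[i]} exceeds "
                    f"chromosome length {lengths[c]}"
                )

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def ids(self) -> list[str]:
        """Stable row identifiers: the BED name if present, else coords."""
        if self.names is not None:
            return [str(n) for n in self.names]
        return [f"{c}:{s}-{e}" for c, s, e in zip(self.chroms, self.starts, self.ends)]

    def subset(self, index) -> "RegionSet":
        index = np.asarray(index)
        if index.dtype != bool:
            index = index.astype(np.int64)
        return RegionSet(
            self.chroms[index],
            self.starts[index],
            self.ends[index],
            None if self.names is None else self.names[index],
            None if self.scores is None else self.scores[index],
            None if self.strands is None else self.strands[index],
        )

    @classmethod
    def from_records(cls, records, genome: GenomeTable | None = None) -> "RegionSet":
        """Build from (chrom, start, end[, name[, score[, strand]]]) tuples."""
        records = list(records)
        chroms = [r[0] for r in records]
        starts = [r[1] for r in records]
        ends = [r[2] for r in records]
        names = [r[3] for r in records] if records and len(records[0]) > 3 else None
        scores = [r[4] for r in records] if records and len(records[0]) > 4 else None
        strands = [r[5] for r in records] if records and len(records[0]) > 5 else None
        return cls(np.array(chroms, dtype=object), np.array(starts), np.array(ends),
                   names, scores, strands, genome)


class GeneAnnotation(RegionSet):
    """RegionSet where every record is named and stranded; provides TSS."""

    def __post_init__(self):
        super().__post_init__()
        if self.names is None or self.strands is None:
            raise ValueError("gene annotation requires name and strand columns")
        for i, s in enumerate(self.strands):
            if s not in ("+", "-"):
                raise ValueError(f"gene {self.names[i]!r}: strand must be + or -, got {s!r}")

    def tss(self) -> np.ndarray:
        """Transcription start site: start for + genes, end-1 for - genes."""
        minus = np.array([s == "-" for s in self.strands])
        return np.where(minus, self.ends - 1, self.starts)


def read_regions(path, genome: GenomeTable | None = None, *,
                 as_genes: bool = False) -> RegionSet:
    """Parse a BED3/BED6 file. Track/browser/comment lines are ignored."""
    chroms, starts, ends, names, scores, strands = [], [], [], [], [], []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or any(line.startswith(p) for p in _BED_SKIP):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            chroms.append(parts[0])
            starts.append(start)
            ends.append(end)
            if ncols is None:
                ncols = len(parts)
            if len(parts) > 3:
                names.append(parts[3])
            if len(parts) > 4:
                scores.append(parts[4])
            if len(parts) > 5:
                strands.append(parts[5])
    cls = GeneAnnotation if as_genes else RegionSet
    return cls(
        np.array(chroms, dtype=object),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        np.array(names, dtype=object) if len(names) == len(chroms) else None,
        np.array(scores, dtype=object) if len(scores) == len(chroms) else None,
        np.array(strands, dtype=object) if len(strands) == len(chroms) else None,
        genome,
    )


def write_regions(regions: RegionSet, path) -> None:
    """Write BED3 or BED6 depending on which optional columns are present."""
    n = len(regions)
    names = regions.names if regions.names is not None else np.array(["."] * n, dtype=object)
    scores = regions.scores if regions.scores is not None else np.array(["0"] * n, dtype=object)
    full = regions.strands is not None or regions.names is not None
    with open(path, "w") as fh:
        for i in range(n):
            if full:
                strand = regions.strands[i] if regions.strands is not None else "."
                fh.write(f"{regions.chroms[i]}\t{regions.starts[i]}\t{regions.ends[i]}"
                         f"\t{names[i]}\t{scores[i]}\t{strand}\n")
            else:
                fh.write(f"{regions.chroms[i]}\t{regions.starts[i]}\t{regions.ends[i]}\n")


def derive_promoters(genes: GeneAnnotation, flank: int = 2500,
                     genome: GenomeTable | None = None) -> RegionSet:
    """Promoter = [TSS - flank, TSS + flank), clipped to chromosome bounds.

    The 2.5 kb default matches the common promoter definition of regions
    both up- and downstream of the TSS.
    """
    tss = genes.tss()
    starts = np.maximum(tss - flank, 0)
    ends = tss + flank
    if genome is not None:
        lengths = genome.lengths
        for i, c in enumerate(genes.chroms):
            if c not in lengths:
                raise ValueError(f"gene {genes.names[i]!r} on unknown chromosome {c!r}")
        ends = np.minimum(ends, np.array([lengths[c] for c in genes.chroms]))
    return RegionSet(genes.chroms.copy(), starts, ends,
                     genes.names.copy(), None, genes.strands.copy())


def _by_chrom(regions: RegionSet) -> dict[str, np.ndarray]:
    out: dict[str, list[int]] = {}
    for i, c in enumerate(regions.chroms):
        out.setdefault(c, []).append(i)
    return {c: np.array(ix) for c, ix in out.items()}


def overlaps(a: RegionSet, b: RegionSet, min_bp: int = 1) -> np.ndarray:
    """Per-record-of-a boolean: does some b-record share >= min_bp bases."""
    result = np.zeros(len(a), dtype=bool)
    b_ix = _by_chrom(b)
    for chrom, ai in _by_chrom(a).items():
        if chrom not in b_ix:
            continue
        bi = b_ix[chrom]
        bs, be = b.starts[bi], b.ends[bi]
        order = np.argsort(bs)
        bs, be = bs[order], be[order]
        run_max_end = np.maximum.accumulate(be)
        for i in ai:
            s, e = a.starts[i], a.ends[i]
            # candidate window: b.start <= e - min_bp and running max end
            # already past s (run_max_end is nondecreasing)
            hi = np.searchsorted(bs, e - min_bp, side="right")
            lo = np.searchsorted(run_max_end, s + min_bp, side="left")
            if hi <= lo:
                continue
            ov = np.minimum(be[lo:hi], e) - np.maximum(bs[lo:hi], s)
            if ov.size and ov.max() >= min_bp:
                result[i] = True
    return result


def closest_feature(rois: RegionSet, genes: GeneAnnotation, *,
                    mode: str = "body") -> tuple[np.ndarray, np.ndarray]:
    """Assign each ROI to its closest gene.

    mode='body': distance 0 when the ROI overlaps the gene body, otherwise
    the minimal gap between intervals. mode='tss': distance from the nearest
    ROI edge to the gene TSS (0 when the TSS falls inside the ROI) — the
    convention used when linking clusters to expression. Ties break to the
    leftmost gene start, then lexicographic name. Distance is signed:
    negative when the ROI lies left of the feature.
    """
    if len(genes) == 0:
        raise ValueError("empty gene annotation")
    if mode not in ("body", "tss"):
        raise ValueError(f"unknown mode {mode!r}")
    out_names = np.empty(len(rois), dtype=object)
    out_dist = np.zeros(len(rois), dtype=np.int64)
    tss = genes.tss()
    g_ix = _by_chrom(genes)
    for chrom, ri in _by_chrom(rois).items():
        gi = g_ix.get(chrom)
        for i in ri:
            if gi is None:
                out_names[i] = None
                out_dist[i] = np.iinfo(np.int64).max
                continue
            s, e = rois.starts[i], rois.ends[i]
            if mode == "body":
                gs, ge = genes.starts[gi], genes.ends[gi]
                left_gap = gs - e          # >0 when gene strictly right of ROI
                right_gap = s - ge         # >0 when gene strictly left of ROI
                dist = np.where(left_gap > 0, left_gap, np.where(right_gap > 0, right_gap, 0))
                sign = np.where(left_gap > 0, 1, np.where(right_gap > 0, -1, 1))
            else:
                t = tss[gi]
                inside = (t >= s) & (t < e)
                dist = np.where(inside, 0, np.minimum(np.abs(t - s), np.abs(t - (e - 1))))
                sign = np.where(t >= e, 1, -1)
                sign = np.where(inside, 1, sign)
            best = np.lexsort((genes.names[gi].astype(str), genes.starts[gi], dist))[0]
            out_names[i] = genes.names[gi][best]
            out_dist[i] = sign[best] * dist[best]
    return out_names, out_dist


def random_regions(rois: RegionSet, genome: GenomeTable,
                   seed: int | np.random.Generator | None = None) -> RegionSet:
    """Shuffle region coordinates and chromosomes, preserving lengths.

    For each region, a chromosome is chosen with probability proportional to
    its number of valid start positions (length - region_length + 1), then a
    start is drawn uniformly among them — uniform over all valid placements.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    chrom_names = genome.names
    chrom_lengths = np.array([genome[c] for c in chrom_names], dtype=np.int64)
    lengths = rois.lengths
    out_chroms = np.empty(len(rois), dtype=object)
    out_starts = np.zeros(len(rois), dtype=np.int64)
    for i, L in enumerate(lengths):
        valid = chrom_lengths - L + 1
        valid = np.maximum(valid, 0)
        total = valid.sum()
        if total <= 0:
            raise ValueError(f"region of length {L} exceeds every chromosome")
        ci = rng.choice(len(chrom_names), p=valid / total)
        out_chroms[i] = chrom_names[ci]
        out_starts[i] = rng.integers(0, valid[ci])
    return RegionSet(out_chroms, out_starts, out_starts + lengths, genome=genome)


# ---------------------------------------------------------------------------
# Alignment files


def _keep_read(read, include_flagged: bool) -> bool:
    if read.is_unmapped:
        return False
    if include_flagged:
        return True
    return not (read.is_secondary or read.is_supplementary or read.is_duplicate
                or read.is_qcfail)


@dataclass
class ReadStore:
    """Per-chromosome 5' read positions and strands, the unit of counting.

    pos5 holds the 5' end of each read: reference_start on the + strand,
    reference_end - 1 on the - strand. Arrays are sorted by position.
    """

    chroms: dict[str, tuple[np.ndarray, np.ndarray]]  # chrom -> (pos5, strand ±1)
    read_length: int = 36

    @property
    def n_reads(self) -> int:
        return sum(len(p) for p, _ in self.chroms.values())

    @classmethod
    def from_arrays(cls, chroms: dict[str, tuple[np.ndarray, np.ndarray]],
                    read_length: int = 36) -> "ReadStore":
        ordered = {}
        for c, (pos, strand) in chroms.items():
            pos = np.asarray(pos, dtype=np.int64)
            strand = np.asarray(strand, dtype=np.int8)
            order = np.argsort(pos, kind="stable")
            ordered[c] = (pos[order], strand[order])
        return cls(ordered, read_length)

    @classmethod
    def from_alignments(cls, path, include_flagged: bool = False) -> "ReadStore":
        import pysam

        mode = "r" if str(path).endswith(".sam") else "rb"
        store: dict[str, list[tuple[int, int]]] = {}
        read_length = 36
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
            for read in fh.fetch(until_eof=True):
                if not _keep_read(read, include_flagged):
                    continue
                if read.is_reverse:
                    pos5, strand = read.reference_end - 1, -1
                else:
                    pos5, strand = read.reference_start, 1
                if read.query_length:
                    read_length = read.query_length
                elif read.reference_length:
                    read_length = read.reference_length
                store.setdefault(read.reference_name, []).append((pos5, strand))
        arrays = {
            c: (np.array([p for p, _ in v], dtype=np.int64),
                np.array([s for _, s in v], dtype=np.int8))
            for c, v in store.items()
        }
        return cls.from_arrays(arrays, read_length)

    def write_alignments(self, genome: GenomeTable, path) -> None:
        """Write as SAM or BAM (by extension); BAM is coordinate-sorted."""
        import pysam

        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": n, "LN": l} for n, l in genome.entries],
        }
        tid = {n: i for i, (n, _) in enumerate(genome.entries)}
        mode = "w" if str(path).endswith(".sam") else "wb"
        with pysam.AlignmentFile(str(path), mode, header=header) as out:
            counter = 0
            for chrom in genome.names:
                if chrom not in self.chroms:
                    continue
                pos, strand = self.chroms[chrom]
                L = genome[chrom]
                spans = []
                for p, s in zip(pos, strand):
                    if s > 0:
                        start = int(p)
                        end = min(start + self.read_length, L)
                    else:
                        end = int(p) + 1
                        start = max(end - self.read_length, 0)
                    spans.append((start, end, int(s)))
                spans.sort()  # BAM requires coordinate order by start
                for start, end, s in spans:
                    a = pysam.AlignedSegment()
                    a.reference_id = tid[chrom]
                    a.query_name = f"r{counter}"
                    a.reference_start = start
                    a.cigartuples = [(0, end - start)]
                    a.mapping_quality = 60
                    a.flag = 16 if s < 0 else 0
                    out.write(a)
                    counter += 1
        if mode == "wb":
            pysam.index(str(path))


def extend_reads(in_path, out_path, target_length: int, genome: GenomeTable,
                 include_flagged: bool = False) -> int:
    """Extend each aligned read from its 5' end to target_length (extBAM).

    Extension is strand-aware (toward 3'), clipped at chromosome bounds.
    Returns the number of reads written.
    """
    import pysam

    in_mode = "r" if str(in_path).endswith(".sam") else "rb"
    out_mode = "w" if str(out_path).endswith(".sam") else "wb"
    lengths = genome.lengths
    extended = []  # (tid, start, end, reverse, name, mapq); re-sorted below
    with pysam.AlignmentFile(str(in_path), in_mode, check_sq=False) as fh:
        header = fh.header.to_dict()
        for read in fh.fetch(until_eof=True):
            if not _keep_read(read, include_flagged):
                continue
            if target_length < (read.query_length or read.reference_length or 0):
                raise ValueError(
                    f"target_length {target_length} < read length "
                    f"{read.query_length or read.reference_length}"
                )
            L = lengths.get(read.reference_name)
            if L is None:
                raise ValueError(f"read on unknown chromosome {read.reference_name!r}")
            if read.is_reverse:
                end = read.reference_end
                start = max(end - target_length, 0)
            else:
                start = read.reference_start
                end = min(start + target_length, L)
            extended.append((read.reference_id, start, end, read.is_reverse,
                             read.query_name, read.mapping_quality))
    # minus-strand extension moves starts, so restore coordinate order
    extended.sort(key=lambda t: t[:2])
    with pysam.AlignmentFile(str(out_path), out_mode, header=header) as out:
        for tid, start, end, reverse, name, mapq in extended:
            a = pysam.AlignedSegment()
            a.query_name = name
            a.reference_id = tid
            a.reference_start = start
            a.cigartuples = [(0, end - start)]
            a.flag = 16 if reverse else 0
            a.mapping_quality = mapq
            out.write(a)
    if out_mode == "wb":
        pysam.index(str(out_path))
    return len(extended)
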