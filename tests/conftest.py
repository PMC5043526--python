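import numpy as np
import pytest

from epiminer.io_regions import GeneAnnotation, GenomeTable, RegionSet


@pytest.fixture
def toy_genome() -> GenomeTable:
    return GenomeTable((("chr1", 100_000), ("chr2", 50_000)))


@pytest.fixture
def toy_regions() -> RegionSet:
    return RegionSet.from_records([
        ("chr1", 1_000, 2_000, "r0"),
        ("chr1", 10_000, 12_000, "r1"),
        ("chr2", 5_000, 5_500, "r2"),
    ])


@pytest.fixture
def toy_genes() -> GeneAnnotation:
    return GeneAnnotation(
        np.array(["chr1", "chr1", "chr2"], dtype=object),
        np.array([10_000, 40_000, 8_000]),
        np.array([12_000, 45_000, 9_000]),
        np.array(["gA", "gB", "gC"], dtype=object),
        None,
        np.array(["+", "-", "+"], dtype=object),
    )
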