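import pytest

from regal.model import (
    Dataset,
    GenomicRegion,
    MetadataStore,
    RegionSchema,
    Sample,
)


def region(chrom, start, stop, strand="*", attrs=()):
    return GenomicRegion(chrom, start, stop, strand, tuple(attrs))


@pytest.fixture
def scored_dataset():
    """Two samples with a float score column and distinct target metadata."""
    schema = RegionSchema((("score", "float"),))
    s1 = Sample(
        "s1",
        [region("chr1", 0, 10, "+", (3.0,)), region("chr1", 20, 30, "-", (7.0,))],
        MetadataStore([("experiment_target", "H3K9ac"), ("cell", "K562")]),
    )
    s2 = Sample(
        "s2",
        [region("chr1", 5, 15, "*", (2.0,)), region("chr2", 0, 4, "+", (4.0,))],
        MetadataStore([("experiment_target", "CTCF"), ("cell", "HepG2")]),
    )
    return Dataset(schema, [s1, s2])


@pytest.fixture
def cover_dataset():
    """The three staggered intervals used throughout the cover examples."""
    s = Sample(
        "acc",
        [region("chr1", 1, 5), region("chr1", 3, 8), region("chr1", 6, 10)],
        MetadataStore([("source", "demo")]),
    )
    return Dataset(RegionSchema(), [s])
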