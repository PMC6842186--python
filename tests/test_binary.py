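import pytest

from regal.binary import (
    CROSS,
    DGE,
    DLE,
    MD,
    SamplePairing,
    op_difference,
    op_join,
    op_map,
    op_union,
    region_distance,
)
from regal.model import (
    Dataset,
    GenomicRegion,
    MetadataStore,
    RegionSchema,
    Sample,
    validate_dataset,
)
from regal.synth import oracle_min_distance
from regal.unary import AggregateSpec, OperatorError


def region(chrom, start, stop, strand="*", attrs=()):
    return GenomicRegion(chrom, start, stop, strand, tuple(attrs))


def one_sample(sid, regions, schema=RegionSchema(), meta=None):
    return Dataset(schema, [Sample(sid, regions, meta or MetadataStore())])


class TestRegionDistance:
    """Expected distances derived by listing the bases of each interval."""

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (region("chr1", 5, 10), region("chr1", 10, 15), 0),   # adjacent
            (region("chr1", 0, 10), region("chr1", 5, 8), -3),    # overlap 3
            (region("chr1", 0, 5), region("chr1", 8, 12), 3),     # gap {5,6,7}
            (region("chr1", 0, 5), region("chr2", 0, 5), None),   # other chrom
            (region("chr1", 7, 7), region("chr1", 5, 10), -0),    # empty inside
        ],
    )
    def test_examples(self, a, b, expected):
        assert region_distance(a, b) == expected
        if expected is not None:
            assert region_distance(b, a) == expected  # symmetry

    def test_negative_iff_sharing_a_base(self):
        import itertools

        for s1, s2 in itertools.product(range(0, 8), repeat=2):
            a = region("chr1", s1, s1 + 3)
            b = region("chr1", s2, s2 + 2)
            shared = set(range(a.start, a.stop)) & set(range(b.start, b.stop))
            d = region_distance(a, b)
            assert (d < 0) == bool(shared)
            if shared:
                assert -d == len(shared)


class TestJoin:
    def test_dle0_left_mode(self):
        left = one_sample("l", [region("chr1", 5, 10)])
        right = one_sample("r", [region("chr1", 10, 15), region("chr1", 12, 15),
                                 region("chr1", 3, 7)])
        out = op_join(left, right, DLE(0), output="LEFT")
        rows = [(r.start, r.stop, r.attrs[-1]) for r in out.samples[0].regions]
        assert rows == [(5, 10, -2), (5, 10, 0)]  # [3,7) then [10,15)

    def test_md1_picks_global_nearest(self):
        left = one_sample("l", [region("chr1", 100, 200)])
        cands = [region("chr1", 300, 400), region("chr1", 250, 260),
                 region("chr1", 0, 90)]
        right = one_sample("r", cands)
        out = op_join(left, right, MD(1), output="RIGHT")
        (r,) = out.samples[0].regions
        assert (r.start, r.stop, r.attrs[-1]) == (0, 90, 10)
        assert [c for c, _ in oracle_min_distance(
            left.samples[0].regions[0], cands, 1)] == [cands[2]]

    def test_md1_equidistant_tie_takes_smaller_start(self):
        left = one_sample("l", [region("chr1", 100, 200)])
        right = one_sample("r", [region("chr1", 205, 210),
                                 region("chr1", 90, 95)])
        out = op_join(left, right, MD(1), output="RIGHT")
        (r,) = out.samples[0].regions
        assert (r.start, r.stop) == (90, 95)  # both d=5; smaller start wins

    def test_md_conjunction_with_dge_excludes_overlaps(self):
        left = one_sample("l", [region("chr1", 100, 200)])
        right = one_sample("r", [region("chr1", 150, 160),
                                 region("chr1", 300, 310)])
        out = op_join(left, right, MD(1, dge=0), output="RIGHT")
        (r,) = out.samples[0].regions
        assert r.start == 300  # overlapping candidate ruled out by DGE(0)

    def test_int_mode_drops_non_overlapping_pairs(self):
        left = one_sample("l", [region("chr1", 0, 10)])
        right = one_sample("r", [region("chr1", 5, 15), region("chr1", 10, 20)])
        out = op_join(left, right, DLE(0), output="INT")
        rows = [(r.start, r.stop) for r in out.samples[0].regions]
        assert rows == [(5, 10)]  # adjacent pair survives DLE(0) but not INT

    def test_cat_mode_spans_both(self):
        left = one_sample("l", [region("chr1", 0, 10)])
        right = one_sample("r", [region("chr1", 20, 30)])
        out = op_join(left, right, DLE(100), output="CAT")
        (r,) = out.samples[0].regions
        assert (r.start, r.stop, r.attrs[-1]) == (0, 30, 10)

    def test_opposite_strands_never_match(self):
        left = one_sample("l", [region("chr1", 0, 10, "+")])
        right = one_sample("r", [region("chr1", 0, 10, "-")])
        assert op_join(left, right, DLE(0)).samples[0].regions == []
        out = op_join(left, right, DLE(0), ignore_strand=True)
        assert len(out.samples[0].regions) == 1

    def test_schema_prefixes_and_metadata_prefixes(self):
        schema = RegionSchema((("score", "float"),))
        left = one_sample("l", [region("chr1", 0, 10, "*", (1.0,))], schema,
                          MetadataStore([("cell", "K562")]))
        right = one_sample("r", [region("chr1", 0, 10, "*", (2.0,))], schema,
                           MetadataStore([("cell", "GM")]))
        out = op_join(left, right, DLE(0))
        assert out.schema.names == ("left.score", "right.score", "distance")
        (s,) = out.samples
        assert s.meta.get("left.cell") == {"K562"}
        assert s.meta.get("right.cell") == {"GM"}
        assert validate_dataset(out) == []

    def test_self_join_dle0_int_returns_self_overlap(self):
        ds = one_sample("a", [region("chr1", 3, 9), region("chr2", 0, 4)])
        out = op_join(ds, ds, DLE(0), output="INT")
        got = {(r.chrom, r.start, r.stop) for r in out.samples[0].regions}
        assert {("chr1", 3, 9), ("chr2", 0, 4)} <= got


class TestMap:
    def test_counts_against_brute_force(self):
        ref = one_sample("ref", [region("chr1", 0, 10)])
        exp = one_sample("exp", [region("chr1", 2, 4), region("chr1", 8, 12),
                                 region("chr1", 20, 30)])
        out = op_map(ref, exp)
        (r,) = out.samples[0].regions
        assert r.attrs == (2,)

    def test_avg_and_bag_aggregates(self):
        schema = RegionSchema((("signal", "float"), ("trait", "string")))
        ref = one_sample("ref", [region("chr1", 0, 10)])
        exp = one_sample("exp", [
            region("chr1", 2, 4, "*", (2.0, "asthma")),
            region("chr1", 5, 9, "*", (4.0, "T1D")),
        ], schema)
        out = op_map(ref, exp, aggs=[AggregateSpec("AVG", "signal", "avg"),
                                     AggregateSpec("BAG", "trait", "traits")])
        (r,) = out.samples[0].regions
        assert r.attrs == (2, 3.0, "T1D,asthma")

    def test_empty_overlap_defaults(self):
        schema = RegionSchema((("signal", "float"), ("trait", "string")))
        ref = one_sample("ref", [region("chr1", 0, 10)])
        exp = one_sample("exp", [region("chr2", 0, 5, "*", (1.0, "x"))], schema)
        out = op_map(ref, exp, aggs=[AggregateSpec("AVG", "signal", "avg"),
                                     AggregateSpec("BAG", "trait", "traits")])
        (r,) = out.samples[0].regions
        assert r.attrs == (0, None, "")

    def test_reference_regions_preserved_exactly(self, scored_dataset):
        ref = scored_dataset
        exp = one_sample("exp", [region("chr1", 0, 100)])
        out = op_map(ref, exp)
        for rs, os_ in zip(ref.samples, out.samples):
            assert [(r.chrom, r.start, r.stop, r.strand, r.attrs[:-1])
                    for r in os_.regions] == \
                   [(r.chrom, r.start, r.stop, r.strand, r.attrs)
                    for r in rs.regions]

    def test_tiling_references_conserve_counts(self):
        ref = one_sample("ref", [region("chr1", i, i + 100) for i in
                                 range(0, 1000, 100)])
        exp_regions = [region("chr1", s, s + 30) for s in
                       (0, 55, 170, 420, 421, 969)]
        exp = one_sample("exp", [r for r in exp_regions])
        out = op_map(ref, exp, ignore_strand=True)
        total = sum(r.attrs[-1] for r in out.samples[0].regions)
        # regions straddling a tile boundary are counted in both tiles
        straddlers = sum(1 for r in exp_regions
                         if r.start // 100 != (r.stop - 1) // 100)
        assert total == len(exp_regions) + straddlers


class TestPairing:
    def test_joinby_requires_shared_value_on_every_attribute(self):
        mk = lambda sid, cell: Sample(sid, [], MetadataStore([("cell", cell)]))
        left = [mk("a", "K562"), mk("b", "GM")]
        right = [mk("x", "K562"), mk("y", "HepG2")]
        pairs = SamplePairing(("cell",)).pairs(left, right)
        assert [(l.id, r.id) for l, r in pairs] == [("a", "x")]
        assert len(CROSS.pairs(left, right)) == 4


class TestUnionDifference:
    def test_union_counts_and_schema_reconciliation(self):
        sa = RegionSchema((("score", "integer"),))
        sb = RegionSchema((("score", "float"), ("name", "string")))
        a = Dataset(sa, [Sample("a1", [region("chr1", 0, 5, "*", (1,))]),
                         Sample("a2", [])])
        b = Dataset(sb, [Sample("b1", [region("chr1", 0, 5, "*", (2.0, "x"))])])
        out = op_union(a, b)
        assert len(out.samples) == 3
        assert out.schema.columns == (("score", "float"), ("name", "string"))
        assert out.samples[0].regions[0].attrs == (1.0, None)  # promoted + filled
        assert validate_dataset(out) == []

    def test_union_incompatible_types_error(self):
        a = Dataset(RegionSchema((("x", "string"),)), [])
        b = Dataset(RegionSchema((("x", "float"),)), [])
        with pytest.raises(OperatorError, match="incompatible"):
            op_union(a, b)

    def test_difference_keeps_non_overlapping_whole(self):
        a = one_sample("a", [region("chr1", 0, 10), region("chr1", 20, 30)])
        b = one_sample("b", [region("chr1", 25, 35)])
        out = op_difference(a, b)
        assert [(r.start, r.stop) for r in out.samples[0].regions] == [(0, 10)]
        assert out.samples[0].id == "a"  # id and metadata pass through

    def test_difference_with_empty_right_is_identity(self, scored_dataset):
        empty = Dataset(RegionSchema(), [])
        out = op_difference(scored_dataset, empty)
        for s, o in zip(scored_dataset.samples, out.samples):
            assert s.regions == o.regions

    def test_adjacent_regions_survive_difference(self):
        a = one_sample("a", [region("chr1", 0, 10)])
        b = one_sample("b", [region("chr1", 10, 20)])
        assert len(op_difference(a, b).samples[0].regions) == 1
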