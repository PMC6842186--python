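import pytest

from regal.model import (
    Dataset,
    GenomicRegion,
    MetadataStore,
    RegionSchema,
    Sample,
    validate_dataset,
)
from regal.synth import oracle_cover
from regal.unary import (
    ANY,
    AggregateSpec,
    CoverParams,
    MetaAttr,
    OperatorError,
    START,
    STOP,
    col,
    op_cover,
    op_extend,
    op_group,
    op_merge,
    op_order,
    op_project,
    op_select,
)


def region(chrom, start, stop, strand="*", attrs=()):
    return GenomicRegion(chrom, start, stop, strand, tuple(attrs))


class TestSelect:
    def test_meta_predicate_drops_whole_samples(self, scored_dataset):
        out = op_select(scored_dataset,
                        meta=MetaAttr("experiment_target") == "H3K9ac")
        assert [s.id for s in out.samples] == ["s1"]

    def test_region_predicate_drops_regions_but_keeps_sample(self, scored_dataset):
        out = op_select(scored_dataset, region=col("score") > 5)
        assert [len(s.regions) for s in out.samples] == [1, 0]
        assert [s.id for s in out.samples] == ["s1", "s2"]  # emptied retained

    def test_missing_attribute_means_false(self, scored_dataset):
        out = op_select(scored_dataset, meta=MetaAttr("nope") == "x")
        assert out.samples == []

    def test_any_value_semantics_and_numeric_comparators(self):
        m = MetadataStore([("age", "5"), ("age", "40"), ("age", "old")])
        assert (MetaAttr("age") > 30).evaluate(m)      # 40 satisfies
        assert not (MetaAttr("age") > 50).evaluate(m)  # "old" fails, not raises
        assert ((MetaAttr("age") == "old") & ~(MetaAttr("age") == "7")).evaluate(m)

    def test_unknown_region_column_is_an_error(self, scored_dataset):
        with pytest.raises(OperatorError, match="unknown"):
            op_select(scored_dataset, region=col("nope") > 1)

    def test_meta_select_is_idempotent(self, scored_dataset):
        pred = MetaAttr("cell") == "K562"
        once = op_select(scored_dataset, meta=pred)
        twice = op_select(once, meta=pred)
        assert [s.id for s in twice.samples] == [s.id for s in once.samples]


class TestProject:
    def test_promoter_window_on_minus_strand(self):
        ds = Dataset(RegionSchema(), [Sample("g", [region("chr1", 1000, 5000, "-")])])
        out = op_project(ds, new_coordinates=(START - 2000, START + 2000))
        (r,) = out.samples[0].regions
        assert (r.start, r.stop, r.strand) == (3000, 7000, "-")
        assert r.length == 4000

    def test_promoter_window_on_plus_strand_clips_at_zero(self):
        ds = Dataset(RegionSchema(), [Sample("g", [region("chr1", 1000, 5000, "+")])])
        out = op_project(ds, new_coordinates=(START - 2000, START + 2000))
        (r,) = out.samples[0].regions
        assert (r.start, r.stop) == (0, 3000)

    def test_midpoint_then_symmetric_extension(self):
        ds = Dataset(RegionSchema(), [Sample("p", [region("chr1", 10000, 10200)])])
        mid = op_project(ds, new_coordinates=((START + STOP) // 2,
                                              (START + STOP) // 2))
        assert mid.samples[0].regions[0].start == 10100
        assert mid.samples[0].regions[0].length == 0
        out = op_project(mid, new_coordinates=(START - 1500, STOP + 1500))
        (r,) = out.samples[0].regions
        assert (r.start, r.stop, r.length) == (8600, 11600, 3000)

    def test_entirely_negative_interval_dropped(self):
        ds = Dataset(RegionSchema(), [Sample("g", [region("chr1", 10, 20, "+")])])
        out = op_project(ds, new_coordinates=(START - 500, STOP - 500))
        assert out.samples[0].regions == []

    def test_identity_projection(self, scored_dataset):
        out = op_project(scored_dataset, keep_columns=["score"])
        assert out.schema == scored_dataset.schema
        for a, b in zip(scored_dataset.samples, out.samples):
            assert a.regions == b.regions

    def test_new_column_and_meta_keep(self, scored_dataset):
        out = op_project(scored_dataset,
                         new_columns=[("double", col("score") * 2)],
                         meta_keep=["cell"])
        assert out.schema.names == ("score", "double")
        assert out.samples[0].regions[0].attrs == (3.0, 6.0)
        assert out.samples[0].meta.attributes() == {"cell"}


class TestExtend:
    def test_count_and_avg(self, scored_dataset):
        out = op_extend(scored_dataset, [AggregateSpec("COUNT", name="region_count"),
                                         AggregateSpec("AVG", "score")])
        assert out.samples[0].meta.get("region_count") == {"2"}
        assert out.samples[0].meta.get("avg_score") == {"5.0"}

    def test_empty_sample_count_zero_avg_omitted(self):
        schema = RegionSchema((("score", "float"),))
        ds = Dataset(schema, [Sample("e", [])])
        out = op_extend(ds, [AggregateSpec("COUNT"),
                             AggregateSpec("AVG", "score")])
        assert out.samples[0].meta.get("count") == {"0"}
        assert "avg_score" not in out.samples[0].meta

    def test_numeric_aggregate_over_string_column_errors(self):
        schema = RegionSchema((("name", "string"),))
        ds = Dataset(schema, [Sample("a", [region("chr1", 0, 1, "*", ("x",))])])
        with pytest.raises(OperatorError, match="numeric"):
            op_extend(ds, [AggregateSpec("SUM", "name")])


class TestCover:
    """Expected intervals in these cases were derived from the per-base
    accumulation oracle over positions 0..10 and are asserted both frozen
    and against the oracle."""

    def expect(self, cover_dataset, variant, min_acc, max_acc):
        regions = cover_dataset.samples[0].regions
        return oracle_cover(regions, min_acc, max_acc, 11)[variant]

    def test_normal_min2(self, cover_dataset):
        out = op_cover(cover_dataset, CoverParams("normal", 2, ANY))
        got = [(r.start, r.stop) for r in out.samples[0].regions]
        assert got == [(3, 5), (6, 8)]
        assert got == self.expect(cover_dataset, "normal", 2, None)

    def test_histogram_min1(self, cover_dataset):
        out = op_cover(cover_dataset, CoverParams("histogram", 1, ANY))
        got = [(r.start, r.stop, r.attrs[0]) for r in out.samples[0].regions]
        assert got == [(1, 3, 1), (3, 5, 2), (5, 6, 1), (6, 8, 2), (8, 10, 1)]
        assert got == self.expect(cover_dataset, "histogram", 1, None)
        assert out.schema.columns == (("acc_index", "integer"),)

    def test_flat_min2(self, cover_dataset):
        out = op_cover(cover_dataset, CoverParams("flat", 2, ANY))
        got = [(r.start, r.stop) for r in out.samples[0].regions]
        assert got == [(1, 8), (3, 10)]
        assert got == self.expect(cover_dataset, "flat", 2, None)

    def test_summit_picks_local_maxima(self, cover_dataset):
        out = op_cover(cover_dataset, CoverParams("summit", 1, ANY))
        got = [(r.start, r.stop) for r in out.samples[0].regions]
        assert got == self.expect(cover_dataset, "summit", 1, None)
        assert got == [(3, 5), (6, 8)]  # the two acc=2 peaks

    def test_output_is_unstranded_and_valid(self, cover_dataset):
        out = op_cover(cover_dataset, CoverParams("normal", 1, ANY))
        assert all(r.strand == "*" for r in out.samples[0].regions)
        assert validate_dataset(out) == []

    def test_group_by_partitions_and_metadata(self):
        schema = RegionSchema()
        mk = lambda sid, cell, lo, hi: Sample(
            sid, [region("chr1", lo, hi)],
            MetadataStore([("cell", cell), ("assay", "chip")]))
        ds = Dataset(schema, [mk("a", "K562", 0, 10), mk("b", "K562", 5, 15),
                              mk("c", "GM", 100, 110)])
        out = op_cover(ds, CoverParams("normal", 1, ANY, group_by="cell"))
        assert [s.id for s in out.samples] == ["GM", "K562"]
        by_id = {s.id: s for s in out.samples}
        assert [(r.start, r.stop) for r in by_id["K562"].regions] == [(0, 15)]
        # common pairs survive; the grouping pair is attached
        assert by_id["K562"].meta.get("assay") == {"chip"}
        assert by_id["K562"].meta.get("cell") == {"K562"}

    def test_sample_missing_group_attribute_is_own_partition(self):
        ds = Dataset(RegionSchema(), [
            Sample("a", [region("chr1", 0, 10)], MetadataStore([("cell", "x")])),
            Sample("b", [region("chr1", 0, 10)], MetadataStore()),
        ])
        out = op_cover(ds, CoverParams("normal", 1, ANY, group_by="cell"))
        assert len(out.samples) == 2

    def test_bounds_validation(self):
        with pytest.raises(ValueError):
            CoverParams("normal", 3, 2)
        with pytest.raises(ValueError):
            CoverParams("normal", 0)


class TestMergeOrderGroup:
    def test_merge_keeps_duplicates_and_unions_metadata(self, scored_dataset):
        scored_dataset.samples[1].regions.append(
            scored_dataset.samples[0].regions[0])
        out = op_merge(scored_dataset)
        (s,) = out.samples
        assert len(s.regions) == 5  # 2 + 3, duplicate kept
        assert s.meta.get("experiment_target") == {"H3K9ac", "CTCF"}

    def test_merge_empty_dataset(self):
        assert op_merge(Dataset(RegionSchema(), [])).samples == []

    def test_order_numeric_ascending_with_top_k(self):
        mk = lambda sid, size: Sample(sid, [], MetadataStore([("size", size)]))
        ds = Dataset(RegionSchema(), [mk("x", "5"), mk("y", "1"), mk("z", "3")])
        out = op_order(ds, meta_keys=["size"], top_k=2)
        assert [s.id for s in out.samples] == ["y", "z"]
        assert out.samples[0].meta.get("order") == {"1"}

    def test_order_ties_break_by_sample_id(self):
        mk = lambda sid: Sample(sid, [], MetadataStore([("k", "1")]))
        ds = Dataset(RegionSchema(), [mk("b"), mk("a")])
        out = op_order(ds, meta_keys=["k"])
        assert [s.id for s in out.samples] == ["a", "b"]

    def test_order_top_k_zero_empties(self, scored_dataset):
        assert op_order(scored_dataset, meta_keys=["cell"], top_k=0).samples == []

    def test_group_by_metadata_value(self):
        mk = lambda sid, cell: Sample(
            sid, [region("chr1", 0, 5)], MetadataStore([("cell", cell)]))
        ds = Dataset(RegionSchema(), [mk("a", "A"), mk("b", "A"), mk("c", "B")])
        out = op_group(ds, "cell")
        assert [s.id for s in out.samples] == ["group.A", "group.B"]
        assert len(out.samples[0].regions) == 2

    def test_group_all_missing_forms_one_group(self):
        ds = Dataset(RegionSchema(), [Sample("a", []), Sample("b", [])])
        out = op_group(ds, "cell")
        assert len(out.samples) == 1


def test_algebra_outputs_validate(scored_dataset, cover_dataset):
    """Closure: every unary operator output passes validate_dataset."""
    outputs = [
        op_select(scored_dataset, meta=MetaAttr("cell") == "K562"),
        op_project(scored_dataset, new_columns=[("w", STOP - START)]),
        op_extend(scored_dataset, [AggregateSpec("COUNT")]),
        op_cover(cover_dataset, CoverParams("histogram", 1, ANY)),
        op_merge(scored_dataset),
        op_order(scored_dataset, meta_keys=["cell"]),
        op_group(scored_dataset, "cell"),
    ]
    for out in outputs:
        assert validate_dataset(out) == []
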