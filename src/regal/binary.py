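"""Two-dataset operators: genometric distance, join, map, union, difference,
and metadata-driven sample pairing.

"Intersecting" throughout means strict overlap (distance < 0); adjacency is
not intersection under the half-open convention — a DLE(0) join adds it back
explicitly.  Regions of opposite strands never match; ``*`` matches anything
(disable with ``ignore_strand=True``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from intervaltree import IntervalTree

from .model import (
    Dataset,
    GenomicRegion,
    MetadataStore,
    RegionSchema,
    Sample,
    merge_strands,
    sanitize_id,
    strand_compatible,
)
from .unary import AggregateSpec, OperatorError, unique_ids


# ---------------------------------------------------------------------------
# distance
# ---------------------------------------------------------------------------

def region_distance(a: GenomicRegion, b: GenomicRegion) -> Optional[int]:
    """Genometric distance in bp; None if the chromosomes differ.

    Negative iff the intervals strictly overlap (|d| = overlap length), zero
    iff adjacent, positive = gap length.  Symmetric.
    """
    if a.chrom != b.chrom:
        return None
    return max(a.start, b.start) - min(a.stop, b.stop)


@dataclass
class GenometricPredicate:
    """Distance-based join condition.

    ``dle``: keep pairs with distance <= bound; ``dge``: distance >= bound;
    ``md``: keep, per left region, only the ``md`` candidates at minimal
    |distance| (ties: smaller start, then smaller stop).  MD candidates must
    also satisfy any DLE/DGE bound.
    """

    dle: Optional[int] = None
    dge: Optional[int] = None
    md: Optional[int] = None

    def __post_init__(self):
        if self.md is not None and self.md < 1:
            raise ValueError("MD parameter must be >= 1")
        if self.dle is None and self.dge is None and self.md is None:
            raise ValueError("predicate needs at least one of dle/dge/md")

    def bounds_ok(self, d: int) -> bool:
        if self.dle is not None and d > self.dle:
            return False
        if self.dge is not None and d < self.dge:
            return False
        return True


def DLE(bound: int) -> GenometricPredicate:
    return GenometricPredicate(dle=bound)


def DGE(bound: int) -> GenometricPredicate:
    return GenometricPredicate(dge=bound)


def MD(k: int, dle: Optional[int] = None,
       dge: Optional[int] = None) -> GenometricPredicate:
    return GenometricPredicate(dle=dle, dge=dge, md=k)


# ---------------------------------------------------------------------------
# sample pairing
# ---------------------------------------------------------------------------

@dataclass
class SamplePairing:
    """Which (left, right) sample pairs a binary operator evaluates.

    With an empty ``joinby`` list every combination pairs (full cross
    product); otherwise a pair forms iff the two samples' value sets
    intersect on EVERY listed metadata attribute.  Pair order is
    deterministic: (left id, right id).
    """

    joinby: tuple = ()

    def pairs(self, left: Sequence[Sample], right: Sequence[Sample]) -> list:
        out = []
        for ls in sorted(left, key=lambda s: s.id):
            for rs in sorted(right, key=lambda s: s.id):
                if all(ls.meta.get(a) & rs.meta.get(a) for a in self.joinby):
                    out.append((ls, rs))
        return out


CROSS = SamplePairing()


def _pair_sample_id(left_id: str, right_id: str) -> str:
    return sanitize_id(f"{left_id}--{right_id}")


def _pair_metadata(ls: Sample, rs: Sample) -> MetadataStore:
    meta = MetadataStore()
    for a, v in ls.meta.pairs():
        meta.add(f"left.{a}", v)
    for a, v in rs.meta.pairs():
        meta.add(f"right.{a}", v)
    return meta


def _chrom_trees(regions: Sequence[GenomicRegion]):
    """Per-chromosome interval tree of the non-zero-length regions (a
    zero-length interval cannot strictly overlap anything)."""
    trees: dict = {}
    for r in regions:
        if r.start < r.stop:
            trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.stop, r)
    return trees


def _strand_ok(a: str, b: str, ignore_strand: bool) -> bool:
    return ignore_strand or strand_compatible(a, b)


# ---------------------------------------------------------------------------
# join
# ---------------------------------------------------------------------------

JOIN_MODES = ("LEFT", "RIGHT", "INT", "CAT")


def _join_coords(mode: str, l: GenomicRegion, r: GenomicRegion, d: int):
    """Output interval for a surviving pair, or None to drop it (INT mode on
    a non-overlapping pair)."""
    if mode == "LEFT":
        return l.start, l.stop, l.strand
    if mode == "RIGHT":
        return r.start, r.stop, r.strand
    if mode == "INT":
        if d >= 0:
            return None
        return max(l.start, r.start), min(l.stop, r.stop), merge_strands(l.strand, r.strand)
    return min(l.start, r.start), max(l.stop, r.stop), merge_strands(l.strand, r.strand)


def op_join(left: Dataset, right: Dataset, pred: GenometricPredicate,
            output: str = "LEFT", pairing: SamplePairing = CROSS,
            ignore_strand: bool = False) -> Dataset:
    """Genometric join: one output sample per sample pair; one output region
    per surviving region pair, carrying both sides' columns under ``left.`` /
    ``right.`` prefixes plus the pair's ``distance``.

    Candidate right regions live on the left region's chromosome with a
    compatible strand; a DLE bound prunes candidates through an interval-tree
    window query, otherwise all same-chromosome regions are scanned.
    """
    if output not in JOIN_MODES:
        raise OperatorError(f"unknown join output mode {output!r}")
    schema = RegionSchema(
        tuple((f"left.{n}", t) for n, t in left.schema.columns)
        + tuple((f"right.{n}", t) for n, t in right.schema.columns)
        + (("distance", "integer"),)
    )
    out_samples = []
    for ls, rs in pairing.pairs(left.samples, right.samples):
        by_chrom: dict = {}
        for r in rs.regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        trees = _chrom_trees(rs.regions)
        regions = []
        for l in sorted(ls.regions, key=GenomicRegion.sort_key):
            if pred.dle is not None:
                hits = trees.get(l.chrom, IntervalTree()).overlap(
                    l.start - pred.dle - 1, l.stop + pred.dle + 1
                )
                candidates = [iv.data for iv in hits]
                # zero-length right regions are not in the tree
                candidates += [
                    r for r in by_chrom.get(l.chrom, ())
                    if r.start == r.stop
                ]
            else:
                candidates = by_chrom.get(l.chrom, [])
            matches = []
            for r in candidates:
                if not _strand_ok(l.strand, r.strand, ignore_strand):
                    continue
                d = region_distance(l, r)
                if d is None or not pred.bounds_ok(d):
                    continue
                matches.append((d, r))
            # repr(attrs) only breaks ties between coordinate-identical
            # candidates, keeping output order process-independent
            if pred.md is not None:
                matches.sort(key=lambda dr: (abs(dr[0]), dr[1].start,
                                             dr[1].stop, repr(dr[1].attrs)))
                matches = matches[: pred.md]
            else:
                matches.sort(key=lambda dr: (dr[1].sort_key(),
                                             repr(dr[1].attrs)))
            for d, r in matches:
                coords = _join_coords(output, l, r, d)
                if coords is None:
                    continue
                start, stop, strand = coords
                regions.append(GenomicRegion(
                    l.chrom, start, stop, strand, l.attrs + r.attrs + (d,)
                ))
        out_samples.append(Sample(
            _pair_sample_id(ls.id, rs.id), regions, _pair_metadata(ls, rs)
        ))
    unique_ids(out_samples)
    return Dataset(schema, out_samples)


# ---------------------------------------------------------------------------
# map
# ---------------------------------------------------------------------------

def op_map(reference: Dataset, experiment: Dataset,
           aggs: Sequence[AggregateSpec] = (),
           pairing: SamplePairing = CROSS,
           ignore_strand: bool = False,
           count_name: str = "count") -> Dataset:
    """Aggregate, per reference region, over the experiment regions that
    strictly overlap it; one output sample per sample pair.

    Output regions are exactly the reference sample's regions (coordinates,
    strand, columns preserved); a COUNT column is always added, then one
    column per aggregate.  Empty overlap sets yield count 0, missing numeric
    values, and an empty BAG string.
    """
    agg_cols = tuple(
        (a.name, a.output_type(experiment.schema)) for a in aggs
    )
    schema = RegionSchema(
        reference.schema.columns + ((count_name, "integer"),) + agg_cols
    )
    out_samples = []
    for ls, rs in pairing.pairs(reference.samples, experiment.samples):
        trees = _chrom_trees(rs.regions)
        regions = []
        for ref in ls.regions:
            overlapping = []
            if ref.start < ref.stop and ref.chrom in trees:
                for iv in trees[ref.chrom].overlap(ref.start, ref.stop):
                    if _strand_ok(ref.strand, iv.data.strand, ignore_strand):
                        overlapping.append(iv.data)
            overlapping.sort(key=lambda r: (r.sort_key(), repr(r.attrs)))
            attrs = list(ref.attrs) + [len(overlapping)]
            for a in aggs:
                value = a.compute(overlapping, experiment.schema)
                if value is not None and a.func == "AVG":
                    value = float(value)
                attrs.append(value)
            regions.append(GenomicRegion(
                ref.chrom, ref.start, ref.stop, ref.strand, tuple(attrs)
            ))
        out_samples.append(Sample(
            _pair_sample_id(ls.id, rs.id), regions, _pair_metadata(ls, rs)
        ))
    unique_ids(out_samples)
    return Dataset(schema, out_samples)


# ---------------------------------------------------------------------------
# union
# ---------------------------------------------------------------------------

def _reconcile_schemas(a: RegionSchema, b: RegionSchema) -> RegionSchema:
    cols = list(a.columns)
    names = {n: i for i, (n, _) in enumerate(cols)}
    for n, t in b.columns:
        if n not in names:
            cols.append((n, t))
            continue
        ta = cols[names[n]][1]
        if ta == t:
            continue
        if {ta, t} == {"integer", "float"}:
            cols[names[n]] = (n, "float")  # numeric promotion
        else:
            raise OperatorError(
                f"union: column {n!r} has incompatible types {ta} vs {t}"
            )
    return RegionSchema(tuple(cols))


def _remap_attrs(r: GenomicRegion, src: RegionSchema,
                 dst: RegionSchema) -> tuple:
    by_name = dict(zip(src.names, r.attrs))
    out = []
    for n, t in dst.columns:
        v = by_name.get(n)
        if v is not None and t == "float" and isinstance(v, int):
            v = float(v)
        out.append(v)
    return tuple(out)


def op_union(a: Dataset, b: Dataset) -> Dataset:
    """All samples of both datasets; schemas reconciled by column name
    (columns absent on one side are filled with a missing value); sample ids
    disambiguated with ``left.`` / ``right.`` prefixes."""
    schema = _reconcile_schemas(a.schema, b.schema)
    out = []
    for side, ds in (("left", a), ("right", b)):
        for s in ds.samples:
            regions = [
                r.with_attrs(_remap_attrs(r, ds.schema, schema))
                for r in s.regions
            ]
            out.append(Sample(sanitize_id(f"{side}.{s.id}"), regions,
                              s.meta.copy()))
    unique_ids(out)
    return Dataset(schema, out)


# ---------------------------------------------------------------------------
# difference
# ---------------------------------------------------------------------------

def op_difference(a: Dataset, b: Dataset,
                  pairing: SamplePairing = CROSS,
                  ignore_strand: bool = False) -> Dataset:
    """Per a-sample, keep whole the regions that strictly overlap no region
    of any paired b-sample; sample ids and metadata pass through unchanged."""
    pair_map: dict = {}
    for ls, rs in pairing.pairs(a.samples, b.samples):
        pair_map.setdefault(ls.id, []).append(rs)
    out = []
    for s in a.samples:
        others = [r for rs in pair_map.get(s.id, ()) for r in rs.regions]
        trees = _chrom_trees(others)
        kept = []
        for r in s.regions:
            hit = False
            if r.start < r.stop and r.chrom in trees:
                hit = any(
                    _strand_ok(r.strand, iv.data.strand, ignore_strand)
                    for iv in trees[r.chrom].overlap(r.start, r.stop)
                )
            if not hit:
                kept.append(r)
        out.append(Sample(s.id, kept, s.meta.copy()))
    return Dataset(a.schema, out)
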