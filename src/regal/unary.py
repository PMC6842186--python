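"""Single-dataset operators: select, project, extend, the cover family,
merge, order and group — plus the predicate / expression / aggregate
primitives they share with the binary operators.

Every operator is a pure ``Dataset -> Dataset`` function; the lazy query
layer (:mod:`regal.dag`) wraps them into DAG nodes.  Operators never mutate
their input (region objects are immutable and may be shared between the
input and the output of an operator).
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import (
    Dataset,
    GenomicRegion,
    MetadataStore,
    RegionSchema,
    Sample,
    sanitize_id,
    sort_regions,
)

logger = logging.getLogger("regal.unary")

#: Sentinel for an unbounded maximum accumulation in cover.
ANY = None

MISSING_GROUP = "_missing_"


class OperatorError(ValueError):
    """Ill-formed operator parameters detected at evaluation time."""


def unique_ids(samples: Sequence[Sample]) -> None:
    """Disambiguate duplicate sample ids in place (append .2, .3, ...)."""
    seen: dict = {}
    for s in samples:
        n = seen.get(s.id, 0) + 1
        seen[s.id] = n
        if n > 1:
            s.id = f"{s.id}.{n}"


# ---------------------------------------------------------------------------
# metadata predicates
# ---------------------------------------------------------------------------

_NUMERIC_OPS = ("<", "<=", ">", ">=")


class MetaPredicate:
    """Boolean combination of metadata atoms, evaluable on a MetadataStore."""

    def evaluate(self, store: MetadataStore) -> bool:  # pragma: no cover
        raise NotImplementedError

    def __and__(self, other):
        return _MetaBool("and", self, other)

    def __or__(self, other):
        return _MetaBool("or", self, other)

    def __invert__(self):
        return _MetaNot(self)


class MetaAtom(MetaPredicate):
    """(attribute, comparator, constant).

    True iff ANY value of the attribute satisfies the comparison; a missing
    attribute makes the atom false.  Ordering comparators parse both sides
    as numbers on demand; an unparsable value fails the comparison for that
    value (it does not raise).  Equality comparators compare as strings.
    """

    def __init__(self, attr: str, op: str, const):
        if op not in ("==", "!=") + _NUMERIC_OPS:
            raise ValueError(f"unknown comparator {op!r}")
        self.attr, self.op, self.const = attr, op, str(const)

    def _test(self, value: str) -> bool:
        op = self.op
        if op == "==":
            return value == self.const
        if op == "!=":
            return value != self.const
        try:
            v, c = float(value), float(self.const)
        except ValueError:
            return False
        return {"<": v < c, "<=": v <= c, ">": v > c, ">=": v >= c}[op]

    def evaluate(self, store: MetadataStore) -> bool:
        return any(self._test(v) for v in store.get(self.attr))

    def __repr__(self):
        return f"({self.attr} {self.op} {self.const!r})"


class _MetaBool(MetaPredicate):
    def __init__(self, op, left, right):
        self.op, self.left, self.right = op, left, right

    def evaluate(self, store):
        if self.op == "and":
            return self.left.evaluate(store) and self.right.evaluate(store)
        return self.left.evaluate(store) or self.right.evaluate(store)


class _MetaNot(MetaPredicate):
    def __init__(self, inner):
        self.inner = inner

    def evaluate(self, store):
        return not self.inner.evaluate(store)


class MetaAttr:
    """Builder: ``MetaAttr("experiment_target") == "H3K9ac"`` yields an atom."""

    def __init__(self, attr: str):
        self.attr = attr

    def __eq__(self, const):  # type: ignore[override]
        return MetaAtom(self.attr, "==", const)

    def __ne__(self, const):  # type: ignore[override]
        return MetaAtom(self.attr, "!=", const)

    def __lt__(self, const):
        return MetaAtom(self.attr, "<", const)

    def __le__(self, const):
        return MetaAtom(self.attr, "<=", const)

    def __gt__(self, const):
        return MetaAtom(self.attr, ">", const)

    def __ge__(self, const):
        return MetaAtom(self.attr, ">=", const)

    __hash__ = None  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# region expressions and predicates
# ---------------------------------------------------------------------------

class RegionExpr:
    """Arithmetic over the strand-aware coordinate accessors ``START`` /
    ``STOP``, schema columns and constants; evaluates to one number per
    region.

    On the ``-`` strand the accessors refer to the 5' and 3' genomic
    boundaries respectively, so expressions read in transcription order.
    """

    def evaluate(self, ctx: dict):  # pragma: no cover
        raise NotImplementedError

    def columns(self) -> set:
        return set()

    def _bin(self, op, other, swap=False):
        other = other if isinstance(other, RegionExpr) else Const(other)
        return _BinExpr(op, other, self) if swap else _BinExpr(op, self, other)

    def __add__(self, o):
        return self._bin("+", o)

    def __radd__(self, o):
        return self._bin("+", o, swap=True)

    def __sub__(self, o):
        return self._bin("-", o)

    def __rsub__(self, o):
        return self._bin("-", o, swap=True)

    def __mul__(self, o):
        return self._bin("*", o)

    def __rmul__(self, o):
        return self._bin("*", o, swap=True)

    def __truediv__(self, o):
        return self._bin("/", o)

    def __rtruediv__(self, o):
        return self._bin("/", o, swap=True)

    def __floordiv__(self, o):
        return self._bin("//", o)

    def __neg__(self):
        return _BinExpr("-", Const(0), self)

    def _cmp(self, op, other):
        other = other if isinstance(other, RegionExpr) else Const(other)
        return RegionAtom(self, op, other)

    def __eq__(self, o):  # type: ignore[override]
        return self._cmp("==", o)

    def __ne__(self, o):  # type: ignore[override]
        return self._cmp("!=", o)

    def __lt__(self, o):
        return self._cmp("<", o)

    def __le__(self, o):
        return self._cmp("<=", o)

    def __gt__(self, o):
        return self._cmp(">", o)

    def __ge__(self, o):
        return self._cmp(">=", o)

    __hash__ = None  # type: ignore[assignment]


class Const(RegionExpr):
    def __init__(self, value):
        self.value = value

    def evaluate(self, ctx):
        return self.value


class _Accessor(RegionExpr):
    def __init__(self, which: str):
        self.which = which  # "start" | "stop"

    def evaluate(self, ctx):
        return ctx[self.which]


class Column(RegionExpr):
    def __init__(self, name: str):
        self.name = name

    def evaluate(self, ctx):
        try:
            return ctx["columns"][self.name]
        except KeyError:
            raise OperatorError(f"unknown schema column {self.name!r}") from None

    def columns(self):
        return {self.name}


class _BinExpr(RegionExpr):
    def __init__(self, op, left, right):
        self.op, self.left, self.right = op, left, right

    def evaluate(self, ctx):
        a, b = self.left.evaluate(ctx), self.right.evaluate(ctx)
        if a is None or b is None:
            return None
        if self.op == "+":
            return a + b
        if self.op == "-":
            return a - b
        if self.op == "*":
            return a * b
        if b == 0 and self.op in ("/", "//"):
            raise OperatorError(
                f"division by zero in region expression at {ctx.get('where')}"
            )
        return a / b if self.op == "/" else a // b

    def columns(self):
        return self.left.columns() | self.right.columns()


#: Strand-aware 5' boundary accessor (genomic stop on the ``-`` strand).
START = _Accessor("start")
#: Strand-aware 3' boundary accessor (genomic start on the ``-`` strand).
STOP = _Accessor("stop")


def col(name: str) -> Column:
    return Column(name)


class RegionPredicate:
    """Boolean combination of region-expression comparisons."""

    def evaluate(self, ctx) -> bool:  # pragma: no cover
        raise NotImplementedError

    def columns(self) -> set:
        return set()

    def __and__(self, other):
        return _RegionBool("and", self, other)

    def __or__(self, other):
        return _RegionBool("or", self, other)

    def __invert__(self):
        return _RegionNot(self)


class RegionAtom(RegionPredicate):
    def __init__(self, left: RegionExpr, op: str, right: RegionExpr):
        self.left, self.op, self.right = left, op, right

    def evaluate(self, ctx):
        a, b = self.left.evaluate(ctx), self.right.evaluate(ctx)
        if a is None or b is None:
            return False
        return {
            "==": a == b, "!=": a != b, "<": a < b,
            "<=": a <= b, ">": a > b, ">=": a >= b,
        }[self.op]

    def columns(self):
        return self.left.columns() | self.right.columns()


class _RegionBool(RegionPredicate):
    def __init__(self, op, left, right):
        self.op, self.left, self.right = op, left, right

    def evaluate(self, ctx):
        if self.op == "and":
            return self.left.evaluate(ctx) and self.right.evaluate(ctx)
        return self.left.evaluate(ctx) or self.right.evaluate(ctx)

    def columns(self):
        return self.left.columns() | self.right.columns()


class _RegionNot(RegionPredicate):
    def __init__(self, inner):
        self.inner = inner

    def evaluate(self, ctx):
        return not self.inner.evaluate(ctx)

    def columns(self):
        return self.inner.columns()


def _value_ctx(region: GenomicRegion, schema: RegionSchema) -> dict:
    """Expression context for value computation: accessors resolve to the 5'
    and 3' genomic boundaries of the region."""
    if region.strand == "-":
        start, stop = region.stop, region.start
    else:
        start, stop = region.start, region.stop
    return {
        "start": start,
        "stop": stop,
        "columns": dict(zip(schema.names, region.attrs)),
        "where": f"{region.chrom}:{region.start}-{region.stop}",
    }


def _coordinate_ctx(region: GenomicRegion, schema: RegionSchema) -> dict:
    """Expression context for coordinate recomputation.

    On the ``-`` strand the genome is reflected (g -> -g) so that the
    accessors read 5'->3' and additive offsets act in the transcription
    direction; results are reflected back by the caller.
    """
    ctx = _value_ctx(region, schema)
    if region.strand == "-":
        ctx["start"], ctx["stop"] = -region.stop, -region.start
    return ctx


# ---------------------------------------------------------------------------
# aggregates
# ---------------------------------------------------------------------------

AGG_FUNCS = ("COUNT", "SUM", "AVG", "MIN", "MAX", "BAG")


@dataclass
class AggregateSpec:
    """One aggregate over a group of regions.

    ``COUNT`` needs no source column.  ``SUM/AVG/MIN/MAX`` require a numeric
    column.  ``BAG`` joins the sorted string values with commas (duplicates
    preserved); over an empty group it yields the empty string, while the
    numeric aggregates yield a missing value.
    """

    func: str
    column: Optional[str] = None
    name: Optional[str] = None

    def __post_init__(self):
        if self.func not in AGG_FUNCS:
            raise ValueError(f"unknown aggregate {self.func!r}")
        if self.func != "COUNT" and self.column is None:
            raise ValueError(f"{self.func} needs a source column")
        if self.name is None:
            self.name = (
                self.func.lower() if self.func == "COUNT"
                else f"{self.func.lower()}_{self.column}"
            )

    def output_type(self, schema: RegionSchema) -> str:
        if self.func == "COUNT":
            return "integer"
        if self.func == "BAG":
            return "string"
        src = schema.type_of(self.column)
        if src == "string":
            raise OperatorError(
                f"{self.func} requires a numeric column, {self.column!r} is string"
            )
        if self.func in ("SUM", "MIN", "MAX"):
            return src
        return "float"  # AVG

    def compute(self, regions: Sequence[GenomicRegion], schema: RegionSchema):
        """Aggregate value over ``regions``; None for an empty numeric group."""
        if self.func == "COUNT":
            return len(regions)
        idx = schema.index(self.column)
        values = [r.attrs[idx] for r in regions if r.attrs[idx] is not None]
        if self.func == "BAG":
            return ",".join(sorted(str(v) for v in values))
        self.output_type(schema)  # numeric-column check
        if not values:
            return None
        if self.func == "SUM":
            return sum(values)
        if self.func == "AVG":
            return sum(values) / len(values)
        return min(values) if self.func == "MIN" else max(values)


# ---------------------------------------------------------------------------
# select
# ---------------------------------------------------------------------------

def op_select(ds: Dataset, meta: Optional[MetaPredicate] = None,
              region: Optional[RegionPredicate] = None) -> Dataset:
    """Metadata predicate drops whole samples; region predicate drops
    individual regions within the surviving samples.  A sample emptied by the
    region predicate is retained (metadata-only traceability)."""
    if region is not None:
        unknown = region.columns() - set(ds.schema.names)
        if unknown:
            raise OperatorError(
                f"region predicate references unknown columns {sorted(unknown)}"
            )
    out = []
    for s in ds.samples:
        if meta is not None and not meta.evaluate(s.meta):
            continue
        regions = s.regions
        if region is not None:
            regions = [
                r for r in regions
                if region.evaluate(_value_ctx(r, ds.schema))
            ]
        out.append(Sample(s.id, list(regions), s.meta.copy()))
    return Dataset(ds.schema, out)


# ---------------------------------------------------------------------------
# project
# ---------------------------------------------------------------------------

def op_project(ds: Dataset,
               new_columns: Optional[Sequence] = None,
               keep_columns: Optional[Sequence] = None,
               new_coordinates: Optional[tuple] = None,
               meta_keep: Optional[Sequence] = None) -> Dataset:
    """Project region attributes and/or recompute coordinates.

    ``new_columns``: (name, RegionExpr) pairs evaluated per region on the
    original coordinates; results are float columns.
    ``keep_columns``: names of existing columns to retain (None keeps all).
    ``new_coordinates``: (start_expr, stop_expr) evaluated strand-aware (see
    :func:`_coordinate_ctx`); the two boundaries are then normalised so left
    <= right and clipped at 0; a region whose recomputed interval lies
    entirely below 0 is dropped (logged).  Strand is preserved.
    ``meta_keep``: metadata attributes to retain (None keeps all).
    """
    new_columns = list(new_columns or [])
    if keep_columns is None:
        kept = list(ds.schema.names)
    else:
        kept = list(keep_columns)
        for name in kept:
            ds.schema.index(name)  # raise on unknown
    schema = RegionSchema(
        tuple((n, ds.schema.type_of(n)) for n in kept)
        + tuple((n, "float") for n, _ in new_columns)
    )
    kept_idx = [ds.schema.index(n) for n in kept]
    out_samples = []
    dropped = 0
    for s in ds.samples:
        regions = []
        for r in s.regions:
            attrs = [r.attrs[i] for i in kept_idx]
            for _, expr in new_columns:
                v = expr.evaluate(_value_ctx(r, ds.schema))
                attrs.append(None if v is None else float(v))
            if new_coordinates is None:
                regions.append(GenomicRegion(r.chrom, r.start, r.stop,
                                             r.strand, tuple(attrs)))
                continue
            ctx = _coordinate_ctx(r, ds.schema)
            start_e, stop_e = new_coordinates
            a = int(start_e.evaluate(ctx))
            b = int(stop_e.evaluate(ctx))
            if r.strand == "-":
                a, b = -a, -b
            left, right = min(a, b), max(a, b)
            if right <= 0 and left < 0:
                dropped += 1
                continue
            left = max(left, 0)
            regions.append(GenomicRegion(r.chrom, left, right,
                                         r.strand, tuple(attrs)))
        if meta_keep is None:
            meta = s.meta.copy()
        else:
            meta = MetadataStore(
                (a, v) for a, v in s.meta.pairs() if a in set(meta_keep)
            )
        out_samples.append(Sample(s.id, regions, meta))
    if dropped:
        logger.warning("project: dropped %d regions with entirely negative "
                       "recomputed intervals", dropped)
    return Dataset(schema, out_samples)


# ---------------------------------------------------------------------------
# extend
# ---------------------------------------------------------------------------

def op_extend(ds: Dataset, aggs: Sequence[AggregateSpec]) -> Dataset:
    """Add one metadata pair per aggregate, computed over each sample's own
    regions; regions are unchanged.  An empty numeric aggregate (e.g. AVG of
    zero regions) omits the pair rather than emitting NaN."""
    out = []
    for s in ds.samples:
        meta = s.meta.copy()
        for agg in aggs:
            value = agg.compute(s.regions, ds.schema)
            if value is None:
                continue
            meta.add(agg.name, str(value))
        out.append(Sample(s.id, list(s.regions), meta))
    return Dataset(ds.schema, out)


# ---------------------------------------------------------------------------
# cover
# ---------------------------------------------------------------------------

COVER_VARIANTS = ("normal", "flat", "summit", "histogram")


@dataclass
class CoverParams:
    """Accumulation bounds and optional metadata grouping for cover.

    ``max_acc=None`` (exported as ``ANY``) means unbounded.
    """

    variant: str = "normal"
    min_acc: int = 1
    max_acc: Optional[int] = ANY
    group_by: Optional[str] = None

    def __post_init__(self):
        if self.variant not in COVER_VARIANTS:
            raise ValueError(f"unknown cover variant {self.variant!r}")
        if self.min_acc < 1:
            raise ValueError("min_acc must be a positive integer")
        if self.max_acc is not None and self.min_acc > self.max_acc:
            raise ValueError("min_acc must not exceed max_acc")


def _accumulation_runs(regions: Sequence[GenomicRegion]) -> list:
    """Maximal constant-accumulation runs (start, stop, acc) with acc > 0,
    from a boundary sweep over all (non-zero-length) intervals; strand and
    duplicates are counted as-is."""
    deltas: dict = {}
    for r in regions:
        if r.start < r.stop:
            deltas[r.start] = deltas.get(r.start, 0) + 1
            deltas[r.stop] = deltas.get(r.stop, 0) - 1
    runs = []
    acc = 0
    prev = None
    for pos in sorted(deltas):
        if acc > 0 and prev is not None and pos > prev:
            if runs and runs[-1][1] == prev and runs[-1][2] == acc:
                runs[-1] = (runs[-1][0], pos, acc)  # merge equal-acc neighbours
            else:
                runs.append((prev, pos, acc))
        acc += deltas[pos]
        prev = pos
    return runs


def _qualifies(acc: int, p: CoverParams) -> bool:
    return acc >= p.min_acc and (p.max_acc is None or acc <= p.max_acc)


def _cover_chrom(regions: list, p: CoverParams) -> list:
    """Cover one chromosome; returns (start, stop, acc-or-None) tuples."""
    runs = _accumulation_runs(regions)
    qual = [run for run in runs if _qualifies(run[2], p)]
    # chains of contiguous qualifying runs = the normal-variant regions
    blocks: list = []
    for run in qual:
        if blocks and blocks[-1][-1][1] == run[0]:
            blocks[-1].append(run)
        else:
            blocks.append([run])
    if p.variant == "histogram":
        return [(s, e, a) for s, e, a in qual]
    if p.variant == "normal":
        return [(b[0][0], b[-1][1], None) for b in blocks]
    if p.variant == "summit":
        out = []
        for b in blocks:
            for i, (s, e, a) in enumerate(b):
                left_ok = i == 0 or b[i - 1][2] <= a
                right_ok = i == len(b) - 1 or b[i + 1][2] <= a
                if left_ok and right_ok:
                    out.append((s, e, None))
        return out
    # flat: extent of all input regions strictly overlapping each normal region
    out = []
    for b in blocks:
        bs, be = b[0][0], b[-1][1]
        touching = [r for r in regions if r.start < be and r.stop > bs]
        out.append((min(r.start for r in touching),
                    max(r.stop for r in touching), None))
    return out


def _common_pairs(samples: Sequence[Sample]) -> set:
    if not samples:
        return set()
    common = set(samples[0].meta.pairs())
    for s in samples[1:]:
        common &= set(s.meta.pairs())
    return common


def op_cover(ds: Dataset, params: CoverParams) -> Dataset:
    """Collapse the regions of several samples into consensus regions of one
    sample per partition, based on the per-base accumulation count.

    Samples are partitioned by the value set of the ``group_by`` metadata
    attribute (a single partition when absent); accumulation ignores strand
    and counts duplicated intervals within and across samples.  Output
    metadata keeps only the pairs common to every contributing sample, plus
    the grouping pair; output regions are unstranded.
    """
    if params.group_by is None:
        partitions = [("cover", list(ds.samples))] if ds.samples else []
    else:
        grouped: dict = {}
        missing = []
        for s in ds.samples:
            values = sorted(s.meta.get(params.group_by))
            if not values:
                missing.append(s)
                continue
            grouped.setdefault(",".join(values), []).append(s)
        partitions = [(k, grouped[k]) for k in sorted(grouped)]
        for s in missing:
            logger.warning(
                "cover: sample %r lacks groupBy attribute %r; kept as its own "
                "missing partition", s.id, params.group_by
            )
            partitions.append((f"{MISSING_GROUP}.{s.id}", [s]))
    schema = (RegionSchema((("acc_index", "integer"),))
              if params.variant == "histogram" else RegionSchema())
    out_samples = []
    for key, members in partitions:
        pooled = [r for s in members for r in s.regions]
        by_chrom: dict = {}
        for r in pooled:
            by_chrom.setdefault(r.chrom, []).append(r)
        regions = []
        for chrom in sorted(by_chrom):
            for s_, e_, a_ in _cover_chrom(by_chrom[chrom], params):
                attrs = (a_,) if params.variant == "histogram" else ()
                regions.append(GenomicRegion(chrom, s_, e_, "*", attrs))
        meta = MetadataStore(sorted(_common_pairs(members)))
        if params.group_by is not None and not key.startswith(MISSING_GROUP):
            meta.add(params.group_by, key)
        out_samples.append(Sample(sanitize_id(key), regions, meta))
    unique_ids(out_samples)
    return Dataset(schema, out_samples)


# ---------------------------------------------------------------------------
# merge / order / group
# ---------------------------------------------------------------------------

def op_merge(ds: Dataset) -> Dataset:
    """One sample holding the multiset union of all regions (not collapsed)
    and the deduplicated union of all metadata pairs."""
    if not ds.samples:
        return Dataset(ds.schema, [])
    regions = [r for s in ds.samples for r in s.regions]
    pairs = sorted({p for s in ds.samples for p in s.meta.pairs()})
    return Dataset(ds.schema, [Sample("merged", regions, MetadataStore(pairs))])


def _order_component(sample: Sample, attr: str):
    values = sample.meta.get(attr)
    if not values:
        return None  # missing sorts last regardless of direction
    try:
        return (0, min(float(v) for v in values))
    except ValueError:
        return (1, min(values))


def _order_cmp(attrs: Sequence[str], ascending: bool):
    def cmp(s1: Sample, s2: Sample) -> int:
        for attr in attrs:
            k1, k2 = _order_component(s1, attr), _order_component(s2, attr)
            if k1 is None and k2 is None:
                continue
            if k1 is None:
                return 1
            if k2 is None:
                return -1
            if k1 != k2:
                less = -1 if ascending else 1
                return less if k1 < k2 else -less
        return -1 if s1.id < s2.id else (1 if s1.id > s2.id else 0)
    return cmp


def op_order(ds: Dataset, meta_keys: Optional[Sequence[str]] = None,
             region_keys: Optional[Sequence[str]] = None,
             ascending: bool = True,
             top_k: Optional[int] = None) -> Dataset:
    """Reorder (and optionally truncate) samples by metadata keys, adding the
    rank as an ``order`` metadata pair; ``region_keys`` (schema columns)
    reorder regions within each sample.  Ties break by sample id."""
    samples = [Sample(s.id, list(s.regions), s.meta.copy()) for s in ds.samples]
    if meta_keys:
        samples.sort(key=functools.cmp_to_key(_order_cmp(meta_keys, ascending)))
    if top_k is not None:
        if top_k < 0:
            raise OperatorError("top_k must be >= 0")
        samples = samples[:top_k]
    if region_keys:
        idx = [ds.schema.index(k) for k in region_keys]
        for s in samples:
            s.regions.sort(key=GenomicRegion.sort_key)
            s.regions.sort(key=lambda r: tuple(
                (r.attrs[i] is None, r.attrs[i]) for i in idx
            ))
    if meta_keys:
        for rank, s in enumerate(samples, start=1):
            s.meta.add("order", str(rank))
    return Dataset(ds.schema, samples)


def op_group(ds: Dataset, attr: str) -> Dataset:
    """One output sample per distinct value of ``attr``; a multi-valued sample
    contributes to each of its values' groups; samples missing the attribute
    form a single missing group.  Group metadata keeps the pairs common to
    all members plus the grouping pair."""
    groups: dict = {}
    for s in ds.samples:
        values = sorted(s.meta.get(attr))
        if not values:
            groups.setdefault(MISSING_GROUP, []).append(s)
        else:
            for v in values:
                groups.setdefault(v, []).append(s)
    out = []
    for value in sorted(groups):
        members = groups[value]
        regions = [r for s in members for r in s.regions]
        meta = MetadataStore(sorted(_common_pairs(members)))
        meta.add(attr, value)
        out.append(Sample(sanitize_id(f"group.{value}"), regions, meta))
    unique_ids(out)
    return Dataset(ds.schema, out)
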