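"""Lazy query construction and materialization.

Building operators only grows a directed acyclic graph of ``QueryNode``s —
no file is read and no region is touched before :meth:`QueryVariable.
materialize` (or :meth:`head`) is called.  Materialization evaluates the
DAG bottom-up, memoising shared subtrees within the call, and produces a
:class:`ResultTables`: one pandas region table and one metadata table,
deterministically ordered so repeated runs agree row for row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import pandas as pd

from . import binary, io, unary
from .model import (
    Dataset,
    GenomicRegion,
    MetadataStore,
    RegionSchema,
    Sample,
)

logger = logging.getLogger("regal.dag")

REGION_CORE_COLUMNS = ("sample_id", "chrom", "start", "stop", "strand")
META_COLUMNS = ("sample_id", "attribute", "value")


class QueryError(RuntimeError):
    """An operator failed during materialization; names the failing node."""


class QueryNode:
    """One operator application: a tag, its parameters, 0-2 parents and the
    evaluation function.  ``eval_count`` instruments how often the node was
    actually computed (laziness and subtree-caching are asserted with it)."""

    __slots__ = ("op", "params", "parents", "func", "eval_count")

    def __init__(self, op: str, params: dict, parents: tuple,
                 func: Callable[[list], Dataset]):
        self.op = op
        self.params = params
        self.parents = parents
        self.func = func
        self.eval_count = 0

    def describe(self) -> str:
        return f"{self.op}({self.params})"


def _evaluate(node: QueryNode, memo: dict) -> Dataset:
    if id(node) in memo:
        return memo[id(node)]
    inputs = [_evaluate(p, memo) for p in node.parents]
    try:
        result = node.func(inputs)
    except QueryError:
        raise
    except Exception as exc:
        raise QueryError(f"node {node.describe()}: {exc}") from exc
    node.eval_count += 1
    memo[id(node)] = result
    return result


# ---------------------------------------------------------------------------
# result container
# ---------------------------------------------------------------------------

@dataclass
class ResultTables:
    """Materialized query result.

    ``regions``: one row per region — (sample_id, chrom, start, stop,
    strand, schema columns...), sorted by (sample_id, chrom, start, stop).
    ``metadata``: one row per metadata pair — (sample_id, attribute, value).
    ``sample_ids`` records the full sample set (a sample may legitimately
    have zero regions or zero metadata rows).
    """

    regions: pd.DataFrame
    metadata: pd.DataFrame
    schema: RegionSchema
    sample_ids: tuple

    def head(self, n: int = 5) -> "ResultTables":
        """First ``n`` region rows plus the metadata of their samples."""
        if n < 0:
            raise ValueError("n must be >= 0")
        regions = self.regions.head(n).reset_index(drop=True)
        ids = tuple(sorted(regions["sample_id"].unique()))
        meta = self.metadata[self.metadata["sample_id"].isin(ids)]
        return ResultTables(regions, meta.reset_index(drop=True),
                            self.schema, ids)

    def equals(self, other: "ResultTables") -> bool:
        return (
            self.regions.equals(other.regions)
            and self.metadata.equals(other.metadata)
            and self.schema == other.schema
            and self.sample_ids == other.sample_ids
        )


def dataset_to_tables(ds: Dataset) -> ResultTables:
    region_rows = []
    meta_rows = []
    for s in ds.samples:
        for r in s.regions:
            region_rows.append((s.id, r.chrom, r.start, r.stop, r.strand)
                               + tuple(r.attrs))
        for a, v in s.meta.pairs():
            meta_rows.append((s.id, a, v))
    columns = list(REGION_CORE_COLUMNS) + list(ds.schema.names)
    regions = pd.DataFrame(region_rows, columns=columns)
    regions = regions.sort_values(
        ["sample_id", "chrom", "start", "stop", "strand"], kind="stable"
    ).reset_index(drop=True)
    metadata = pd.DataFrame(sorted(meta_rows), columns=list(META_COLUMNS))
    return ResultTables(regions, metadata, ds.schema,
                        tuple(sorted(s.id for s in ds.samples)))


def tables_to_dataset(rt: ResultTables) -> Dataset:
    """Rebuild a Dataset from result tables (inverse of
    :func:`dataset_to_tables`); rejects rows whose sample id is not in the
    declared sample set."""
    known = set(rt.sample_ids)
    orphans = (set(rt.regions["sample_id"]) | set(rt.metadata["sample_id"])) - known
    if orphans:
        raise ValueError(f"orphan sample ids in tables: {sorted(orphans)}")
    samples = {sid: Sample(sid, [], MetadataStore()) for sid in rt.sample_ids}
    types = rt.schema.types
    # positional iteration: schema column names (e.g. "left.score") need not
    # be valid Python identifiers
    for row in rt.regions.itertuples(index=False, name=None):
        sid, chrom, start, stop, strand = row[:5]
        attrs = []
        for v, t in zip(row[5:], types):
            if v is None or (not isinstance(v, str) and pd.isna(v)):
                attrs.append(None)
            else:
                attrs.append(_coerce_cell(v, t))
        samples[sid].regions.append(GenomicRegion(
            chrom, int(start), int(stop), strand, tuple(attrs)))
    for row in rt.metadata.itertuples(index=False):
        samples[row.sample_id].meta.add(row.attribute, row.value)
    return Dataset(rt.schema, [samples[sid] for sid in sorted(samples)])


def _coerce_cell(v, t: str):
    if t == "integer":
        return int(v)
    if t == "float":
        return float(v)
    return str(v)


def to_matrix(rt: ResultTables, index_cols: Union[str, Sequence[str]],
              column_key: str, value_col: str, fill=None,
              reducer: str = "mean") -> pd.DataFrame:
    """Pivot the region table to a matrix (e.g. gene x sample).

    ``column_key`` is a region column, a metadata attribute (joined via
    sample_id; multiple values sorted-joined), or ``"sample_id"``.
    Duplicate (index, column) cells reduce by mean for numeric value
    columns; for string columns duplicates are an error.  Missing cells are
    set to ``fill`` when given.
    """
    if value_col not in rt.regions.columns:
        raise ValueError(f"value column {value_col!r} not in region table")
    df = rt.regions.copy()
    if column_key in df.columns:
        key = df[column_key]
    else:
        lookup: dict = {}
        sub = rt.metadata[rt.metadata["attribute"] == column_key]
        for sid, grp in sub.groupby("sample_id"):
            lookup[sid] = ",".join(sorted(set(grp["value"])))
        if not lookup:
            raise ValueError(
                f"column key {column_key!r} is neither a region column nor a "
                f"metadata attribute"
            )
        key = df["sample_id"].map(lookup)
    df["_column_key"] = key
    numeric = (value_col in rt.schema
               and rt.schema.type_of(value_col) != "string")
    if numeric:
        df[value_col] = pd.to_numeric(df[value_col])
    index_cols = [index_cols] if isinstance(index_cols, str) else list(index_cols)
    if not numeric:
        dup = df.duplicated(subset=index_cols + ["_column_key"], keep=False)
        if dup.any():
            raise ValueError(
                "duplicate (index, column) cells with a string value column"
            )
        aggfunc = "first"
    else:
        aggfunc = reducer
    matrix = df.pivot_table(index=index_cols, columns="_column_key",
                            values=value_col, aggfunc=aggfunc, dropna=False)
    matrix = matrix.sort_index(axis=0).sort_index(axis=1)
    matrix.columns.name = column_key
    if fill is not None:
        matrix = matrix.fillna(fill)
    return matrix


# ---------------------------------------------------------------------------
# query variables
# ---------------------------------------------------------------------------

class QueryVariable:
    """Lazy handle to a DAG of operator applications.

    Operator methods only create nodes; nothing is read or computed until
    :meth:`materialize` or :meth:`head`.
    """

    def __init__(self, node: QueryNode):
        self.node = node

    # -- construction helpers ------------------------------------------------
    def _unary(self, op: str, params: dict, func) -> "QueryVariable":
        return QueryVariable(QueryNode(op, params, (self.node,), func))

    def _binary(self, op: str, other: "QueryVariable", params: dict,
                func) -> "QueryVariable":
        return QueryVariable(QueryNode(op, params, (self.node, other.node),
                                       func))

    # -- unary operators -----------------------------------------------------
    def select(self, meta=None, region=None) -> "QueryVariable":
        return self._unary(
            "select", {"meta": meta, "region": region},
            lambda ins: unary.op_select(ins[0], meta=meta, region=region),
        )

    def project(self, new_columns=None, keep_columns=None,
                new_coordinates=None, meta_keep=None) -> "QueryVariable":
        return self._unary(
            "project", {"new_columns": new_columns,
                        "new_coordinates": new_coordinates},
            lambda ins: unary.op_project(
                ins[0], new_columns=new_columns, keep_columns=keep_columns,
                new_coordinates=new_coordinates, meta_keep=meta_keep),
        )

    def extend(self, aggs: Sequence[unary.AggregateSpec]) -> "QueryVariable":
        return self._unary(
            "extend", {"aggs": aggs},
            lambda ins: unary.op_extend(ins[0], aggs),
        )

    def cover(self, variant: str = "normal", min_acc: int = 1,
              max_acc: Optional[int] = unary.ANY,
              group_by: Optional[str] = None) -> "QueryVariable":
        params = unary.CoverParams(variant, min_acc, max_acc, group_by)
        return self._unary(
            f"{variant}_cover", {"params": params},
            lambda ins: unary.op_cover(ins[0], params),
        )

    def normal_cover(self, min_acc=1, max_acc=unary.ANY, group_by=None):
        return self.cover("normal", min_acc, max_acc, group_by)

    def flat_cover(self, min_acc=1, max_acc=unary.ANY, group_by=None):
        return self.cover("flat", min_acc, max_acc, group_by)

    def summit_cover(self, min_acc=1, max_acc=unary.ANY, group_by=None):
        return self.cover("summit", min_acc, max_acc, group_by)

    def histogram_cover(self, min_acc=1, max_acc=unary.ANY, group_by=None):
        return self.cover("histogram", min_acc, max_acc, group_by)

    def merge(self) -> "QueryVariable":
        return self._unary("merge", {}, lambda ins: unary.op_merge(ins[0]))

    def order(self, meta_keys=None, region_keys=None, ascending=True,
              top_k=None) -> "QueryVariable":
        return self._unary(
            "order", {"meta_keys": meta_keys, "top_k": top_k},
            lambda ins: unary.op_order(ins[0], meta_keys=meta_keys,
                                       region_keys=region_keys,
                                       ascending=ascending, top_k=top_k),
        )

    def group(self, attr: str) -> "QueryVariable":
        return self._unary("group", {"attr": attr},
                           lambda ins: unary.op_group(ins[0], attr))

    # -- binary operators ----------------------------------------------------
    def join(self, other: "QueryVariable", pred: binary.GenometricPredicate,
             output: str = "LEFT", pairing: binary.SamplePairing = binary.CROSS,
             ignore_strand: bool = False) -> "QueryVariable":
        return self._binary(
            "join", other, {"pred": pred, "output": output},
            lambda ins: binary.op_join(ins[0], ins[1], pred, output=output,
                                       pairing=pairing,
                                       ignore_strand=ignore_strand),
        )

    def map(self, experiment: "QueryVariable", aggs=(),
            pairing: binary.SamplePairing = binary.CROSS,
            ignore_strand: bool = False,
            count_name: str = "count") -> "QueryVariable":
        return self._binary(
            "map", experiment, {"aggs": aggs},
            lambda ins: binary.op_map(ins[0], ins[1], aggs=aggs,
                                      pairing=pairing,
                                      ignore_strand=ignore_strand,
                                      count_name=count_name),
        )

    def union(self, other: "QueryVariable") -> "QueryVariable":
        return self._binary("union", other, {},
                            lambda ins: binary.op_union(ins[0], ins[1]))

    def difference(self, other: "QueryVariable",
                   pairing: binary.SamplePairing = binary.CROSS,
                   ignore_strand: bool = False) -> "QueryVariable":
        return self._binary(
            "difference", other, {},
            lambda ins: binary.op_difference(ins[0], ins[1], pairing=pairing,
                                             ignore_strand=ignore_strand),
        )

    # -- execution -----------------------------------------------------------
    def materialize(self, out_path=None) -> ResultTables:
        """Trigger evaluation of the whole DAG (shared subtrees computed once
        per call) and flatten the resulting dataset into tables; optionally
        also write it as a dataset directory."""
        ds = _evaluate(self.node, {})
        if out_path is not None:
            io.write_gdm_dataset(ds, out_path)
        return dataset_to_tables(ds)

    def head(self, n: int = 5) -> ResultTables:
        """Evaluate and preview the first ``n`` region rows together with the
        metadata of their samples."""
        return self.materialize().head(n)


# ---------------------------------------------------------------------------
# sources
# ---------------------------------------------------------------------------

def from_dataset(ds: Dataset, name: str = "memory") -> QueryVariable:
    """Source node over an in-memory dataset (reads nothing until
    materialization; eval_count instruments evaluation)."""
    return QueryVariable(QueryNode(f"source:{name}", {}, (),
                                   lambda ins: ds))


def load_from_path(path, parser: Optional[io.ParserSpec] = None,
                   format: Optional[str] = None) -> QueryVariable:
    """Lazy source over files on disk.

    With no parser, ``path`` is a dataset directory.  With ``parser`` (a
    :class:`ParserSpec`) or ``format`` (``"bed"`` / ``"gtf"``), ``path`` is
    a single region file imported as a one-sample dataset.  The path is not
    touched — and may not even exist — until materialization.
    """
    def read(_ins) -> Dataset:
        if parser is None and format is None:
            return io.read_gdm_dataset(path)
        sample_id = io.Path(path).stem
        if parser is not None:
            sample = io.parse_custom_tsv(path, parser, sample_id=sample_id)
            return Dataset(parser.schema(), [sample])
        if format == "bed":
            sample = io.parse_bed(path, sample_id=sample_id,
                                  attr_cols=list(io.BED_DEFAULT_ATTRS))
            return Dataset(RegionSchema(
                tuple((n, t) for _, n, t in io.BED_DEFAULT_ATTRS)), [sample])
        if format == "gtf":
            sample = io.parse_gtf(path, sample_id=sample_id)
            return Dataset(io.gtf_schema(), [sample])
        raise ValueError(f"unknown format {format!r}")

    return QueryVariable(QueryNode(f"load:{path}", {"parser": parser}, (),
                                   read))


def load_from_file(path, parser: io.ParserSpec) -> QueryVariable:
    """Lazy import of a single delimited region file (see
    :class:`regal.io.ParserSpec`)."""
    return load_from_path(path, parser=parser)


def to_source(rt: ResultTables, name: str = "result") -> QueryVariable:
    """Convert a materialized result back into a query variable;
    ``to_source(r).materialize()`` equals ``r``."""
    ds = tables_to_dataset(rt)
    return from_dataset(ds, name=name)
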