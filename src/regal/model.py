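"""Core genomic data model: regions, samples, datasets.

A dataset is a set of samples; each sample couples a list of stranded genomic
regions (carrying typed signal attributes) with multi-valued attribute/value
metadata describing the experimental context.  Coordinates are 0-based,
half-open ``[start, stop)`` (BED convention) throughout; 1-based closed inputs
are converted on read by the parsers in :mod:`regal.io`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

logger = logging.getLogger("regal")

#: Legal strand symbols. ``*`` means unstranded / strand-unknown.
STRANDS = ("+", "-", "*")

#: Legal schema column types.
COLUMN_TYPES = ("string", "integer", "float")

_ID_SAFE = re.compile(r"[^A-Za-z0-9._-]+")


def sanitize_id(raw: str) -> str:
    """Make a sample identifier filesystem-safe (ids double as file names)."""
    cleaned = _ID_SAFE.sub("-", raw).strip("-")
    return cleaned or "sample"


def coerce_value(value, col_type: str):
    """Coerce a raw (string) value to the schema column type; None stays None."""
    if value is None:
        return None
    if col_type == "string":
        return str(value)
    if col_type == "integer":
        return int(value)
    if col_type == "float":
        return float(value)
    raise ValueError(f"unknown column type {col_type!r}")


@dataclass(frozen=True)
class GenomicRegion:
    """One stranded interval with typed attribute values.

    ``start`` is 0-based inclusive, ``stop`` exclusive; ``start == stop`` is a
    legal zero-length region (anchor/midpoint projections can produce them).
    ``attrs`` is an ordered tuple matching the dataset schema.
    """

    chrom: str
    start: int
    stop: int
    strand: str = "*"
    attrs: tuple = ()

    def sort_key(self):
        return (self.chrom, self.start, self.stop, self.strand)

    @property
    def length(self) -> int:
        return self.stop - self.start

    def with_coords(self, start: int, stop: int) -> "GenomicRegion":
        return GenomicRegion(self.chrom, start, stop, self.strand, self.attrs)

    def with_attrs(self, attrs: tuple) -> "GenomicRegion":
        return GenomicRegion(self.chrom, self.start, self.stop, self.strand, attrs)


def five_prime_anchor(region: GenomicRegion) -> int:
    """Strand-aware 5' boundary (TSS for a gene): ``start`` on ``+``/``*``,
    ``stop`` on ``-``."""
    return region.stop if region.strand == "-" else region.start


def three_prime_anchor(region: GenomicRegion) -> int:
    """Strand-aware 3' boundary: ``stop`` on ``+``/``*``, ``start`` on ``-``."""
    return region.start if region.strand == "-" else region.stop


def strand_flip(region: GenomicRegion) -> GenomicRegion:
    """Flip strand, preserving the interval (``*`` is its own flip)."""
    flipped = {"+": "-", "-": "+", "*": "*"}[region.strand]
    return GenomicRegion(region.chrom, region.start, region.stop, flipped, region.attrs)


def strand_compatible(a: str, b: str) -> bool:
    """Strand matching rule for binary operators: ``*`` matches anything,
    otherwise strands must be equal."""
    return a == "*" or b == "*" or a == b


def merge_strands(a: str, b: str) -> str:
    if a == b:
        return a
    if a == "*":
        return b
    if b == "*":
        return a
    return "*"


@dataclass(frozen=True)
class RegionSchema:
    """Ordered, uniquely named, typed signal columns of a dataset's regions.

    Coordinates and strand are structural, never schema columns.
    """

    columns: tuple = ()  # tuple of (name, type) pairs

    def __post_init__(self):
        cols = tuple((str(n), str(t)) for n, t in self.columns)
        object.__setattr__(self, "columns", cols)

    @property
    def names(self) -> tuple:
        return tuple(n for n, _ in self.columns)

    @property
    def types(self) -> tuple:
        return tuple(t for _, t in self.columns)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no schema column named {name!r}") from None

    def type_of(self, name: str) -> str:
        return self.columns[self.index(name)][1]

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __len__(self) -> int:
        return len(self.columns)


class MetadataStore:
    """Multiset of (attribute, value) pairs; an attribute may carry several
    values and lookup returns the (possibly empty) value set."""

    __slots__ = ("_pairs",)

    def __init__(self, pairs: Optional[Iterable] = None):
        self._pairs: list = []
        if pairs is not None:
            for attr, value in pairs:
                self.add(attr, value)

    def add(self, attr: str, value) -> None:
        self._pairs.append((str(attr), str(value)))

    def get(self, attr: str) -> set:
        """Value set of ``attr`` (empty set when absent)."""
        return {v for a, v in self._pairs if a == attr}

    def __contains__(self, attr: str) -> bool:
        return any(a == attr for a, _ in self._pairs)

    def pairs(self) -> list:
        """All pairs, sorted, duplicates preserved."""
        return sorted(self._pairs)

    def attributes(self) -> set:
        return {a for a, _ in self._pairs}

    def copy(self) -> "MetadataStore":
        return MetadataStore(self._pairs)

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self) -> Iterator:
        return iter(self.pairs())

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetadataStore):
            return NotImplemented
        return sorted(self._pairs) == sorted(other._pairs)

    def __repr__(self) -> str:
        return f"MetadataStore({self.pairs()!r})"


@dataclass
class Sample:
    """One experimental track: an id, its regions and its metadata."""

    id: str
    regions: list = field(default_factory=list)
    meta: MetadataStore = field(default_factory=MetadataStore)

    def sorted_regions(self) -> list:
        return sorted(self.regions, key=GenomicRegion.sort_key)


@dataclass
class Dataset:
    """Schema plus a list of samples; the operand of every algebra operator."""

    schema: RegionSchema = field(default_factory=RegionSchema)
    samples: list = field(default_factory=list)

    def sample_ids(self) -> list:
        return [s.id for s in self.samples]

    def __len__(self) -> int:
        return len(self.samples)


def sort_regions(regions: Sequence[GenomicRegion]) -> list:
    """Stable sort by (chrom, start, stop, strand); idempotent."""
    return sorted(regions, key=GenomicRegion.sort_key)


def validate_dataset(ds: Dataset) -> list:
    """Check every data-model invariant; return the list of violations.

    An empty report means the dataset is valid.  This reports rather than
    raises so that it can audit files of unknown provenance.
    """
    report: list = []
    n_cols = len(ds.schema)
    names = ds.schema.names
    if len(set(names)) != len(names):
        report.append(f"schema column names not unique: {names}")
    for name, typ in ds.schema.columns:
        if typ not in COLUMN_TYPES:
            report.append(f"schema column {name!r} has unknown type {typ!r}")
    seen_ids: set = set()
    for sample in ds.samples:
        if sample.id in seen_ids:
            report.append(f"duplicate sample id {sample.id!r}")
        seen_ids.add(sample.id)
        for i, r in enumerate(sample.regions):
            where = f"sample {sample.id!r} region {i}"
            if not (0 <= r.start <= r.stop):
                report.append(
                    f"{where}: bad coordinates start={r.start} stop={r.stop}"
                )
            if r.strand not in STRANDS:
                report.append(f"{where}: bad strand {r.strand!r}")
            if len(r.attrs) != n_cols:
                report.append(
                    f"{where}: {len(r.attrs)} attrs, schema has {n_cols} columns"
                )
            else:
                for (cname, ctype), value in zip(ds.schema.columns, r.attrs):
                    if value is None:
                        continue
                    ok = (
                        (ctype == "string" and isinstance(value, str))
                        or (ctype == "integer" and isinstance(value, int)
                            and not isinstance(value, bool))
                        or (ctype == "float" and isinstance(value, float))
                    )
                    if not ok:
                        report.append(
                            f"{where}: column {cname!r} expected {ctype}, "
                            f"got {type(value).__name__}"
                        )
    return report
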