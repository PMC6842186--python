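"""Readers and writers: BED, GTF, user-specified delimited files, and the
on-disk dataset directory layout (one region file + one metadata file per
sample plus a JSON schema descriptor).

All parsers normalise to 0-based half-open coordinates.  Writers are
bit-exact: integers unpadded, floats in repr-minimal form, missing values as
``.``, LF line endings, UTF-8.  Gzip-compressed inputs (``.gz``) are read
transparently.
"""

from __future__ import annotations

import gzip
import json
import logging
import math
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from .model import (
    COLUMN_TYPES,
    Dataset,
    GenomicRegion,
    MetadataStore,
    RegionSchema,
    Sample,
    coerce_value,
    sort_regions,
)

logger = logging.getLogger("regal.io")

REGION_SUFFIX = ".gdm"
META_SUFFIX = ".gdm.meta"
SCHEMA_FILE = "schema.json"

#: On-disk marker for a missing value in a typed region column.
MISSING = "."

SAME_AS_START = "same-as-start"


class FormatError(ValueError):
    """Malformed record or inconsistent dataset layout."""


# ---------------------------------------------------------------------------
# value serialisation
# ---------------------------------------------------------------------------

def format_value(value, col_type: str) -> str:
    if value is None:
        return MISSING
    if col_type == "float":
        if isinstance(value, float) and math.isnan(value):
            return MISSING
        return repr(float(value))
    return str(value)


def parse_value(text: str, col_type: str):
    if text == MISSING:
        return None
    return coerce_value(text, col_type)


def _open_text(path):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def _iter_lines(source) -> Iterable:
    """Accept a path, an open file, or an iterable of lines."""
    if isinstance(source, (str, os.PathLike)):
        with _open_text(source) as fh:
            yield from fh
    else:
        yield from source


def convert_coords(start: int, stop: int, basis: str):
    """Convert coordinates to 0-based half-open.

    ``basis`` is ``"0-based"`` (half-open; identity) or ``"1-based"``
    (closed; start decremented).  The two encodings are in bijection:
    [s, e] 1-based closed <-> [s-1, e) 0-based half-open.
    """
    if basis == "0-based":
        return start, stop
    if basis == "1-based":
        return start - 1, stop
    raise ValueError(f"unknown coordinate basis {basis!r}")


# ---------------------------------------------------------------------------
# ParserSpec and the generic delimited-file parser
# ---------------------------------------------------------------------------

@dataclass
class ParserSpec:
    """Column mapping for an arbitrary delimited region file.

    Column indices are 1-based, as a user reads them off a file preview.
    ``stop_col`` may be the string ``"same-as-start"`` for single-position
    records (e.g. GWAS variants), which become width-1 intervals.
    ``coordinate_basis`` must be stated explicitly — files in the wild use
    both conventions and guessing silently corrupts positions.
    """

    chrom_col: int
    start_col: int
    stop_col: Union[int, str] = SAME_AS_START
    strand_col: Optional[int] = None
    coordinate_basis: str = "0-based"
    attr_cols: list = field(default_factory=list)  # (1-based index, name, type)
    delimiter: str = "\t"
    header_rows: int = 0

    def validate(self) -> None:
        used = [self.chrom_col, self.start_col]
        if self.stop_col != SAME_AS_START:
            used.append(self.stop_col)
        if self.strand_col is not None:
            used.append(self.strand_col)
        for idx, _, _ in self.attr_cols:
            used.append(idx)
        if any((not isinstance(i, int)) or i < 1 for i in used):
            raise ValueError("ParserSpec column indices must be positive integers")
        core = [self.chrom_col, self.start_col]
        if self.stop_col != SAME_AS_START:
            core.append(self.stop_col)
        if len(set(core)) != len(core):
            raise ValueError("chrom/start/stop columns must be distinct")
        names = [n for _, n, _ in self.attr_cols]
        if len(set(names)) != len(names):
            raise ValueError("attribute names must be unique")
        for _, n, t in self.attr_cols:
            if t not in COLUMN_TYPES:
                raise ValueError(f"attribute {n!r} has unknown type {t!r}")
        if self.coordinate_basis not in ("0-based", "1-based"):
            raise ValueError(f"unknown coordinate basis {self.coordinate_basis!r}")

    def schema(self) -> RegionSchema:
        return RegionSchema(tuple((n, t) for _, n, t in self.attr_cols))


def _field(parts: list, index: int, lineno: int):
    if index > len(parts):
        raise FormatError(
            f"line {lineno}: needs column {index} but the record has only "
            f"{len(parts)} columns"
        )
    return parts[index - 1]


def parse_custom_tsv(source, spec: ParserSpec, sample_id: str = "sample",
                     on_error: str = "abort") -> Sample:
    """Parse a delimited file according to ``spec`` into one sample.

    ``on_error``: ``"abort"`` raises on the first malformed record,
    ``"skip"`` drops malformed records and logs how many were skipped.
    """
    spec.validate()
    regions: list = []
    skipped = 0
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        if lineno <= spec.header_rows:
            continue
        line = raw.rstrip("\n").rstrip("\r")
        if not line:
            continue
        try:
            parts = line.split(spec.delimiter)
            chrom = _field(parts, spec.chrom_col, lineno)
            try:
                start = int(_field(parts, spec.start_col, lineno))
                if spec.stop_col == SAME_AS_START:
                    stop = start if spec.coordinate_basis == "1-based" else start + 1
                else:
                    stop = int(_field(parts, spec.stop_col, lineno))
            except ValueError as exc:
                raise FormatError(f"line {lineno}: bad coordinate ({exc})") from None
            start, stop = convert_coords(start, stop, spec.coordinate_basis)
            if not (0 <= start <= stop):
                raise FormatError(
                    f"line {lineno}: invalid interval [{start}, {stop})"
                )
            strand = "*"
            if spec.strand_col is not None:
                raw_strand = _field(parts, spec.strand_col, lineno)
                strand = raw_strand if raw_strand in ("+", "-") else "*"
            attrs = []
            for idx, name, typ in spec.attr_cols:
                text = _field(parts, idx, lineno)
                try:
                    attrs.append(parse_value(text, typ))
                except ValueError:
                    raise FormatError(
                        f"line {lineno}: column {name!r} expects {typ}, "
                        f"got {text!r}"
                    ) from None
            regions.append(GenomicRegion(chrom, start, stop, strand, tuple(attrs)))
        except FormatError:
            if on_error == "skip":
                skipped += 1
                continue
            raise
    if skipped:
        logger.warning("parse_custom_tsv: skipped %d malformed records", skipped)
    return Sample(sample_id, regions)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

#: Default signal columns read from BED6 files.
BED_DEFAULT_ATTRS = ((4, "name", "string"), (5, "score", "float"))


def bed_parser_spec(attr_cols=BED_DEFAULT_ATTRS) -> ParserSpec:
    return ParserSpec(
        chrom_col=1, start_col=2, stop_col=3, strand_col=6,
        coordinate_basis="0-based", attr_cols=list(attr_cols),
    )


def parse_bed(source, sample_id: str = "sample", attr_cols=None,
              on_error: str = "abort") -> Sample:
    """Parse a BED3+ file (tab-delimited, 0-based half-open).

    Column 6, when present, is the strand; shorter records are unstranded.
    ``attr_cols`` maps extra BED columns into schema columns as
    (1-based index, name, type); records missing an optional attribute or
    strand column simply carry a missing value / ``*``.
    """
    if attr_cols is None:
        attr_cols = []
    regions: list = []
    skipped = 0
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        try:
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"line {lineno}: BED needs >= 3 columns")
            chrom = parts[0]
            try:
                start, stop = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(
                    f"line {lineno}: malformed coordinates "
                    f"{parts[1]!r}/{parts[2]!r}"
                ) from None
            if not (0 <= start <= stop):
                raise FormatError(
                    f"line {lineno}: invalid interval [{start}, {stop})"
                )
            strand = "*"
            if len(parts) >= 6 and parts[5] in ("+", "-"):
                strand = parts[5]
            attrs = []
            for idx, name, typ in attr_cols:
                if idx <= len(parts):
                    try:
                        attrs.append(parse_value(parts[idx - 1], typ))
                    except ValueError:
                        raise FormatError(
                            f"line {lineno}: column {name!r} expects {typ}, "
                            f"got {parts[idx - 1]!r}"
                        ) from None
                else:
                    attrs.append(None)
            regions.append(GenomicRegion(chrom, start, stop, strand, tuple(attrs)))
        except FormatError:
            if on_error == "skip":
                skipped += 1
                continue
            raise
    if skipped:
        logger.warning("parse_bed: skipped %d malformed records", skipped)
    return Sample(sample_id, regions)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

GTF_FIXED_COLUMNS = (("source", "string"), ("feature", "string"),
                     ("score", "float"))

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def gtf_schema(attribute_keys=("gene_id",)) -> RegionSchema:
    cols = list(GTF_FIXED_COLUMNS) + [(k, "string") for k in attribute_keys]
    return RegionSchema(tuple(cols))


def parse_gtf(source, sample_id: str = "sample",
              attribute_keys=("gene_id",), on_error: str = "abort") -> Sample:
    """Parse GTF v2.2 (1-based closed) into 0-based half-open regions.

    source/feature/score become schema columns; the key/value attribute field
    contributes one string column per key in ``attribute_keys``.
    """
    regions: list = []
    skipped = 0
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line or line.startswith("#"):
            continue
        try:
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(
                    f"line {lineno}: GTF needs 9 columns, got {len(parts)}"
                )
            seqname, src, feature, start_s, end_s, score_s, strand_s = parts[:7]
            try:
                start, stop = convert_coords(int(start_s), int(end_s), "1-based")
            except ValueError:
                raise FormatError(f"line {lineno}: malformed coordinates") from None
            if not (0 <= start <= stop):
                raise FormatError(
                    f"line {lineno}: invalid interval [{start}, {stop})"
                )
            strand = strand_s if strand_s in ("+", "-") else "*"
            score = None if score_s == "." else float(score_s)
            kv = dict(_GTF_ATTR.findall(parts[8]))
            attrs = [src, feature, score] + [kv.get(k) for k in attribute_keys]
            regions.append(GenomicRegion(seqname, start, stop, strand, tuple(attrs)))
        except FormatError:
            if on_error == "skip":
                skipped += 1
                continue
            raise
    if skipped:
        logger.warning("parse_gtf: skipped %d malformed records", skipped)
    return Sample(sample_id, regions)


# ---------------------------------------------------------------------------
# dataset directory layout
# ---------------------------------------------------------------------------

def write_gdm_dataset(ds: Dataset, path) -> Path:
    """Write a dataset directory: ``schema.json`` plus, per sample,
    ``<id>.gdm`` (chrom TAB start TAB stop TAB strand TAB attrs...) and
    ``<id>.gdm.meta`` (attribute TAB value per line)."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    schema_doc = {"columns": [[n, t] for n, t in ds.schema.columns]}
    (root / SCHEMA_FILE).write_text(
        json.dumps(schema_doc, indent=2) + "\n", encoding="utf-8"
    )
    types = ds.schema.types
    for sample in ds.samples:
        lines = []
        for r in sort_regions(sample.regions):
            fields = [r.chrom, str(r.start), str(r.stop), r.strand]
            fields += [format_value(v, t) for v, t in zip(r.attrs, types)]
            lines.append("\t".join(fields))
        (root / f"{sample.id}{REGION_SUFFIX}").write_text(
            "".join(line + "\n" for line in lines), encoding="utf-8"
        )
        meta_lines = [f"{a}\t{v}" for a, v in sample.meta.pairs()]
        (root / f"{sample.id}{META_SUFFIX}").write_text(
            "".join(line + "\n" for line in meta_lines), encoding="utf-8"
        )
    return root


def read_gdm_dataset(path) -> Dataset:
    """Read a dataset directory written by :func:`write_gdm_dataset`.

    ``read(write(ds))`` reproduces ``ds`` exactly: coordinates, typed
    attributes, the metadata multiset and sample ids.
    """
    root = Path(path)
    if not root.is_dir():
        raise FormatError(f"dataset directory not found: {root}")
    schema_path = root / SCHEMA_FILE
    if not schema_path.exists():
        raise FormatError(f"missing {SCHEMA_FILE} in {root}")
    doc = json.loads(schema_path.read_text(encoding="utf-8"))
    schema = RegionSchema(tuple((n, t) for n, t in doc["columns"]))
    samples = []
    region_files = sorted(
        p for p in root.iterdir()
        if p.name.endswith(REGION_SUFFIX) and not p.name.endswith(META_SUFFIX)
    )
    for region_file in region_files:
        sample_id = region_file.name[: -len(REGION_SUFFIX)]
        meta_file = root / f"{sample_id}{META_SUFFIX}"
        if not meta_file.exists():
            raise FormatError(
                f"sample {sample_id!r}: region file has no metadata file "
                f"{meta_file.name}"
            )
        regions = []
        for lineno, line in enumerate(
            region_file.read_text(encoding="utf-8").splitlines(), start=1
        ):
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4 + len(schema):
                raise FormatError(
                    f"{region_file.name} line {lineno}: expected "
                    f"{4 + len(schema)} columns, got {len(parts)}"
                )
            chrom, start_s, stop_s, strand = parts[:4]
            attrs = tuple(
                parse_value(text, typ)
                for text, typ in zip(parts[4:], schema.types)
            )
            regions.append(
                GenomicRegion(chrom, int(start_s), int(stop_s), strand, attrs)
            )
        meta = MetadataStore()
        for line in meta_file.read_text(encoding="utf-8").splitlines():
            if not line:
                continue
            attr, _, value = line.partition("\t")
            meta.add(attr, value)
        samples.append(Sample(sample_id, regions, meta))
    return Dataset(schema, samples)
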