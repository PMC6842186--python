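"""Seeded synthetic dataset generation and exhaustive per-base reference
implementations used as test oracles.

The generator emulates multi-sample peak tracks (ChIP-seq-like intervals
with a float signal column) annotated with a metadata vocabulary — the shape
of the consortium datasets the algebra is meant for — without modelling peak
shapes or read-level noise.  The oracles deliberately work base by base and
all-pairs-quadratically: clarity over speed, and full independence from the
production sweep/interval-tree code (the only shared primitive is
:func:`regal.binary.region_distance` and the strand-compatibility rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .binary import region_distance
from .model import (
    Dataset,
    GenomicRegion,
    MetadataStore,
    RegionSchema,
    Sample,
    strand_compatible,
)

ORACLE_MAX_GENOME = 100_000


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

@dataclass
class SynthConfig:
    """Parameters of a synthetic multi-sample peak dataset.

    Defaults describe a small but realistic desk-scale track collection:
    a handful of samples, tens of peaks of a few hundred bp on a short
    genome, a uniform float signal, and a categorical metadata vocabulary
    (cell line and target) drawn per sample.
    """

    n_samples: int = 5
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 100_000, "chr2": 80_000})
    regions_per_sample: tuple = (20, 40)       # inclusive bounds
    region_length: tuple = (100, 600)          # inclusive bounds, bp
    strand_probs: tuple = (0.4, 0.4, 0.2)      # P(+), P(-), P(*)
    signal_range: tuple = (0.0, 10.0)
    start_margin: int = 0                      # no regions in the first N bp
    metadata_vocab: dict = field(default_factory=lambda: {
        "cell": ["K562", "GM12878", "HepG2"],
        "experiment_target": ["H3K27ac", "H3K9ac", "CTCF"],
    })
    seed: int = 0


def generate_dataset(config: SynthConfig) -> Dataset:
    """Deterministically generate a dataset from ``config`` (same seed, same
    dataset).  Regions lie within chromosome bounds and respect the length
    bounds; metadata draws one value per vocabulary attribute per sample."""
    rng = np.random.default_rng(config.seed)
    schema = RegionSchema((("signal", "float"),))
    chroms = sorted(config.chrom_lengths)
    samples = []
    for i in range(config.n_samples):
        n = int(rng.integers(config.regions_per_sample[0],
                             config.regions_per_sample[1] + 1))
        regions = []
        for _ in range(n):
            chrom = chroms[int(rng.integers(len(chroms)))]
            clen = config.chrom_lengths[chrom]
            length = int(rng.integers(config.region_length[0],
                                      min(config.region_length[1], clen) + 1))
            start = int(rng.integers(config.start_margin,
                                     clen - length + 1))
            strand = ("+", "-", "*")[
                int(rng.choice(3, p=np.asarray(config.strand_probs)))]
            signal = float(rng.uniform(*config.signal_range))
            regions.append(GenomicRegion(chrom, start, start + length,
                                         strand, (round(signal, 4),)))
        meta = MetadataStore()
        for attr in sorted(config.metadata_vocab):
            values = config.metadata_vocab[attr]
            meta.add(attr, values[int(rng.integers(len(values)))])
        samples.append(Sample(f"s{i:02d}", regions, meta))
    return Dataset(schema, samples)


# ---------------------------------------------------------------------------
# per-base cover oracle
# ---------------------------------------------------------------------------

def per_base_accumulation(regions: Sequence[GenomicRegion],
                          genome_length: int) -> list:
    """A(x) for every base x in [0, genome_length): the number of regions
    covering x, duplicates counted, strand ignored."""
    if genome_length > ORACLE_MAX_GENOME:
        raise ValueError(
            f"oracle refuses genomes over {ORACLE_MAX_GENOME} bases"
        )
    acc = [0] * genome_length
    for r in regions:
        for x in range(max(r.start, 0), min(r.stop, genome_length)):
            acc[x] += 1
    return acc


def _qual(a: int, min_acc: int, max_acc: Optional[int]) -> bool:
    return a >= min_acc and (max_acc is None or a <= max_acc)


def oracle_cover(regions: Sequence[GenomicRegion], min_acc: int,
                 max_acc: Optional[int], genome_length: int) -> dict:
    """All four cover variants for one chromosome, derived base by base.

    Returns ``{"normal": [(s, e)], "histogram": [(s, e, acc)],
    "summit": [(s, e)], "flat": [(s, e)]}``.
    """
    acc = per_base_accumulation(regions, genome_length)
    qual = [_qual(a, min_acc, max_acc) for a in acc]
    # normal: maximal runs of qualifying bases
    normal = []
    x = 0
    while x < genome_length:
        if qual[x]:
            start = x
            while x < genome_length and qual[x]:
                x += 1
            normal.append((start, x))
        else:
            x += 1
    # histogram: constant-accumulation sub-runs of each normal region
    histogram = []
    for s, e in normal:
        x = s
        while x < e:
            start, a = x, acc[x]
            while x < e and acc[x] == a:
                x += 1
            histogram.append((start, x, a))
    # summit: histogram runs that are local maxima within their normal region
    summit = []
    for s, e in normal:
        runs = [h for h in histogram if s <= h[0] and h[1] <= e]
        for i, (rs, re, a) in enumerate(runs):
            if (i == 0 or runs[i - 1][2] <= a) and \
               (i == len(runs) - 1 or runs[i + 1][2] <= a):
                summit.append((rs, re))
    # flat: extent of the input regions strictly overlapping each normal run
    flat = []
    for s, e in normal:
        touching = [r for r in regions if r.start < e and r.stop > s]
        flat.append((min(r.start for r in touching),
                     max(r.stop for r in touching)))
    return {"normal": normal, "histogram": histogram, "summit": summit,
            "flat": flat}


# ---------------------------------------------------------------------------
# quadratic map / join / difference oracles
# ---------------------------------------------------------------------------

def _compat(a: GenomicRegion, b: GenomicRegion, ignore_strand: bool) -> bool:
    return ignore_strand or strand_compatible(a.strand, b.strand)


def oracle_map_count(ref_regions: Sequence[GenomicRegion],
                     exp_regions: Sequence[GenomicRegion],
                     ignore_strand: bool = False) -> list:
    """Per reference region, the number of experiment regions at strictly
    negative distance (all-pairs)."""
    counts = []
    for ref in ref_regions:
        n = 0
        for e in exp_regions:
            d = region_distance(ref, e)
            if d is not None and d < 0 and _compat(ref, e, ignore_strand):
                n += 1
        counts.append(n)
    return counts


def oracle_map_values(ref_regions, exp_regions, column_index: int,
                      ignore_strand: bool = False) -> list:
    """Per reference region, the list of attribute values of the strictly
    overlapping experiment regions (for checking aggregates)."""
    out = []
    for ref in ref_regions:
        values = []
        for e in exp_regions:
            d = region_distance(ref, e)
            if d is not None and d < 0 and _compat(ref, e, ignore_strand):
                if e.attrs[column_index] is not None:
                    values.append(e.attrs[column_index])
        out.append(values)
    return out


def oracle_min_distance(ref: GenomicRegion,
                        candidates: Sequence[GenomicRegion], k: int,
                        dle: Optional[int] = None, dge: Optional[int] = None,
                        ignore_strand: bool = False) -> list:
    """The k candidates at minimal |distance| from ``ref`` (ties: smaller
    start, then smaller stop), restricted to any DLE/DGE bound; exhaustive."""
    scored = []
    for c in candidates:
        d = region_distance(ref, c)
        if d is None or not _compat(ref, c, ignore_strand):
            continue
        if dle is not None and d > dle:
            continue
        if dge is not None and d < dge:
            continue
        scored.append((abs(d), c.start, c.stop, d, c))
    scored.sort(key=lambda t: t[:3])
    return [(t[4], t[3]) for t in scored[:k]]


def oracle_join(left_regions, right_regions, dle=None, dge=None, md=None,
                ignore_strand: bool = False) -> list:
    """All surviving (left, right, distance) triples, quadratically."""
    out = []
    for l in left_regions:
        if md is not None:
            for c, d in oracle_min_distance(l, right_regions, md, dle=dle,
                                            dge=dge,
                                            ignore_strand=ignore_strand):
                out.append((l, c, d))
            continue
        for r in right_regions:
            d = region_distance(l, r)
            if d is None or not _compat(l, r, ignore_strand):
                continue
            if dle is not None and d > dle:
                continue
            if dge is not None and d < dge:
                continue
            out.append((l, r, d))
    return out


def oracle_difference(a_regions, b_regions,
                      ignore_strand: bool = False) -> list:
    """Regions of ``a`` with no strictly overlapping region in ``b``."""
    kept = []
    for a in a_regions:
        if not any(
            (d := region_distance(a, b)) is not None and d < 0
            and _compat(a, b, ignore_strand)
            for b in b_regions
        ):
            kept.append(a)
    return kept


# ---------------------------------------------------------------------------
# equivalence battery
# ---------------------------------------------------------------------------

#: Default battery size and seed base; instance i uses seed BATTERY_SEED0+i,
#: so a failure report identifies the exact reproducible instance.
BATTERY_INSTANCES = 200
BATTERY_SEED0 = 0


def _random_instance(rng: np.random.Generator):
    """Two small single-chromosome datasets within the battery bounds
    (genome <= 10 kb, <= 10 samples/side, <= 50 regions/sample)."""
    genome = int(rng.integers(2_000, 10_001))
    schema = RegionSchema((("signal", "float"),))

    def make(side: str) -> Dataset:
        samples = []
        for i in range(int(rng.integers(1, 4))):
            regions = []
            for _ in range(int(rng.integers(4, 21))):
                length = int(rng.integers(0, 401))  # zero-length allowed
                start = int(rng.integers(0, genome - length + 1))
                strand = ("+", "-", "*")[int(rng.integers(3))]
                signal = round(float(rng.uniform(0, 10)), 3)
                regions.append(GenomicRegion("chr1", start, start + length,
                                             strand, (signal,)))
            meta = MetadataStore([("side", side), ("idx", str(i))])
            samples.append(Sample(f"{side}{i}", regions, meta))
        return Dataset(schema, samples)

    return genome, make("a"), make("b")


def _region_tuples(sample, with_acc=False):
    if with_acc:
        return sorted((r.start, r.stop, r.attrs[0]) for r in sample.regions)
    return sorted((r.start, r.stop) for r in sample.regions)


def run_equivalence_battery(n_instances: int = BATTERY_INSTANCES,
                            base_seed: int = BATTERY_SEED0) -> dict:
    """Compare the production cover/map/join/difference implementations with
    the per-base and all-pairs oracles on ``n_instances`` random instances.

    Returns ``{"instances": n, "checks": total, "failures": [...]}`` where
    each failure names the instance seed and the check that disagreed.
    """
    from .binary import DGE, DLE, MD, op_difference, op_join, op_map
    from .unary import AggregateSpec, CoverParams, op_cover, op_merge

    failures = []
    checks = 0

    def expect(cond: bool, seed: int, label: str):
        nonlocal checks
        checks += 1
        if not cond:
            failures.append((seed, label))

    for i in range(n_instances):
        seed = base_seed + i
        rng = np.random.default_rng(seed)
        genome, ds_a, ds_b = _random_instance(rng)
        pooled = [r for s in ds_a.samples for r in s.regions]

        # --- cover, all four variants, random accumulation bounds
        min_acc = int(rng.integers(1, 4))
        max_acc = None if rng.random() < 0.5 else min_acc + int(rng.integers(0, 3))
        want = oracle_cover(pooled, min_acc, max_acc, genome)
        for variant in ("normal", "histogram", "summit", "flat"):
            got = op_cover(ds_a, CoverParams(variant, min_acc, max_acc))
            got_t = (_region_tuples(got.samples[0], with_acc=True)
                     if variant == "histogram"
                     else _region_tuples(got.samples[0]))
            expect(got_t == sorted(want[variant]), seed, f"cover:{variant}")

        # --- map counts and AVG against the all-pairs oracle
        ref = Dataset(ds_a.schema, [op_merge(ds_a).samples[0]])
        exp = Dataset(ds_b.schema, [op_merge(ds_b).samples[0]])
        mapped = op_map(ref, exp, aggs=[AggregateSpec("AVG", "signal", "avg")])
        counts = [r.attrs[1] for r in mapped.samples[0].regions]
        avgs = [r.attrs[2] for r in mapped.samples[0].regions]
        want_counts = oracle_map_count(ref.samples[0].regions,
                                       exp.samples[0].regions)
        want_values = oracle_map_values(ref.samples[0].regions,
                                        exp.samples[0].regions, 0)
        expect(counts == want_counts, seed, "map:count")
        ok = all(
            (a is None and not vs) or
            (a is not None and vs and math.isclose(a, sum(vs) / len(vs),
                                                   rel_tol=1e-9))
            for a, vs in zip(avgs, want_values)
        )
        expect(ok, seed, "map:avg")

        # --- joins: DLE / DGE / MD(1)
        lregs, rregs = ref.samples[0].regions, exp.samples[0].regions
        for label, pred, kw in (
            ("join:dle", DLE(int(rng.integers(-1, 301))), {}),
            ("join:dge", DGE(int(rng.integers(0, 301))), {}),
            ("join:md1", MD(1), {}),
        ):
            mode = "CAT" if pred.md else "LEFT"
            got = op_join(ref, exp, pred, output=mode)
            got_t = sorted(
                (r.chrom, r.start, r.stop, r.attrs[-1])
                for r in got.samples[0].regions
            )
            want_t = sorted(
                ((l.chrom, min(l.start, c.start), max(l.stop, c.stop), d)
                 if mode == "CAT" else (l.chrom, l.start, l.stop, d))
                for l, c, d in oracle_join(lregs, rregs, dle=pred.dle,
                                           dge=pred.dge, md=pred.md)
            )
            expect(got_t == want_t, seed, label)

        # --- difference
        got = op_difference(ref, exp)
        got_t = sorted((r.start, r.stop, r.strand)
                       for r in got.samples[0].regions)
        want_t = sorted((r.start, r.stop, r.strand)
                        for r in oracle_difference(lregs, rregs))
        expect(got_t == want_t, seed, "difference")

    return {"instances": n_instances, "checks": checks, "failures": failures}
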