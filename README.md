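# regal — a metadata-aware genomic region algebra

`regal` is a Python library (plus a small CLI) for querying *datasets* of
genomic tracks rather than single files. It targets tertiary analysis in
epigenomics and regulatory genomics: intersecting, aggregating and pairing
ChIP-seq peaks, annotations, and variant sets across tens of samples at
once, while keeping each sample's descriptive metadata attached to the
computation.

## The data model and algebra

A **dataset** is a set of **samples**; each sample couples

* a list of **regions** — stranded intervals `(chrom, start, stop, strand)`
  in 0-based half-open coordinates, carrying typed signal attributes that
  follow a per-dataset schema — and
* **metadata** — a multiset of `(attribute, value)` pairs describing the
  experimental context (cell line, target, replicate, ...).

Operators close over this model (every output is again a valid dataset) and
iterate implicitly over all samples:

| operator | effect |
|---|---|
| `select` | metadata predicates drop samples; region predicates drop regions |
| `project` | keep/derive region columns; recompute coordinates strand-aware |
| `extend` | aggregate a sample's regions into new metadata pairs |
| `cover` (normal / flat / summit / histogram) | consensus regions from the per-base accumulation count A(x), with `minAcc <= A <= maxAcc` and optional metadata grouping |
| `merge`, `order`, `group` | reshape the sample set |
| `join` | genometric join under DLE(x) (distance ≤ x), DGE(x), MD(k) (k nearest) |
| `map` | counts/aggregates of overlapping "experiment" regions onto reference regions |
| `union`, `difference` | sample union; whole-region subtraction of intersecting regions |

The genometric distance between same-chromosome regions is
`d = max(a.start, b.start) − min(a.stop, b.stop)`; `d < 0` iff the regions
share bases, `d = 0` for adjacency, `d > 0` is the gap length.

Queries are **lazy**: operator calls only build a DAG; nothing is read or
computed until `materialize()`, which evaluates shared subtrees once and
returns two deterministic pandas tables (regions and metadata) that can be
pivoted to matrices (`to_matrix`) or turned back into a query variable
(`to_source`).

## Worked example

```python
import regal as rg

peaks = rg.Dataset(
    rg.RegionSchema((("signal", "float"),)),
    [
        rg.Sample("rep1",
                  [rg.GenomicRegion("chr1", 1, 5, "*", (2.0,)),
                   rg.GenomicRegion("chr1", 3, 8, "*", (4.0,))],
                  rg.MetadataStore([("cell", "K562"), ("target", "H3K9ac")])),
        rg.Sample("rep2",
                  [rg.GenomicRegion("chr1", 6, 10, "*", (6.0,))],
                  rg.MetadataStore([("cell", "K562"), ("target", "H3K9ac")])),
    ],
)
rt = rg.from_dataset(peaks).histogram_cover(min_acc=1).materialize()
print(rt.regions.to_string(index=False))
```

```
sample_id chrom  start  stop strand  acc_index
    cover  chr1      1     3      *          1
    cover  chr1      3     5      *          2
    cover  chr1      5     6      *          1
    cover  chr1      6     8      *          2
    cover  chr1      8    10      *          1
```

The three peaks decompose into maximal constant-accumulation runs;
`acc_index` is the number of regions covering each run (across samples,
duplicates counted). A strand-aware promoter projection reads the same on
both strands — for a `-`-strand gene at `[1000, 5000)` the window
`[TSS − 2000, TSS + 2000]` anchors on the 5' end at 5000:

```python
promoters = rg.from_dataset(genes).project(
    new_coordinates=(rg.START - 2000, rg.START + 2000))
```

```
sample_id chrom  start  stop strand gene_id
    genes  chr1   3000  7000      -      g1
```

Three demonstration pipelines (promoter signal matrices, GWAS traits on
cell-specific enhancers, minimal-distance TF binding pairs) run on seeded
synthetic fixtures from the command line:

```bash
regal demo --seed 1 --out demo-out tf-pairs
regal validate demo-out/tf-pairs/fixtures/tf
regal convert peaks.bed --format bed --out peaks-dataset
```

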