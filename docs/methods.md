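# Methods

## Model

A dataset D = (S, Σ) is a schema Σ (ordered, typed signal columns) and a set
of samples; a sample s = (id, R, M) is a region list R and a metadata
multiset M of (attribute, value) string pairs. Regions are stranded
intervals [start, stop) with strand ∈ {+, −, *}; coordinates are 0-based
half-open throughout (the BED convention — it makes interval arithmetic
additive and most inputs conversion-free; GTF and other 1-based closed
inputs are converted on read, `[s, e]` ↦ `[s−1, e)`, a bijection between the
two encodings). Zero-length regions (start = stop) are legal: anchor and
midpoint projections produce them, and they participate in distance
computations (a zero-length region can be adjacent to, but never strictly
overlap, anything). Chromosome names are opaque strings compared for
equality only.

Metadata values are stored as strings. Predicate atoms are satisfied if
*any* value of the attribute satisfies them; a missing attribute makes the
atom false. Ordering comparators (`<`, `<=`, `>`, `>=`) parse both sides as
numbers per evaluation and simply fail (not raise) on unparsable values;
equality comparators compare strings.

## Operator semantics — the decisions that were genuinely open

**Intersection.** "Intersecting" always means strictly negative genometric
distance, d = max(a.start, b.start) − min(a.stop, b.stop) < 0; adjacency
(d = 0) is not intersection under half-open coordinates. A DLE(0) join adds
adjacency back explicitly, which keeps `map` and `difference` crisp while
letting join-based workflows use the looser reading. The DLE bound is
exposed, so DLE(−1) gives the strict variant where wanted.

**Strand matching.** In binary operators, regions match only when strands
are compatible (+ with +/*, − with −/*, * with anything); an
`ignore_strand` flag disables this. Cover accumulation ignores strand
entirely — its uses here (replicate merging, consensus enhancers) are
strand-free.

**Cover.** Per partition, a boundary sweep produces maximal
constant-accumulation runs of A(x), the number of covering regions per base
(duplicates counted within and across samples). With bounds minAcc ≤ A ≤
maxAcc:

* *normal* merges contiguous qualifying runs into maximal regions;
* *histogram* emits the qualifying runs with `acc_index` = A;
* *summit* emits, within each normal region, the constant-A runs whose A is
  ≥ both neighbouring runs (edge runs compare only their one neighbour;
  plateaus are emitted whole). This summit definition is a documented
  dialect isolated behind the variant switch;
* *flat* emits, per normal region, the span from the minimum start to the
  maximum stop of all input regions intersecting it.

Partitioning uses the sample's sorted value set for the groupBy attribute
as key (keeping partitions disjoint when an attribute is multi-valued);
samples missing the attribute each form their own logged "missing"
partition. Output metadata keeps only pairs common to every contributing
sample — any other pair is no longer attributable — plus the grouping pair;
outputs are unstranded.

**MD(k) ties** break by (|d|, candidate start, candidate stop), then by the
candidate's attribute tuple, making output order process-independent even
for coordinate-identical candidates. MD candidates must also satisfy any
DLE/DGE bound in the same predicate.

**Join output** regions follow the requested mode (LEFT, RIGHT, INT —
non-overlapping pairs silently dropped —, CAT = spanning interval) and carry
both sides' columns under `left.`/`right.` prefixes plus a `distance`
integer column; the distance would otherwise be unrecoverable from LEFT/
RIGHT outputs and downstream minimal-distance analyses need it.

**Samples emptied by region predicates are retained** (metadata-only
traceability); `merge` keeps region duplicates (multiset semantics) but
deduplicates metadata pairs; `union` reconciles schemas by name, promoting
integer+float to float and rejecting string/numeric clashes; `difference`
keeps surviving regions whole (no clipping). Aggregates over empty groups
omit the pair (extend) or yield a missing value (map) rather than NaN; BAG
joins the sorted values with commas, duplicates preserved, empty string for
an empty group.

**Coordinate projection** evaluates `(start_expr, stop_expr)` in a
strand-aware frame: on the − strand the genome is reflected (g ↦ −g) so the
accessors read 5'→3' and additive offsets act in transcription direction;
results are reflected back, normalised so left ≤ right, clipped at 0, and
regions whose recomputed interval lies entirely below zero are dropped with
a logged count. One consequence: the integer midpoint `(START+STOP)//2`
floors on +/* strands and ceils on −, which never changes widths.

## Laziness and determinism

Operators build DAG nodes only; materialization evaluates bottom-up with
per-call memoisation of shared subtrees (no algebraic rewriting). Output
tables are pinned to (sample_id, chrom, start, stop) order and result
sample ids are deterministic strings derived from lineage (group keys, pair
ids like `left--right`), so re-running a query reproduces tables row for
row. Within-sample region order in `order(region_keys=...)` is therefore
visible on the in-memory dataset but re-sorted in the flattened tables.

## File formats

The dataset directory holds `schema.json`, and per sample `<id>.gdm`
(chrom TAB start TAB stop TAB strand TAB attributes) and `<id>.gdm.meta`
(attribute TAB value per line, repeated lines = repeated pairs). Writers
are bit-exact (unpadded integers, repr-minimal floats, LF, UTF-8); missing
values serialize as `.` and `.` in a typed column reads back as missing — a
documented dialect. The JSON schema descriptor is likewise a dialect chosen
for dependency-free parsing. Malformed records abort by default; a
skip-and-log policy is available (`--skip-bad-records`). Generic delimited
files are described by a `ParserSpec` whose coordinate basis is explicit
(files in the wild use both conventions; guessing corrupts positions
silently), with `stop_col="same-as-start"` turning single-position records
(e.g. GWAS variants) into width-1 intervals.

## Synthetic data and oracles

The generator emulates multi-sample peak collections: per sample, a seeded
draw of interval count, length, position (optionally keeping a margin clear
at the chromosome tip, where real tracks have no peaks), strand, a uniform
float signal, and one value per metadata vocabulary attribute. It does not
model peak shape, signal autocorrelation, replicate structure beyond what
fixtures add explicitly, or realistic chromosome sizes — so passing tests
certify the algebra's semantics, not biological realism of any result.

Reference implementations are deliberately naive and independent of the
production code (shared primitives: `region_distance` and the strand rule
only): cover variants are derived from a literal per-base count over the
genome, map/join/difference from all-pairs distance scans. The equivalence
battery draws 200 instances (seeds base+0..199; genome 2–10 kb, 1–3
samples/side, 4–20 regions/sample, zero-length regions included, mixed
strands) and compares every cover variant, map counts and means, DLE/DGE/
MD(1) joins and difference. Instance sizes keep the quadratic oracles
comfortable on one CPU while staying inside the stated bounds (≤ 10 kb,
≤ 10 samples, ≤ 50 regions).

## Pipelines

Fixed defaults: promoter flank 2000 bp around the strand-aware TSS;
enhancer half-width 1500 bp around peak midpoints (normalised enhancers are
exactly 3000 bp); `max_overlapping` = 2 cell lines for cell-specificity.
Pipeline fixtures carry engineered spike-ins on a dedicated chromosome — a
GWAS trait inside the only cell-specific enhancer of one cell line, and a
TF pair bound 12 bp apart inside a promoter — so recovery is an exact,
seeded check. "Active promoters" for the TF pipeline are an input dataset
(synthetic in the fixtures). Trait counting after the enhancer pipeline
splits the per-region BAG strings; a region matching several specific
fragments would contribute its variants once per fragment, which the
spike-in construction avoids by keeping the spike isolated. Heatmaps are
rendered best-effort; the TSV tables and the `manifest.json` parameter log
are the tested artifacts.

## Known limitations

No assembly awareness, liftover or sequence content; no BAM/VCF/bigWig
ingestion (convert externally to BED/TSV); no remote execution or
repository access; no percentage/ALL accumulation thresholds in cover; no
upstream/downstream-constrained or three-way joins (compose pairwise).
String values containing tabs or newlines are not escaped by the writers.
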