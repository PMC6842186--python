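"""Three desk-scale demonstration pipelines over the region algebra, plus
seeded synthetic fixture generators for each.

1. Promoter signal — strand-aware promoter windows around gene TSSs, ChIP-seq
   peak samples filtered by a metadata predicate, mean peak signal mapped per
   promoter, pivoted to a gene x sample matrix.
2. Cell-specific enhancers x GWAS — peak midpoints extended to fixed-width
   putative enhancers, consensus per cell line (cover with groupBy), a second
   cover keeping regions active in at most ``max_overlapping`` cell lines, a
   DLE(0) join back to the per-cell consensus, and GWAS variants mapped on
   with COUNT and a BAG of traits.
3. Minimal-distance TF pairs — replicate merging per transcription factor
   (cover with groupBy), restriction to promoter-overlapping bindings via a
   DLE(0) join, then an MD(1) join per TF pair extracting nearest binding
   pairs with their distances.

Each pipeline is deterministic given (inputs, config), writes its tables as
TSV plus a ``manifest.json`` of all parameters, and renders heatmaps on a
best-effort basis (the numeric tables are the tested artifact).
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import dag, io, synth
from .binary import DLE, MD
from .model import (
    Dataset,
    GenomicRegion,
    MetadataStore,
    RegionSchema,
    Sample,
)
from .unary import START, STOP, AggregateSpec, MetaAttr

logger = logging.getLogger("regal.pipelines")


@dataclass
class PipelineConfig:
    """Shared pipeline parameters.

    ``flank``: promoter half-window around the TSS (bp).
    ``interval``: enhancer half-width around the peak midpoint (bp); the
    normalised enhancers are exactly ``2 * interval`` bp long.
    ``max_overlapping``: a cell-specific region may be active in at most
    this many cell lines (typically 1 or 2).
    ``meta_attribute`` / ``meta_value``: sample selection predicate of the
    promoter-signal pipeline.
    ``group_attribute``: metadata attribute naming the cell line (pipeline
    2) or the experiment identity for replicate merging (pipeline 3).
    """

    flank: int = 2000
    interval: int = 1500
    max_overlapping: int = 2
    meta_attribute: str = "experiment_target"
    meta_value: str = "H3K9ac"
    group_attribute: str = "biosample_term_name"
    seed: int = 0

    def __post_init__(self):
        if self.flank < 0 or self.interval < 0:
            raise ValueError("flank and interval must be >= 0 bp")
        if self.max_overlapping < 1:
            raise ValueError("max_overlapping must be >= 1")


def _write_manifest(out_dir: Path, pipeline: str, config: PipelineConfig,
                    extra: dict) -> None:
    doc = {"pipeline": pipeline, "config": asdict(config), **extra}
    (out_dir / "manifest.json").write_text(
        json.dumps(doc, indent=2, default=str) + "\n", encoding="utf-8"
    )


def _heatmap(df: pd.DataFrame, path: Path, title: str) -> None:
    """Best-effort heatmap rendering; failures only log."""
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(max(4, 0.5 * df.shape[1] + 2),
                     max(3, 0.3 * df.shape[0] + 2)))
        data = df.astype(float).to_numpy()
        im = ax.imshow(data, aspect="auto", cmap="viridis")
        ax.set_xticks(range(df.shape[1]), [str(c) for c in df.columns],
                      rotation=90, fontsize=7)
        ax.set_yticks(range(df.shape[0]), [str(i) for i in df.index],
                      fontsize=7)
        ax.set_title(title)
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
    except Exception as exc:  # pragma: no cover - rendering is best-effort
        logger.warning("heatmap rendering failed: %s", exc)


# ---------------------------------------------------------------------------
# pipeline 1: promoter signal matrix
# ---------------------------------------------------------------------------

def pipeline_promoter_signal(genes_path, peaks_path, config: PipelineConfig,
                             out_dir=None,
                             column_attribute: str = "cell") -> pd.DataFrame:
    """Mean ChIP-seq signal per promoter per selected sample.

    Selects peak samples whose ``meta_attribute`` carries ``meta_value``,
    projects genes to the strand-aware window [TSS - flank, TSS + flank],
    maps AVG(signal) of the strictly overlapping peaks onto each promoter,
    and pivots to a gene x ``column_attribute`` matrix (missing cells 0).
    """
    genes = dag.load_from_path(genes_path)
    peaks = dag.load_from_path(peaks_path)
    selected = peaks.select(
        meta=MetaAttr(config.meta_attribute) == config.meta_value)
    promoters = genes.project(
        new_coordinates=(START - config.flank, START + config.flank))
    mapped = promoters.map(
        selected, aggs=[AggregateSpec("AVG", "signal", "avg_signal")])
    result = mapped.materialize()
    if result.regions.empty:
        raise ValueError(
            f"no peak samples satisfy {config.meta_attribute} == "
            f"{config.meta_value!r}"
        )
    matrix = dag.to_matrix(result, index_cols="gene_id",
                           column_key=f"right.{column_attribute}",
                           value_col="avg_signal", fill=0.0)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        matrix.to_csv(out_dir / "promoter_signal_matrix.tsv", sep="\t")
        _heatmap(matrix, out_dir / "promoter_signal_heatmap.png",
                 "mean peak signal per promoter")
        _write_manifest(out_dir, "promoter_signal", config, {
            "genes_path": str(genes_path), "peaks_path": str(peaks_path),
            "n_genes": int(matrix.shape[0]), "n_columns": int(matrix.shape[1]),
        })
    return matrix


# ---------------------------------------------------------------------------
# pipeline 2: GWAS traits on cell-specific enhancers
# ---------------------------------------------------------------------------

#: Layout of the synthetic GWAS TSV: trait in column 7, chromosome in column
#: 11, 1-based position in column 12 (single-position records).
GWAS_PARSER = io.ParserSpec(
    chrom_col=11, start_col=12, stop_col=io.SAME_AS_START,
    coordinate_basis="1-based",
    attr_cols=[(7, "trait", "string")],
)


def pipeline_cell_specific_enhancers(gwas_path, peaks_path,
                                     config: PipelineConfig,
                                     out_dir=None,
                                     parser: io.ParserSpec = GWAS_PARSER):
    """Count GWAS variants (and collect their traits) on enhancers active in
    at most ``max_overlapping`` cell lines.

    Returns ``(trait_counts, mapped_result)`` where ``trait_counts`` is a
    cell-line x trait table of variant counts on that cell line's specific
    enhancers.
    """
    gwas = dag.load_from_file(gwas_path, parser)
    peaks = dag.load_from_path(peaks_path)
    # midpoint, then symmetric extension: enhancers of exactly 2*interval bp
    midpoints = peaks.project(new_coordinates=((START + STOP) // 2,
                                               (START + STOP) // 2))
    enhancers = midpoints.project(
        new_coordinates=(START - config.interval, STOP + config.interval))
    per_cell = enhancers.normal_cover(min_acc=1,
                                      group_by=config.group_attribute)
    specific = per_cell.normal_cover(min_acc=1,
                                     max_acc=config.max_overlapping)
    cell_specific = per_cell.join(specific, DLE(0), output="LEFT")
    mapped = cell_specific.map(
        gwas, aggs=[AggregateSpec("BAG", "trait", "traits")])
    result = mapped.materialize()

    counts: dict = {}
    meta = result.metadata
    # the grouping attribute reaches the result under stacked left. prefixes
    # (one per binary operator on the reference side)
    is_cell_attr = meta["attribute"].map(
        lambda a: a.split(".")[-1] == config.group_attribute
        and not a.startswith("right."))
    cell_of = dict(meta[is_cell_attr][["sample_id", "value"]].values)
    for row in result.regions.itertuples(index=False):
        cell = cell_of.get(row.sample_id)
        if cell is None or not row.traits:
            continue
        for trait in row.traits.split(","):
            counts[(cell, trait)] = counts.get((cell, trait), 0) + 1
    trait_counts = pd.Series(counts, dtype="int64").unstack(fill_value=0) \
        if counts else pd.DataFrame()
    if not trait_counts.empty:
        trait_counts = trait_counts.sort_index(axis=0).sort_index(axis=1)
        trait_counts.index.name = config.group_attribute
        trait_counts.columns.name = "trait"
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        trait_counts.to_csv(out_dir / "trait_counts.tsv", sep="\t")
        if not trait_counts.empty:
            _heatmap(trait_counts, out_dir / "trait_counts_heatmap.png",
                     "GWAS variants on cell-specific enhancers")
        _write_manifest(out_dir, "cell_specific_enhancers", config, {
            "gwas_path": str(gwas_path), "peaks_path": str(peaks_path),
            "n_cells": int(trait_counts.shape[0]),
            "n_traits": int(trait_counts.shape[1]),
        })
    return trait_counts, result


# ---------------------------------------------------------------------------
# pipeline 3: minimal-distance TF binding pairs
# ---------------------------------------------------------------------------

def pipeline_min_distance_pairs(tf_path, promoters_path,
                                config: PipelineConfig,
                                out_dir=None,
                                target_attribute: str = "experiment_target"
                                ) -> pd.DataFrame:
    """Nearest binding pairs, per TF pair, within active promoter regions.

    Replicate samples of the same TF are merged with a grouped cover, each
    TF's bindings are restricted to those overlapping a promoter (DLE(0)
    join), and every unordered pair of distinct TFs contributes its MD(1)
    minimal-distance binding pairs.  Returns a table with columns
    (tf_left, tf_right, chrom, left_start, left_stop, right_start,
    right_stop, distance).
    """
    tfs = dag.load_from_path(tf_path)
    promoters = dag.load_from_path(promoters_path)
    merged = tfs.normal_cover(min_acc=1, group_by=target_attribute)
    active = merged.join(promoters, DLE(0), output="LEFT")
    active_rt = active.materialize()

    meta = active_rt.metadata
    attr = f"left.{target_attribute}"
    targets = sorted(set(meta[meta["attribute"] == attr]["value"]))
    if len(targets) < 2:
        raise ValueError(
            f"need at least 2 distinct transcription factors, found "
            f"{len(targets)}"
        )
    # back to a variable; keep the TF identity as plain metadata again
    base = dag.to_source(active_rt, name="active_bindings")
    rows = []
    for tf_a, tf_b in itertools.combinations(targets, 2):
        left = base.select(meta=MetaAttr(attr) == tf_a)
        right = base.select(meta=MetaAttr(attr) == tf_b)
        pairs = left.join(right, MD(1), output="CAT", ignore_strand=True)
        rt = pairs.materialize()
        for row in rt.regions.itertuples(index=False):
            d = row._asdict()
            rows.append({
                "tf_left": tf_a, "tf_right": tf_b, "chrom": d["chrom"],
                "span_start": int(d["start"]), "span_stop": int(d["stop"]),
                "distance": int(d["distance"]),
            })
    table = pd.DataFrame(
        rows, columns=["tf_left", "tf_right", "chrom", "span_start",
                       "span_stop", "distance"],
    ).sort_values(["tf_left", "tf_right", "chrom", "span_start"],
                  kind="stable").reset_index(drop=True)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "tf_pairs.tsv", sep="\t", index=False)
        _write_manifest(out_dir, "min_distance_pairs", config, {
            "tf_path": str(tf_path), "promoters_path": str(promoters_path),
            "n_tf": len(targets), "n_pairs_evaluated":
                len(targets) * (len(targets) - 1) // 2,
            "n_rows": int(table.shape[0]),
        })
    return table


# ---------------------------------------------------------------------------
# seeded fixtures
# ---------------------------------------------------------------------------

def make_promoter_fixture(root, seed: int = 0, n_genes: int = 5,
                          n_samples: int = 6) -> dict:
    """Gene annotation + peak datasets for pipeline 1.

    Half the peak samples target H3K9ac (and pass the default metadata
    filter); genes sit on both strands.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    root = Path(root)
    gene_schema = RegionSchema((("gene_id", "string"),))
    genes = []
    for i in range(n_genes):
        start = int(rng.integers(10_000, 80_000))
        strand = "+" if i % 2 == 0 else "-"
        genes.append(GenomicRegion("chr1", start, start + int(rng.integers(
            2_000, 10_000)), strand, (f"g{i}",)))
    genes_ds = Dataset(gene_schema, [Sample(
        "genes", genes, MetadataStore([("annotation", "synthetic-genes")]))])
    io.write_gdm_dataset(genes_ds, root / "genes")

    cfg = synth.SynthConfig(
        n_samples=n_samples,
        chrom_lengths={"chr1": 100_000},
        regions_per_sample=(30, 60),
        region_length=(200, 1_000),
        strand_probs=(0.0, 0.0, 1.0),
        metadata_vocab={},
        seed=seed + 1,
    )
    peaks_ds = synth.generate_dataset(cfg)
    cells = ["K562", "GM12878", "HepG2"]
    for i, s in enumerate(peaks_ds.samples):
        s.meta.add("experiment_target", "H3K9ac" if i % 2 == 0 else "CTCF")
        s.meta.add("cell", cells[i % len(cells)])
    io.write_gdm_dataset(peaks_ds, root / "peaks")
    return {"genes": root / "genes", "peaks": root / "peaks",
            "n_genes": n_genes,
            "n_selected": sum(1 for i in range(n_samples) if i % 2 == 0)}


def make_gwas_fixture(root, seed: int = 0, n_cells: int = 3,
                      interval: int = 1500) -> dict:
    """GWAS TSV + peak datasets for pipeline 2, with an engineered spike-in.

    On a dedicated chromosome, exactly one cell line has a peak; the
    spike-in variant (trait ``SpikeTrait``) falls inside the resulting
    cell-specific enhancer, so it must surface in that cell's trait counts.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    root = Path(root)
    cells = [f"cell{c}" for c in range(n_cells)]
    schema = RegionSchema((("signal", "float"),))
    samples = []
    for i, cell in enumerate(cells):
        regions = []
        for _ in range(25):
            # keep peaks >= interval away from the chromosome tip so the
            # normalised enhancers never clip at 0
            start = int(rng.integers(2_000, 190_000))
            regions.append(GenomicRegion(
                "chr1", start, start + int(rng.integers(200, 900)), "*",
                (float(round(rng.uniform(1, 10), 3)),)))
        if i == 0:
            # unique activity on chrS -> a cell0-specific enhancer
            regions.append(GenomicRegion("chrS", 50_000, 50_400, "*", (5.0,)))
        samples.append(Sample(
            f"peaks_{cell}", regions,
            MetadataStore([("biosample_term_name", cell),
                           ("assay", "ChIP-seq")])))
    peaks_ds = Dataset(schema, samples)
    io.write_gdm_dataset(peaks_ds, root / "peaks")

    # GWAS TSV: 12 columns, trait in col 7, chrom col 11, 1-based pos col 12
    midpoint = (50_000 + 50_400) // 2  # spike enhancer centre on chrS
    gwas_rows = []
    traits = ["Asthma", "T1D", "Height"]
    for j in range(40):
        chrom = "chr1"
        pos = int(rng.integers(1, 190_000))
        trait = traits[int(rng.integers(len(traits)))]
        gwas_rows.append((trait, chrom, pos))
    gwas_rows.append(("SpikeTrait", "chrS", midpoint + 1))  # 1-based
    lines = []
    for trait, chrom, pos in gwas_rows:
        fields = ["na"] * 12
        fields[6], fields[10], fields[11] = trait, chrom, str(pos)
        lines.append("\t".join(fields))
    gwas_path = root / "gwas.tsv"
    gwas_path.write_text("".join(l + "\n" for l in lines), encoding="utf-8")
    return {"gwas": gwas_path, "peaks": root / "peaks", "cells": cells,
            "spike_cell": cells[0], "spike_trait": "SpikeTrait"}


def make_tf_fixture(root, seed: int = 0, n_tfs: int = 3,
                    spike_distance: int = 12) -> dict:
    """TF binding + promoter datasets for pipeline 3, with an engineered
    nearest-neighbour pair.

    Each TF has two replicate samples with overlapping bindings.  On a
    dedicated chromosome, TF_A and TF_B bind ``spike_distance`` bp apart
    inside a promoter, with no other binding nearby, so the MD(1) join must
    report exactly that distance for the (TF_A, TF_B) pair.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    root = Path(root)
    schema = RegionSchema((("signal", "float"),))
    tf_names = [f"TF_{chr(ord('A') + i)}" for i in range(n_tfs)]
    samples = []
    promoter_regions = []
    for p in range(30):
        start = 3_000 * p + int(rng.integers(0, 800))
        promoter_regions.append(
            GenomicRegion("chr1", start, start + 2_000, "*", ()))
    for tf in tf_names:
        base_regions = []
        for _ in range(20):
            # bindings biased into promoters so the DLE(0) join keeps most
            anchor = promoter_regions[int(rng.integers(len(promoter_regions)))]
            start = int(rng.integers(anchor.start, anchor.stop - 200))
            base_regions.append(GenomicRegion(
                "chr1", start, start + int(rng.integers(50, 200)), "*",
                (float(round(rng.uniform(1, 10), 3)),)))
        for rep in (1, 2):
            regions = list(base_regions)
            if rep == 2:  # replicate with a small jitter subset
                regions = regions[: len(regions) - 3]
            if tf == "TF_A":
                regions.append(GenomicRegion("chrS", 10_000, 10_010, "*", (9.0,)))
            if tf == "TF_B":
                s = 10_010 + spike_distance
                regions.append(GenomicRegion("chrS", s, s + 8, "*", (9.0,)))
            samples.append(Sample(
                f"{tf}_rep{rep}", regions,
                MetadataStore([("experiment_target", tf),
                               ("replicate", str(rep))])))
    tf_ds = Dataset(schema, samples)
    io.write_gdm_dataset(tf_ds, root / "tf")
    promoter_regions.append(GenomicRegion("chrS", 9_500, 10_600, "*", ()))
    prom_ds = Dataset(RegionSchema(), [Sample(
        "promoters", promoter_regions,
        MetadataStore([("annotation", "synthetic-active-promoters")]))])
    io.write_gdm_dataset(prom_ds, root / "promoters")
    return {"tf": root / "tf", "promoters": root / "promoters",
            "tf_names": tf_names, "spike_pair": ("TF_A", "TF_B"),
            "spike_distance": spike_distance}
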