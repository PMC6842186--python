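import json

import pytest

from regal.pipelines import (
    GWAS_PARSER,
    PipelineConfig,
    make_gwas_fixture,
    make_promoter_fixture,
    make_tf_fixture,
    pipeline_cell_specific_enhancers,
    pipeline_min_distance_pairs,
    pipeline_promoter_signal,
)


@pytest.fixture(scope="module")
def config():
    return PipelineConfig(seed=11)


class TestPromoterSignal:
    def test_matrix_shape_and_manifest(self, tmp_path, config):
        fx = make_promoter_fixture(tmp_path / "fx", seed=config.seed)
        matrix = pipeline_promoter_signal(fx["genes"], fx["peaks"], config,
                                          out_dir=tmp_path / "out")
        assert matrix.shape[0] == fx["n_genes"]
        assert 1 <= matrix.shape[1] <= fx["n_selected"]
        manifest = json.loads((tmp_path / "out" / "manifest.json").read_text())
        assert manifest["config"]["flank"] == 2000
        assert (tmp_path / "out" / "promoter_signal_matrix.tsv").exists()

    def test_no_passing_samples_is_an_explicit_error(self, tmp_path, config):
        fx = make_promoter_fixture(tmp_path / "fx", seed=config.seed)
        bad = PipelineConfig(meta_value="NoSuchTarget", seed=config.seed)
        with pytest.raises(ValueError, match="NoSuchTarget"):
            pipeline_promoter_signal(fx["genes"], fx["peaks"], bad)

    def test_single_peak_covering_promoter_gives_its_signal(self, tmp_path):
        """A peak exactly covering one promoter puts its signal in the cell."""
        from regal import io
        from regal.model import (Dataset, GenomicRegion, MetadataStore,
                                 RegionSchema, Sample)

        genes = Dataset(RegionSchema((("gene_id", "string"),)), [Sample(
            "genes", [GenomicRegion("chr1", 5000, 9000, "+", ("g0",))],
            MetadataStore([("src", "t")]))])
        io.write_gdm_dataset(genes, tmp_path / "genes")
        peaks = Dataset(RegionSchema((("signal", "float"),)), [Sample(
            "p0", [GenomicRegion("chr1", 3000, 7000, "*", (7.0,))],
            MetadataStore([("experiment_target", "H3K9ac"),
                           ("cell", "K562")]))])
        io.write_gdm_dataset(peaks, tmp_path / "peaks")
        m = pipeline_promoter_signal(tmp_path / "genes", tmp_path / "peaks",
                                     PipelineConfig())
        assert m.loc["g0", "K562"] == 7.0


class TestEnhancerGwas:
    def test_normalised_enhancers_are_exactly_3000bp(self, tmp_path, config):
        from regal import dag
        from regal.unary import START, STOP

        fx = make_gwas_fixture(tmp_path / "fx", seed=config.seed)
        peaks = dag.load_from_path(fx["peaks"])
        mid = peaks.project(new_coordinates=((START + STOP) // 2,
                                             (START + STOP) // 2))
        enh = mid.project(new_coordinates=(START - config.interval,
                                           STOP + config.interval))
        rt = enh.materialize()
        widths = set(rt.regions["stop"] - rt.regions["start"])
        assert widths == {2 * config.interval} == {3000}

    def test_spiked_trait_recovered_in_its_cell_only(self, tmp_path, config):
        fx = make_gwas_fixture(tmp_path / "fx", seed=config.seed)
        counts, _ = pipeline_cell_specific_enhancers(
            fx["gwas"], fx["peaks"], config, out_dir=tmp_path / "out")
        col = counts[fx["spike_trait"]]
        assert col.loc[fx["spike_cell"]] == 1
        assert col.drop(fx["spike_cell"]).eq(0).all()
        assert (tmp_path / "out" / "trait_counts.tsv").exists()

    def test_gwas_parser_reads_one_based_single_positions(self, tmp_path,
                                                          config):
        fx = make_gwas_fixture(tmp_path / "fx", seed=config.seed)
        from regal.io import parse_custom_tsv

        sample = parse_custom_tsv(fx["gwas"], GWAS_PARSER)
        assert all(r.length == 1 for r in sample.regions)
        spike = [r for r in sample.regions if r.attrs == ("SpikeTrait",)]
        assert len(spike) == 1 and spike[0].chrom == "chrS"

    def test_region_in_too_many_groups_excluded(self, tmp_path):
        """A region active in 3 cell lines is not cell-specific at
        max_overlapping=2."""
        from regal import io
        from regal.model import (Dataset, GenomicRegion, MetadataStore,
                                 RegionSchema, Sample)

        samples = [
            Sample(f"c{i}", [GenomicRegion("chr1", 50_000, 50_300, "*", (1.0,))],
                   MetadataStore([("biosample_term_name", f"cell{i}")]))
            for i in range(3)
        ]
        ds = Dataset(RegionSchema((("signal", "float"),)), samples)
        io.write_gdm_dataset(ds, tmp_path / "peaks")
        lines = ["\t".join(["na"] * 6 + ["TraitX"] + ["na"] * 3
                           + ["chr1", "50150"])]
        gwas = tmp_path / "gwas.tsv"
        gwas.write_text("".join(l + "\n" for l in lines))
        counts, _ = pipeline_cell_specific_enhancers(
            gwas, tmp_path / "peaks", PipelineConfig(max_overlapping=2))
        assert counts.empty  # shared region is never cell-specific


class TestTfPairs:
    def test_spiked_nearest_pair_distance_recovered(self, tmp_path, config):
        fx = make_tf_fixture(tmp_path / "fx", seed=config.seed,
                             spike_distance=12)
        table = pipeline_min_distance_pairs(fx["tf"], fx["promoters"], config,
                                            out_dir=tmp_path / "out")
        spike = table[(table.chrom == "chrS")
                      & (table.tf_left == fx["spike_pair"][0])
                      & (table.tf_right == fx["spike_pair"][1])]
        assert list(spike["distance"]) == [fx["spike_distance"]]

    def test_all_tf_pairs_evaluated(self, tmp_path, config):
        fx = make_tf_fixture(tmp_path / "fx", seed=config.seed, n_tfs=3)
        table = pipeline_min_distance_pairs(fx["tf"], fx["promoters"], config,
                                            out_dir=tmp_path / "out")
        pairs = set(map(tuple, table[["tf_left", "tf_right"]].values))
        assert pairs == {("TF_A", "TF_B"), ("TF_A", "TF_C"), ("TF_B", "TF_C")}
        manifest = json.loads((tmp_path / "out" / "manifest.json").read_text())
        assert manifest["n_pairs_evaluated"] == 3

    def test_fewer_than_two_tfs_errors(self, tmp_path, config):
        fx = make_tf_fixture(tmp_path / "fx", seed=config.seed, n_tfs=1)
        with pytest.raises(ValueError, match="at least 2"):
            pipeline_min_distance_pairs(fx["tf"], fx["promoters"], config)

    def test_replicates_collapse_after_cover(self, tmp_path, config):
        from regal import dag

        fx = make_tf_fixture(tmp_path / "fx", seed=config.seed)
        merged = dag.load_from_path(fx["tf"]).normal_cover(
            min_acc=1, group_by="experiment_target")
        rt = merged.materialize()
        assert sorted(rt.sample_ids) == sorted(fx["tf_names"])
        # duplicated replicate bindings appear once per TF
        per_tf = rt.regions.groupby("sample_id").size()
        assert (per_tf <= 25).all()


class TestConfig:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PipelineConfig(flank=-1)
        with pytest.raises(ValueError):
            PipelineConfig(max_overlapping=0)
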