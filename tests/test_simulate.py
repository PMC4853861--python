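"""The synthetic-data generator: determinism, LD structure, expression
generative model, annotation/peak geometry, GWAS catalog and network."""

import numpy as np
import pandas as pd
import pytest

from eqtldecon.simulate import (GwasSpec, NetworkSpec, PeakSpec, PlantedEffect,
                                PlantedEnhancer, SimulationConfig,
                                make_planted_study, simulate_annotation_and_peaks,
                                simulate_expression, simulate_genotypes,
                                simulate_gwas_and_network, simulate_study)


def small_config(**kw):
    base = dict(n_samples=100, n_snps=40, n_genes=20,
                genome=(("chr1", 5_000_000),), seed=0)
    base.update(kw)
    return SimulationConfig(**base)


class TestGenotypes:
    def test_determinism(self):
        cfg = small_config(seed=3)
        g1 = simulate_genotypes(cfg)
        g2 = simulate_genotypes(cfg)
        assert g1.dosages.equals(g2.dosages)
        assert g1.snps.equals(g2.snps)

    def test_dosages_are_0_1_2(self):
        g = simulate_genotypes(small_config())
        assert g.dosages.isin([0, 1, 2]).all(axis=None)

    def test_positions_strictly_increasing(self):
        g = simulate_genotypes(small_config(
            genome=(("chr1", 3_000_000), ("chr2", 3_000_000)), n_snps=60))
        for _, grp in g.snps.groupby("chrom"):
            assert (np.diff(grp["pos"].to_numpy()) > 0).all()

    def test_perfect_ld_block_duplicates_columns(self):
        cfg = small_config(ld_blocks=((2, 1.0),), n_snps=10)
        g = simulate_genotypes(cfg)
        for _, grp in g.snps.groupby("block"):
            cols = g.dosages[grp.index].to_numpy()
            if cols.shape[1] == 2:
                np.testing.assert_array_equal(cols[:, 0], cols[:, 1])

    def test_zero_ld_blocks_independent(self):
        cfg = SimulationConfig(n_samples=2000, n_snps=40, n_genes=5,
                               ld_blocks=((2, 0.0),),
                               genome=(("chr1", 5_000_000),), seed=1)
        g = simulate_genotypes(cfg)
        vals = []
        for _, grp in g.snps.groupby("block"):
            cols = g.dosages[grp.index].to_numpy(float)
            if cols.shape[1] == 2 and cols[:, 0].std() > 0 and cols[:, 1].std() > 0:
                vals.append(np.corrcoef(cols[:, 0], cols[:, 1])[0, 1] ** 2)
        assert np.mean(vals) < 0.01

    def test_realized_r2_near_target(self):
        cfg = SimulationConfig(n_samples=2000, n_snps=40, n_genes=5,
                               ld_blocks=((2, 0.8),),
                               genome=(("chr1", 5_000_000),), seed=2)
        g = simulate_genotypes(cfg)
        vals = []
        for _, grp in g.snps.groupby("block"):
            cols = g.dosages[grp.index].to_numpy(float)
            vals.append(np.corrcoef(cols[:, 0], cols[:, 1])[0, 1] ** 2)
        assert np.mean(vals) == pytest.approx(0.8, abs=0.05)

    def test_realized_maf_in_range(self):
        g = simulate_genotypes(small_config(n_samples=1000))
        maf = np.minimum(g.dosages.mean(0) / 2, 1 - g.dosages.mean(0) / 2)
        # binomial sampling slack at n=1000
        assert (maf > 0.05 - 3 * 0.011).all()

    def test_too_many_snps_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            simulate_genotypes(small_config(genome=(("chr1", 1_000),),
                                            n_snps=40))


class TestExpression:
    def test_no_effects_variance_close_to_noise(self):
        cfg = small_config(n_samples=2000, noise_sd=1.0)
        g = simulate_genotypes(cfg)
        expr, truth = simulate_expression(g, cfg)
        assert truth.empty
        assert expr.var(axis=0).mean() == pytest.approx(1.0, abs=0.05)

    def test_confounder_variance_closed_form(self):
        """With k factors of loading scale s, per-gene variance is about
        noise² + k·s² on average."""
        cfg = small_config(n_samples=1000, n_genes=200, noise_sd=1.0,
                           n_confounder_pcs=3, confounder_scale=1.0)
        g = simulate_genotypes(cfg)
        expr, _ = simulate_expression(g, cfg)
        assert expr.var(axis=0).mean() == pytest.approx(4.0, rel=0.15)

    def test_noiseless_limit_exact_slope(self):
        cfg = small_config(noise_sd=1e-12, planted_cis_effects=(
            PlantedEffect("rs01", "g01", 2.0),))
        g = simulate_genotypes(cfg)
        expr, truth = simulate_expression(g, cfg)
        x = g.dosage_vector("rs01")
        y = expr["g01"].to_numpy()
        slope = np.cov(x, y)[0, 1] / np.var(x, ddof=1)
        assert slope == pytest.approx(2.0, abs=1e-6)
        assert truth.iloc[0].to_dict() == {"snp": "rs01", "gene": "g01",
                                           "beta": 2.0}

    def test_confounder_pcs_dominate_variance(self):
        cfg = small_config(n_samples=500, n_genes=50, noise_sd=0.5,
                           n_confounder_pcs=3, confounder_scale=3.0)
        g = simulate_genotypes(cfg)
        expr, _ = simulate_expression(g, cfg)
        x = expr.to_numpy() - expr.to_numpy().mean(0)
        s = np.linalg.svd(x, compute_uv=False)
        share = (s[:3] ** 2).sum() / (s ** 2).sum()
        assert share > 0.5

    def test_unknown_planted_ids_rejected(self):
        cfg = small_config(planted_cis_effects=(
            PlantedEffect("rs_nope", "g01", 1.0),))
        g = simulate_genotypes(cfg)
        with pytest.raises(ValueError, match="unknown SNP"):
            simulate_expression(g, cfg)


class TestAnnotationAndPeaks:
    def test_planted_enhancer_covers_snp(self):
        cfg = small_config(peak_spec=PeakSpec(planted_enhancers=(
            PlantedEnhancer("monocyte", "H3K27ac", "rs05"),)))
        ann, peaks, seg, truth = simulate_annotation_and_peaks(cfg)
        from eqtldecon.simulate import snp_map
        pos = int(snp_map(cfg).loc["rs05", "pos"])
        enh = peaks[("monocyte", "H3K27ac")].df
        planted = enh[enh["name"].str.contains("enh_rs05")]
        assert len(planted) == 1
        assert planted["start"].iloc[0] <= pos - 1 < planted["end"].iloc[0]

    def test_segmentation_tiles_genome(self):
        cfg = small_config(genome=(("chr1", 1_000_000),))
        _, _, seg, _ = simulate_annotation_and_peaks(cfg)
        df = seg.df[seg.df["chrom"] == "chr1"].sort_values("start")
        assert df["start"].iloc[0] == 0
        assert df["end"].iloc[-1] == 1_000_000
        assert (df["start"].iloc[1:].to_numpy()
                == df["end"].iloc[:-1].to_numpy()).all()
        assert (df["end"] - df["start"]).sum() == 1_000_000

    def test_peak_fold_filter_removes_about_half(self):
        cfg = small_config(peak_spec=PeakSpec(n_background_peaks=2000,
                                              fold_range=(0.5, 7.5)),
                           genome=(("chr1", 50_000_000),), n_snps=40)
        _, peaks, _, _ = simulate_annotation_and_peaks(cfg)
        from eqtldecon.intervals import filter_peaks
        df = peaks[("monocyte", "H3K4me1")]
        frac = len(filter_peaks(df)) / len(df)
        assert frac == pytest.approx(0.5, abs=0.05)

    def test_unknown_planted_snp_rejected(self):
        cfg = small_config(peak_spec=PeakSpec(planted_enhancers=(
            PlantedEnhancer("monocyte", "H3K27ac", "rs_nope"),)))
        with pytest.raises(ValueError, match="unknown SNP"):
            simulate_annotation_and_peaks(cfg)

    def test_planted_effect_genes_always_active(self):
        cfg = small_config(planted_cis_effects=(
            PlantedEffect("rs01", "g01", 1.0),),
            peak_spec=PeakSpec(inactive_gene_fraction=0.5))
        _, _, _, truth = simulate_annotation_and_peaks(cfg)
        for ct, active in truth["active_genes"].items():
            assert "g01" in active


class TestGwasAndNetwork:
    def test_path_module_connected(self):
        cfg = small_config(network_spec=NetworkSpec(
            module_genes=("g01", "g02", "g03", "g04", "g05"),
            module_shape="path", edge_density=0.0))
        _, edges, truth = simulate_gwas_and_network(cfg)
        assert len(edges) == 4  # path over 5 nodes, no background
        import networkx as nx
        g = nx.Graph()
        g.add_edges_from(edges.itertuples(index=False, name=None))
        assert nx.is_connected(g.subgraph(truth["module_genes"]))

    def test_er_background_edge_count(self):
        cfg = small_config(n_genes=300, network_spec=NetworkSpec(
            n_extra_nodes=200, edge_density=0.01, module_genes=()))
        _, edges, _ = simulate_gwas_and_network(cfg)
        n = 500
        expected = 0.01 * n * (n - 1) / 2
        assert len(edges) == pytest.approx(expected, rel=0.2)

    def test_module_node_must_exist(self):
        cfg = small_config(network_spec=NetworkSpec(module_genes=("nope",)))
        with pytest.raises(ValueError, match="absent"):
            simulate_gwas_and_network(cfg)

    def test_gwas_snp_must_exist(self):
        cfg = small_config(gwas_spec=GwasSpec(traits=(("t", ("rs_nope",)),)))
        with pytest.raises(ValueError, match="unknown SNP"):
            simulate_gwas_and_network(cfg)

    def test_catalog_lists_positions(self):
        cfg = small_config(gwas_spec=GwasSpec(traits=(("t", ("rs01", "rs02")),)))
        catalog, _, _ = simulate_gwas_and_network(cfg)
        assert set(catalog.columns) == {"trait", "snp", "chrom", "pos"}
        assert len(catalog) == 2


class TestStudyClosure:
    def test_full_study_deterministic(self):
        cfg = make_planted_study(seed=5)
        s1 = simulate_study(cfg)
        s2 = simulate_study(cfg)
        assert s1.geno.dosages.equals(s2.geno.dosages)
        assert s1.expr.equals(s2.expr)
        assert s1.gwas_catalog.equals(s2.gwas_catalog)
        assert s1.network_edges.equals(s2.network_edges)
        assert s1.segmentation.df.equals(s2.segmentation.df)
        for key in s1.peaks:
            assert s1.peaks[key].df.equals(s2.peaks[key].df)

    def test_planted_truth_closure(self, planted_study):
        """Every planted element appears in the emitted ground truth."""
        truth = planted_study.truth
        assert len(truth["planted_effects"]) == 5
        for eff in truth["planted_effects"].itertuples():
            assert eff.snp in planted_study.geno.snp_ids
            assert eff.gene in planted_study.expr.columns
            for ct, active in truth["active_genes"].items():
                assert eff.gene in active
        for pe in truth["planted_enhancers"]:
            assert pe.snp in planted_study.geno.snp_ids
        module = truth["module_genes"]
        import networkx as nx
        g = nx.Graph()
        g.add_edges_from(planted_study.network_edges.itertuples(
            index=False, name=None))
        assert nx.is_connected(g.subgraph(module))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_samples=0)
        with pytest.raises(ValueError):
            SimulationConfig(maf_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            SimulationConfig(ld_blocks=((2, 1.5),))
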