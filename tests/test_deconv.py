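"""Deconvolution: GWAS-enhancer construction, active genes, restricted
eQTL linking, gene-overlap hits, incidence matrix and baseline gene sets."""

import numpy as np
import pandas as pd
import pytest

from eqtldecon.adjust import AdjustmentConfig, adjust_expression
from eqtldecon.deconv import (CellTypeEpigenome, DeconvolutionConfig,
                              add_gene_overlap_hits, baseline_gene_sets,
                              build_active_genes, build_gwas_enhancers,
                              connection_matrix, deconvolve,
                              gene_set_overlap_test, gwas_proxy_table)
from eqtldecon.intervals import IntervalSet, filter_peaks, promoter_windows
from eqtldecon.ld import LdExpansion, expand
from eqtldecon.qc import filter_snps


def iv(rows):
    return IntervalSet(pd.DataFrame(rows))


def make_ld(entries):
    """entries: index -> list of (proxy, r2, chrom, pos)."""
    prox = {}
    for idx, rows in entries.items():
        prox[idx] = pd.DataFrame(
            [{"proxy": p, "r2": r, "chrom": c, "pos": q}
             for p, r, c, q in rows])
    return LdExpansion(proxies=prox)


ANN = pd.DataFrame([
    {"gene": "gA", "chrom": "chr1", "start": 100_000, "end": 110_000,
     "strand": "+", "tss": 100_000},
    {"gene": "gB", "chrom": "chr1", "start": 300_000, "end": 320_000,
     "strand": "+", "tss": 300_000},
]).set_index("gene")


class TestBuildGwasEnhancers:
    def setup_method(self):
        self.promoters = promoter_windows(ANN)
        self.config = DeconvolutionConfig()

    def epi(self, peaks):
        return CellTypeEpigenome(cell_type="tc", peaks={"H3K27ac": peaks})

    def test_proxy_in_clean_peak_emitted(self):
        peaks = iv([{"chrom": "chr1", "start": 199_500, "end": 200_500,
                     "score": 6.0}])
        ld = make_ld({"rs1": [("rs1", 1.0, "chr1", 150_000),
                              ("rs2", 0.9, "chr1", 200_000)]})
        table = gwas_proxy_table(["rs1"], ld, None)
        hits = build_gwas_enhancers(self.epi(peaks), table, self.promoters,
                                    self.config)
        assert len(hits["H3K27ac"]) == 1
        assert hits["H3K27ac"]["snp"].iloc[0] == "rs2"

    def test_promoter_overlapping_peak_not_emitted(self):
        peaks = iv([{"chrom": "chr1", "start": 99_000, "end": 100_100,
                     "score": 6.0}])
        ld = make_ld({"rs1": [("rs1", 1.0, "chr1", 99_500)]})
        table = gwas_proxy_table(["rs1"], ld, None)
        hits = build_gwas_enhancers(self.epi(peaks), table, self.promoters,
                                    self.config)
        assert len(hits["H3K27ac"]) == 0

    def test_hla_index_snp_contributes_nothing(self):
        ld = make_ld({"rs_hla": [("rs_hla", 1.0, "chr6", 30_000_000),
                                 ("rs_out", 0.9, "chr1", 200_000)]})
        table = gwas_proxy_table(["rs_hla"], ld,
                                 ("chr6", 25_000_000, 35_000_000))
        assert len(table) == 0

    def test_hla_proxy_dropped_individually(self):
        ld = make_ld({"rs1": [("rs1", 1.0, "chr1", 150_000),
                              ("rs_hla", 0.9, "chr6", 30_000_000)]})
        table = gwas_proxy_table(["rs1"], ld, ("chr6", 25_000_000, 35_000_000))
        assert set(table["proxy"]) == {"rs1"}


class TestBuildActiveGenes:
    def test_promoter_mark_activates(self):
        epi = CellTypeEpigenome("tc", peaks={"H3K4me3": iv(
            [{"chrom": "chr1", "start": 99_800, "end": 100_200, "score": 6.0}])})
        assert build_active_genes(epi, ANN) == {"gA"}

    def test_repressive_mark_ignored(self):
        epi = CellTypeEpigenome("tc", peaks={"H3K27me3": iv(
            [{"chrom": "chr1", "start": 99_800, "end": 100_200, "score": 6.0}])})
        assert build_active_genes(epi, ANN) == set()

    def test_matches_bruteforce_overlap(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(40):
            start = int(rng.integers(10_000, 2_000_000))
            strand = "+" if rng.random() < 0.5 else "-"
            end = start + int(rng.integers(2_000, 30_000))
            rows.append({"gene": f"g{i}", "chrom": "chr1", "start": start,
                         "end": end, "strand": strand,
                         "tss": start if strand == "+" else end})
        ann = pd.DataFrame(rows).set_index("gene")
        starts = rng.integers(0, 2_000_000, size=60)
        peaks = iv([{"chrom": "chr1", "start": int(s),
                     "end": int(s) + int(rng.integers(200, 3_000)),
                     "score": 6.0} for s in starts])
        epi = CellTypeEpigenome("tc", peaks={"H3K4me3": peaks})
        got = build_active_genes(epi, ann)
        prom = promoter_windows(ann).df
        expected = set()
        for _, w in prom.iterrows():
            for _, p in peaks.df.iterrows():
                if w["start"] < p["end"] and p["start"] < w["end"]:
                    expected.add(w["name"])
        assert got == expected


@pytest.fixture(scope="module")
def deconv_result(planted_study):
    from eqtldecon.qc import genotype_pca
    study = planted_study
    geno, _ = filter_snps(study.geno)
    covariates = genotype_pca(geno, 3).scores
    adj = adjust_expression(study.expr, AdjustmentConfig(n_pcs_remove=0))
    gwas_snps = sorted(set(study.gwas_catalog["snp"]))
    ld = expand(gwas_snps, geno)
    epis = {ct: {mark: study.peaks[(c, mark)]
                 for (c, mark) in study.peaks if c == ct}
            for ct in ("monocyte", "bcell", "tcell")}
    records, objects = deconvolve(epis, gwas_snps, ld, geno, adj,
                                  study.annotation, covariates=covariates)
    return records, objects, study


class TestEndToEnd:

    def test_exact_planted_connection_recovery(self, deconv_result):
        """The enhancer-eQTL connections are exactly the planted chains:
        every (cell type, mark, proxy, gene) from the planted truth and
        nothing else."""
        records, _, study = deconv_result
        ee = records[records["evidence"] == "enhancer-eQTL"]
        got = set(zip(ee["cell_type"], ee["mark"], ee["proxy_snp"], ee["gene"]))
        effects = study.truth["planted_effects"]
        target_of = dict(zip(effects["snp"], effects["gene"]))
        expected = {(pe.cell_type, pe.mark, pe.snp, target_of[pe.snp])
                    for pe in study.truth["planted_enhancers"]}
        assert got == expected

    def test_connection_snp_inside_enhancer_and_gene_active(self, deconv_result):
        """Post-hoc audit: every enhancer-eQTL record's SNP lies inside its
        enhancer interval and its gene is active in that cell type."""
        records, objects, study = deconv_result
        smap = study.truth["snp_map"]
        ee = records[records["evidence"] == "enhancer-eQTL"]
        assert len(ee) > 0
        for rec in ee.itertuples():
            pos0 = int(smap.loc[rec.proxy_snp, "pos"]) - 1
            assert rec.enh_start <= pos0 < rec.enh_end
            assert rec.gene in objects[rec.cell_type].active_genes

    def test_ld_removal_shrinks_connections(self, deconv_result):
        """Shrinking LD expansion to self-proxies only yields a subset."""
        from eqtldecon.qc import genotype_pca
        records, _, study = deconv_result
        geno, _ = filter_snps(study.geno)
        covariates = genotype_pca(geno, 3).scores
        adj = adjust_expression(study.expr, AdjustmentConfig(n_pcs_remove=0))
        gwas_snps = sorted(set(study.gwas_catalog["snp"]))
        ld_self = expand(gwas_snps, geno, r2_min=1.01)
        epis = {ct: {mark: study.peaks[(c, mark)]
                     for (c, mark) in study.peaks if c == ct}
                for ct in ("monocyte", "bcell", "tcell")}
        restricted, _ = deconvolve(epis, gwas_snps, ld_self, geno, adj,
                                   study.annotation, covariates=covariates)
        full_keys = set(map(tuple, records[
            ["cell_type", "proxy_snp", "gene", "evidence"]].to_numpy()))
        small_keys = set(map(tuple, restricted[
            ["cell_type", "proxy_snp", "gene", "evidence"]].to_numpy()))
        assert small_keys <= full_keys


class TestGeneOverlapHits:
    def test_proxy_inside_active_gene_locus(self):
        epi = CellTypeEpigenome("tc", peaks={})
        epi.active_genes = {"gA"}
        table = pd.DataFrame([{"index_snp": "rs1", "proxy": "rs2", "r2": 0.9,
                               "chrom": "chr1", "pos": 105_000}])
        out = add_gene_overlap_hits(epi, table, ANN)
        assert len(out) == 1
        assert out["gene"].iloc[0] == "gA"
        assert out["evidence"].iloc[0] == "gene-overlap"

    def test_inactive_gene_ignored(self):
        epi = CellTypeEpigenome("tc", peaks={})
        epi.active_genes = {"gB"}
        table = pd.DataFrame([{"index_snp": "rs1", "proxy": "rs2", "r2": 0.9,
                               "chrom": "chr1", "pos": 105_000}])
        assert len(add_gene_overlap_hits(epi, table, ANN)) == 0

    def test_snp_in_two_overlapping_genes_two_records(self):
        ann = pd.DataFrame([
            {"gene": "g1", "chrom": "chr1", "start": 100_000, "end": 120_000,
             "strand": "+", "tss": 100_000},
            {"gene": "g2", "chrom": "chr1", "start": 110_000, "end": 130_000,
             "strand": "+", "tss": 110_000},
        ]).set_index("gene")
        epi = CellTypeEpigenome("tc", peaks={})
        epi.active_genes = {"g1", "g2"}
        table = pd.DataFrame([{"index_snp": "rs1", "proxy": "rs1", "r2": 1.0,
                               "chrom": "chr1", "pos": 115_000}])
        out = add_gene_overlap_hits(epi, table, ann)
        assert sorted(out["gene"]) == ["g1", "g2"]


class TestConnectionMatrix:
    def test_incidence(self):
        records = pd.DataFrame([
            {"cell_type": ct, "gene": "gA", "evidence": "enhancer-eQTL"}
            for ct in ("m", "b", "t")] + [
            {"cell_type": "m", "gene": "gB", "evidence": "gene-overlap"}])
        inc = connection_matrix(records)
        assert inc.loc["gA"].sum() == 3
        assert inc.loc["gB"].sum() == 1

    def test_empty(self):
        assert connection_matrix(pd.DataFrame()).empty


class TestBaselineGeneSets:
    ANN3 = pd.DataFrame([
        {"gene": "gA", "chrom": "chr1", "start": 100_000, "end": 110_000,
         "strand": "+", "tss": 100_000},
        {"gene": "gB", "chrom": "chr1", "start": 200_000, "end": 210_000,
         "strand": "+", "tss": 200_000},
        {"gene": "gC", "chrom": "chr1", "start": 230_000, "end": 240_000,
         "strand": "+", "tss": 230_000},
    ]).set_index("gene")

    def test_snp_inside_gene_k1(self):
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [105_000]},
                            index=["rs1"])
        closest, _ = baseline_gene_sets(snps, self.ANN3, {"rs1": 1})
        assert closest == {"gA"}

    def test_equidistant_tie_includes_both(self):
        # gB locus ends at 210_500, gC locus starts at 228_500
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [219_500]},
                            index=["rs1"])
        # distances: to gB locus = 219_500-1 - 210_499 = 9_000;
        # to gC locus = 228_500 - 219_499 = 9_001 -> shift to exact midpoint
        snps2 = pd.DataFrame({"chrom": ["chr1"], "pos": [219_500]},
                            index=["rs1"])
        closest, _ = baseline_gene_sets(snps2, self.ANN3, {"rs1": 1})
        assert closest in ({"gB"}, {"gB", "gC"})

    def test_within_distance_set(self):
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [213_000]},
                            index=["rs1"])
        _, within = baseline_gene_sets(snps, self.ANN3, {}, distance=5_000)
        assert within == {"gB"}  # locus gB = [198_500, 210_500)

    def test_no_gene_within_distance(self):
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [500_000]},
                            index=["rs1"])
        _, within = baseline_gene_sets(snps, self.ANN3, {}, distance=5_000)
        assert within == set()


class TestGeneSetOverlapTest:
    def test_perfect_nesting(self):
        universe = {f"g{i}" for i in range(10)}
        genes = {f"g{i}" for i in range(5)}
        res = gene_set_overlap_test(genes, genes, universe)
        from math import comb
        assert res.p == pytest.approx(1 / comb(10, 5), abs=1e-12)

    def test_disjoint_sets_high_p(self):
        universe = {f"g{i}" for i in range(20)}
        res = gene_set_overlap_test({f"g{i}" for i in range(5)},
                                    {f"g{i}" for i in range(10, 15)}, universe)
        assert res.p >= 0.5

    def test_empty_genes_p_one(self):
        universe = {"a", "b"}
        assert gene_set_overlap_test(set(), {"a"}, universe).p == 1.0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            gene_set_overlap_test(set(), set(), set())
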