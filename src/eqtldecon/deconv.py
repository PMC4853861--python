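"""Deconvolution of GWAS risk loci into (cell type, enhancer, gene)
connections.

Four steps per cell-type epigenome:

1. **GWAS enhancers** — histone-mark peaks (fold-enrichment > 4) minus any
   peak overlapping a promoter window, retained iff overlapped by a GWAS
   index SNP or an LD proxy (r² >= 0.8); HLA-region SNPs excluded first.
2. **Active genes** — genes whose promoter window (−1500/+500 around the
   TSS) overlaps a filtered H3K4me3 or H3K27ac peak.
3. **Enhancer-eQTL links** — a fresh eQTL scan (with its own permutation
   FDR) restricted to SNPs inside GWAS enhancers x active genes; each
   significant cis association emits a connection.
4. **Gene-overlap hits** — active genes whose locus window (−1500 bp of
   TSS to +500 bp of the termination site) contains a GWAS SNP or proxy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eqtl import EqtlScan, EqtlScanConfig
from .intervals import (IntervalSet, filter_peaks, gene_locus_windows,
                        promoter_windows, snps_in_intervals,
                        subtract_overlapping)
from .ld import LdExpansion
from .types import GenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_HLA_REGION = ("chr6", 25_000_000, 35_000_000)

CONNECTION_COLUMNS = ["cell_type", "index_snp", "proxy_snp", "r2", "mark",
                      "enh_chrom", "enh_start", "enh_end", "gene",
                      "beta", "p", "fdr", "evidence"]


@dataclass
class CellTypeEpigenome:
    """Filtered peak sets for one cell type (marks -> IntervalSet,
    already fold-filtered), with derived enhancer and active-gene sets."""

    cell_type: str
    peaks: dict[str, IntervalSet]
    enhancers: dict[str, IntervalSet] = field(default_factory=dict)
    active_genes: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class DeconvolutionConfig:
    enhancer_marks: tuple[str, ...] = ("H3K27ac", "H3K4me1")
    promoter_marks: tuple[str, ...] = ("H3K4me3", "H3K27ac")
    min_fold: float = 4.0
    promoter_upstream: int = 1500
    promoter_downstream: int = 500
    r2_min: float = 0.8
    exclusion_region: tuple[str, int, int] = DEFAULT_HLA_REGION
    scan: EqtlScanConfig = field(default_factory=lambda: EqtlScanConfig(
        n_permutations=10))


def _excluded(snps: pd.DataFrame, region: tuple[str, int, int]) -> np.ndarray:
    chrom, start, end = region
    return ((snps["chrom"].astype(str) == chrom)
            & (snps["pos"] >= start) & (snps["pos"] < end)).to_numpy()


def gwas_proxy_table(gwas_snps: list[str], ld: LdExpansion,
                     exclusion_region: tuple[str, int, int] | None
                     ) -> pd.DataFrame:
    """(index_snp, proxy, r2, chrom, pos) rows for all GWAS SNPs and their
    proxies, with excluded-region SNPs dropped (index SNPs in the region
    contribute nothing; proxies in the region are dropped individually)."""
    frames = []
    for idx in gwas_snps:
        df = ld.proxies.get(idx)
        if df is None:
            continue
        d = df.dropna(subset=["pos"]).copy()
        if d.empty:
            continue
        d.insert(0, "index_snp", idx)
        frames.append(d)
    if not frames:
        return pd.DataFrame(columns=["index_snp", "proxy", "r2", "chrom", "pos"])
    out = pd.concat(frames, ignore_index=True)
    out["pos"] = out["pos"].astype(np.int64)
    if exclusion_region is not None:
        chrom, start, end = exclusion_region
        idx_pos = out[out["proxy"] == out["index_snp"]].set_index("index_snp")
        bad_index = set(idx_pos.index[
            (idx_pos["chrom"].astype(str) == chrom)
            & (idx_pos["pos"] >= start) & (idx_pos["pos"] < end)])
        out = out[~out["index_snp"].isin(bad_index)]
        keep = ~((out["chrom"].astype(str) == chrom)
                 & (out["pos"] >= start) & (out["pos"] < end))
        out = out[keep]
    return out.reset_index(drop=True)


def build_gwas_enhancers(epigenome: CellTypeEpigenome, proxy_table: pd.DataFrame,
                         promoters: IntervalSet,
                         config: DeconvolutionConfig = DeconvolutionConfig()
                         ) -> dict[str, pd.DataFrame]:
    """Per enhancer mark: the peaks (post fold-filter, promoter-subtracted)
    overlapped by a GWAS index SNP or proxy, with the overlapping SNPs
    attached.

    Returns mark -> DataFrame of hits (columns of
    :func:`snps_in_intervals` plus index_snp, r2); also stores the
    enhancer IntervalSets on the epigenome.
    """
    out: dict[str, pd.DataFrame] = {}
    snp_df = proxy_table.rename(columns={"proxy": "snp"}).set_index("snp")
    snp_positions = snp_df[~snp_df.index.duplicated()][["chrom", "pos"]]
    for mark in config.enhancer_marks:
        peaks = epigenome.peaks.get(mark)
        if peaks is None:
            continue
        enhancers = subtract_overlapping(peaks, promoters)
        epigenome.enhancers[mark] = enhancers
        hits = snps_in_intervals(snp_positions, enhancers)
        if len(hits):
            hits = hits.merge(
                proxy_table.rename(columns={"proxy": "snp"})[
                    ["snp", "index_snp", "r2"]], on="snp", how="left")
        else:
            hits["index_snp"] = pd.Series(dtype=object)
            hits["r2"] = pd.Series(dtype=float)
        out[mark] = hits
    return out


def build_active_genes(epigenome: CellTypeEpigenome, annotation: pd.DataFrame,
                       config: DeconvolutionConfig = DeconvolutionConfig()
                       ) -> set[str]:
    """Genes whose promoter window overlaps >= 1 filtered promoter-mark
    peak (H3K4me3 or H3K27ac)."""
    promoters = promoter_windows(annotation, config.promoter_upstream,
                                 config.promoter_downstream)
    active: set[str] = set()
    for mark in config.promoter_marks:
        peaks = epigenome.peaks.get(mark)
        if peaks is None or len(peaks) == 0:
            continue
        from .intervals import _overlaps_any
        hit = _overlaps_any(promoters.df, peaks)
        active.update(promoters.df.loc[hit, "name"])
    epigenome.active_genes = active
    return active


def link_enhancers_to_genes(epigenome: CellTypeEpigenome,
                            enhancer_hits: dict[str, pd.DataFrame],
                            geno: GenotypeMatrix, adjusted_expr: pd.DataFrame,
                            annotation: pd.DataFrame,
                            covariates: pd.DataFrame | None,
                            config: DeconvolutionConfig = DeconvolutionConfig()
                            ) -> pd.DataFrame:
    """Step 3: restricted eQTL re-mapping.

    Scan only SNPs inside GWAS enhancers x active genes, with a fresh
    permutation FDR at the configured level; each significant cis record
    emits one connection per (enhancer, gene, cell type, mark).
    """
    rows = []
    active = sorted(epigenome.active_genes & set(adjusted_expr.columns))
    for mark, hits in enhancer_hits.items():
        if len(hits) == 0 or not active:
            continue
        snp_ids = sorted(set(hits["snp"]))
        sub_geno = geno.subset_snps(snp_ids)
        if sub_geno.n_snps == 0:
            warnings.warn(f"no genotyped SNPs inside {mark} GWAS enhancers",
                          stacklevel=2)
            continue
        scan = EqtlScan(sub_geno, adjusted_expr.loc[:, active],
                        annotation.loc[annotation.index.intersection(active)],
                        covariates=covariates, config=config.scan)
        res = scan.fit()
        sig = res.significant("cis")
        for rec in sig.itertuples(index=False):
            for h in hits[hits["snp"] == rec.snp].itertuples(index=False):
                rows.append({
                    "cell_type": epigenome.cell_type,
                    "index_snp": h.index_snp, "proxy_snp": rec.snp,
                    "r2": h.r2, "mark": mark, "enh_chrom": h.chrom,
                    "enh_start": h.start, "enh_end": h.end, "gene": rec.gene,
                    "beta": rec.beta, "p": rec.p, "fdr": rec.fdr,
                    "evidence": "enhancer-eQTL"})
    return pd.DataFrame(rows, columns=CONNECTION_COLUMNS)


def add_gene_overlap_hits(epigenome: CellTypeEpigenome,
                          proxy_table: pd.DataFrame, annotation: pd.DataFrame,
                          config: DeconvolutionConfig = DeconvolutionConfig()
                          ) -> pd.DataFrame:
    """Step 4: active genes whose locus window contains a GWAS index SNP or
    proxy; one record per (cell type, SNP, gene)."""
    active = sorted(epigenome.active_genes & set(annotation.index))
    if not active or len(proxy_table) == 0:
        return pd.DataFrame(columns=CONNECTION_COLUMNS)
    loci = gene_locus_windows(annotation.loc[active],
                              config.promoter_upstream,
                              config.promoter_downstream)
    snp_df = proxy_table.rename(columns={"proxy": "snp"}).set_index("snp")
    snp_positions = snp_df[~snp_df.index.duplicated()][["chrom", "pos"]]
    hits = snps_in_intervals(snp_positions, loci)
    rows = []
    for h in hits.itertuples(index=False):
        for link in proxy_table[proxy_table["proxy"] == h.snp].itertuples(index=False):
            rows.append({
                "cell_type": epigenome.cell_type, "index_snp": link.index_snp,
                "proxy_snp": h.snp, "r2": link.r2, "mark": None,
                "enh_chrom": None, "enh_start": None, "enh_end": None,
                "gene": h.name, "beta": np.nan, "p": np.nan, "fdr": np.nan,
                "evidence": "gene-overlap"})
    return pd.DataFrame(rows, columns=CONNECTION_COLUMNS)


def connection_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Gene x cell-type binary incidence matrix, rows/columns sorted."""
    if len(records) == 0:
        return pd.DataFrame()
    inc = (records.assign(v=1)
           .pivot_table(index="gene", columns="cell_type", values="v",
                        aggfunc="max", fill_value=0))
    return inc.sort_index(axis=0).sort_index(axis=1).astype(int)


def deconvolve(epigenomes: dict[str, dict[str, IntervalSet]],
               gwas_snps: list[str], ld: LdExpansion,
               geno: GenotypeMatrix, adjusted_expr: pd.DataFrame,
               annotation: pd.DataFrame, covariates: pd.DataFrame | None = None,
               config: DeconvolutionConfig = DeconvolutionConfig()
               ) -> tuple[pd.DataFrame, dict[str, CellTypeEpigenome]]:
    """Run all four steps for every cell type.

    ``epigenomes`` maps cell type -> mark -> raw peak IntervalSet (with
    fold-enrichment scores; filtering at > 4 happens here).

    Returns (connection records, per-cell-type epigenome objects).
    """
    promoters = promoter_windows(annotation, config.promoter_upstream,
                                 config.promoter_downstream)
    proxy_table = gwas_proxy_table(gwas_snps, ld, config.exclusion_region)
    all_records = []
    objects: dict[str, CellTypeEpigenome] = {}
    for cell_type in sorted(epigenomes):
        filtered = {mark: filter_peaks(peaks, config.min_fold)
                    for mark, peaks in epigenomes[cell_type].items()}
        epi = CellTypeEpigenome(cell_type=cell_type, peaks=filtered)
        build_active_genes(epi, annotation, config)
        hits = build_gwas_enhancers(epi, proxy_table, promoters, config)
        n_enh = {m: h["interval_index"].nunique() for m, h in hits.items()}
        logger.info("%s: %d active genes, GWAS enhancers per mark: %s",
                    cell_type, len(epi.active_genes), n_enh)
        rec_e = link_enhancers_to_genes(epi, hits, geno, adjusted_expr,
                                        annotation, covariates, config)
        rec_g = add_gene_overlap_hits(epi, proxy_table, annotation, config)
        all_records += [r for r in (rec_e, rec_g) if len(r)]
        objects[cell_type] = epi
    records = (pd.concat(all_records, ignore_index=True)
               if all_records else pd.DataFrame(columns=CONNECTION_COLUMNS))
    records = records.sort_values(
        ["cell_type", "evidence", "index_snp", "proxy_snp", "gene"],
        kind="mergesort").reset_index(drop=True)
    return records, objects


# -- baseline gene sets --------------------------------------------------

def baseline_gene_sets(gwas_snps: pd.DataFrame, annotation: pd.DataFrame,
                       per_snp_counts: dict[str, int], distance: int = 5000
                       ) -> tuple[set[str], set[str]]:
    """The two baseline SNP-to-gene assignments the deconvolution is
    compared against.

    "closest": for each SNP the k nearest genes by distance to the gene
    locus (0 if inside), k from ``per_snp_counts`` (ties at rank k all
    included, logged).  "within": every gene whose locus is <= ``distance``
    bp from the SNP.

    ``gwas_snps``: DataFrame indexed by snp id with chrom, pos (1-based).
    """
    loci = gene_locus_windows(annotation)
    closest: set[str] = set()
    within: set[str] = set()
    by_chrom = {c: g for c, g in loci.df.groupby("chrom")}
    for snp_id, row in gwas_snps.iterrows():
        sub = by_chrom.get(str(row["chrom"]))
        if sub is None:
            continue
        base = int(row["pos"]) - 1
        d = np.maximum.reduce([sub["start"].to_numpy(np.int64) - base,
                               base - (sub["end"].to_numpy(np.int64) - 1),
                               np.zeros(len(sub), dtype=np.int64)])
        genes = sub["name"].to_numpy()
        within.update(genes[d <= distance])
        k = per_snp_counts.get(snp_id, 0)
        if k <= 0 or len(d) == 0:
            continue
        order = np.argsort(d, kind="mergesort")
        kth = d[order[min(k, len(d)) - 1]]
        chosen = genes[d <= kth]
        if len(chosen) > k:
            logger.info("closest-gene tie at SNP %s: %d genes at rank %d",
                        snp_id, len(chosen), k)
        closest.update(chosen)
    return closest, within


def gene_set_overlap_test(genes: set[str], de_genes: set[str],
                          universe: set[str]):
    """One-sided Fisher test for over-representation of ``de_genes``
    within ``genes`` against ``universe``."""
    if not universe:
        raise ValueError("empty universe")
    if not genes <= universe or not de_genes <= universe:
        raise ValueError("gene sets must be subsets of the universe")
    from scipy import stats
    big_n = len(universe)
    k = len(genes & de_genes)
    p = float(stats.hypergeom.sf(k - 1, big_n, len(de_genes), len(genes)))
    from .enrichment import EnrichmentResult
    return EnrichmentResult(unit="gene_set", statistic=float(k), p=p,
                            p_adjusted=min(1.0, p))
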