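# eqtldecon

Deconvolution of GWAS risk loci into cell-type-specific gene associations.

Most disease-associated variants from genome-wide association studies sit
outside protein-coding regions, likely in distal transcriptional enhancers,
and a GWAS by itself names neither the target gene nor the cell type in
which the variant acts. `eqtldecon` integrates four data layers to propose
both: matched genotype/expression data (for expression quantitative trait
loci, eQTLs), linkage disequilibrium structure, per-cell-type histone-mark
ChIP-seq peaks (enhancer and promoter activity), and a GWAS catalog. It is
aimed at statistical geneticists and immunogenomics groups who want a
transparent, fully testable implementation of this integration, together
with a synthetic-cohort generator that plants ground truth so every stage
can be verified by recovery.

## The method

**eQTL scan.** For gene *g* and SNP *s* with additive dosage
*x<sub>s</sub>* ∈ {0,1,2}:

```
y_g = μ + β x_s + γᵀc + ε
```

with covariates *c* (subject age and the first three genotype principal
components for population stratification). Expression is first adjusted by
removing leading expression PCs (default ten) and applying a per-gene
rank-based inverse normal transform Φ⁻¹((r − ½)/n). Pairs are *cis* when
the SNP lies within 1 Mb of the gene (strict), *trans* otherwise. The
false discovery rate is estimated by permutation (Freedman–Lane residual
permutation of the expression matrix, preserving gene–gene correlation),
separately for cis and trans: FDR(t) = E#{null p ≤ t} / #{observed p ≤ t}.

**QC.** SNPs must be biallelic, autosomal, with minor allele frequency
> 0.05 and Hardy–Weinberg χ² p > 10⁻⁶ (all strict).

**Deconvolution.** Per cell-type epigenome, four steps:

1. *GWAS enhancers* — H3K27ac (active) and H3K4me1 (primed) peaks with
   fold-enrichment > 4, minus any peak overlapping a promoter window
   (TSS −1500/+500 bp, strand-aware), retained iff covered by a GWAS index
   SNP or an LD proxy (r² ≥ 0.8); HLA-region SNPs (chr6:25–35 Mb) excluded.
2. *Active genes* — genes whose promoter window overlaps a filtered
   H3K4me3 or H3K27ac peak.
3. *Enhancer→gene links* — a fresh eQTL scan (own permutation FDR at 5 %)
   restricted to SNPs inside GWAS enhancers × active genes; significant cis
   associations become (cell type, enhancer, gene) connections.
4. *Gene-overlap hits* — active genes whose locus window (TSS −1500 bp to
   transcript end +500 bp) contains a GWAS SNP or proxy.

**Enrichment and network statistics.** One-sided Fisher (exact
hypergeometric) tests of a SNP set against catalog traits (≥ 10 SNPs,
Bonferroni); chromatin-state fold-enrichment (fraction of variants in
state ÷ genomic fraction of state) over nine collapsed ChromHMM states;
a local-shift permutation test (circular shifts of the annotation within
±500 kb of each lead variant, 10⁴ permutations); and interactome
connectivity of a candidate gene set — largest-connected-component
z-score against random same-size node sets (10⁵ permutations) and mean
shortest distance to the nearest other member.

## Worked example

Generate a synthetic cohort with five planted risk chains
(GWAS SNP → LD proxy → enhancer peak → active target gene) and run the
whole pipeline:

```
$ eqtldecon simulate --seed 1 --out demo
wrote synthetic study to demo (pipeline config: demo/pipeline.yaml)
$ eqtldecon run-all demo/pipeline.yaml
pipeline complete; outputs in demo/pipeline_out
30 connection records
```

The genome-wide scan summary (`demo/pipeline_out/eqtl_summary.txt`):

```
eQTL scan summary
========================================
cis: 746 pairs tested, 17 significant at FDR 0.05
     unique eSNPs: 17, unique egenes: 5
permutations: 10, seed: 0
```

The five egenes are exactly the five planted target genes; the 17 eSNPs
are the planted causal proxies plus their LD-block partners. The
connections table (`connections.tsv`) contains the 30 planted
(cell type × mark × enhancer → gene) records — 5 chains × 3 cell types ×
2 enhancer marks — for example:

```
cell_type  index_snp  proxy_snp  r2     mark     gene  p          evidence
bcell      rs001      rs002      0.845  H3K27ac  g001  3.6e-96    enhancer-eQTL
```

`network_stats.json` shows the planted disease module standing out on the
interactome: the five linked genes form a single connected component
(`lcc: 5`) with permutation z-score 9.56 and mean shortest distance 1.0,
against a null LCC of 1.18 ± 0.40.

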