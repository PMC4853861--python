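# Methods

This note documents the statistical procedures, the synthetic-data
generator, numerical choices, and the design decisions taken where the
problem was genuinely open. Parameters are given with defaults and units.

## 1. Association model and scan

The scan fits, per (SNP, gene) pair, ordinary least squares of expression
on additive dosage (0/1/2) plus covariates and an intercept. The dosage
coefficient's t statistic uses n − q − 2 degrees of freedom (q covariates).
Implementation: both dosage and expression matrices are residualized on
the covariate design once (Frisch–Waugh–Lovell), after which per-pair
statistics reduce to vectorized inner products; this is algebraically
identical to the per-pair OLS fit and is verified against a
normal-equations solver and against statsmodels to 1e-10 in the tests.

* `cis_window` = 1,000,000 bp, strict `<`; same chromosome; distance 0
  inside the gene. A pair at exactly 1 Mb is trans.
* Covariates: subject age and the first 3 genotype PCs (dosages
  mean-centred, unit-variance scaled per SNP; SVD scores with the sign
  fixed so each component's largest-magnitude score is positive).
* p-values are clamped at the smallest positive double (≈4.9e-324) so
  perfect fits never produce p = 0 inside FDR ratios.
* Constant-dosage SNPs are skipped and logged rather than fitted.

## 2. Permutation FDR

Permutation scheme (the choice was open — the literature procedure being
re-implemented is not spelled out in detail): Freedman–Lane. Expression is
residualized on the covariates, the residual **rows** are permuted jointly
(one permutation per round, preserving the gene–gene correlation
structure), fitted values are re-added, and the scan is repeated. Pooled
tail counts over permutations give

FDR(t) = (mean over permutations of #{null p ≤ t}) / #{observed p ≤ t},

evaluated at each observed p, regularized to be monotone non-decreasing in
t (running minimum from the largest threshold down, q-value style), with
ties sharing the count at the last tied position. The significance set is
the p-threshold set {p ≤ t*} with t* the largest threshold at FDR ≤ level.
Cis and trans are corrected independently. Per-gene min-p beta
approximation was considered and rejected in favour of the simpler pooled
estimator; the number of permutations is configurable (desk-scale default
10; the studies this emulates do not report a count).

A consequence of pooled FDR worth knowing when reading recovery numbers:
once several extremely strong signals are called, the threshold t* admits
null pairs with p up to roughly (level × #calls) / #tests — FDR controls
the expected false fraction, not the count. Synthetic recovery runs
therefore occasionally contain a handful of borderline null calls; this is
the procedure behaving as designed, not a defect.

## 3. Expression adjustment

PC removal is PCA over samples (genes as features) of the gene-centred
matrix; the residual subtracts the rank-k reconstruction, so it is exactly
orthogonal to the removed score vectors. The inverse normal transform is
rank-based, Φ⁻¹((r − 0.5)/n) with ties at mean rank; the (r − 3/8)/(n + ¼)
variant was considered and not used (the choice is exposed in config and
immaterial to rank-based inference). Order of operations: PC removal
first, then the per-gene transform.

Default `n_pcs_remove` = 10, the standard choice for microarray blood
expression where batch, RNA quality and cell-composition effects dominate.
**On synthetic cohorts the pipeline configs emitted by `simulate` set the
removal count equal to the number of planted confounder factors (0 by
default)**: with a small gene panel and strong planted effects, the top
expression PCs *are* the genetic signal, and removing ten of them removes
the effects themselves — the small-panel version of the known trade-off
between removing unwanted variation and removing genetically determined
variation.

## 4. Genotype QC

MAF = min(p, 1−p), p = Σdosage/2n. Hardy–Weinberg uses the 1-df χ²
goodness-of-fit test against expected genotype frequencies at the
estimated allele frequency (the exact test is unnecessary at n ≈ 377;
monomorphic SNPs return p = 1 by convention). Filters are strict
(MAF > 0.05, HWE p > 1e-6) and attributed to the first criterion failed in
the order biallelic → autosomal → MAF → HWE. Missing dosages are not
allowed in core operations; readers impute the rounded per-SNP mean and
warn.

## 5. LD

r² is the squared Pearson correlation of unphased dosage vectors
(composite LD), which converges to the haplotype r² under HWE; an EM
haplotype estimator was considered and left as an extension since the
pipeline's inputs are unphased dosages. Proxy expansion returns all SNPs
with r² ≥ 0.8 (inclusive, with a 1e-12 roundoff guard so duplicated
columns pass a threshold of exactly 1.0) within 1 Mb on the same
chromosome; every index SNP maps to itself, and index SNPs missing from
the panel are kept as self-only entries with a warning.

## 6. Interval arithmetic

All in-memory intervals are 0-based half-open; SNP positions are 1-based
and converted at the boundary (a SNP at 1-based p occupies base p−1, so
p = end is the last covered position and p = end+1 the first excluded).
Promoter windows are strand-aware: [tss−1500, tss+500) on +, mirrored on −
(strandedness was an open choice; upstream/downstream semantics require
it). Gene locus windows run from 1500 bp 5′ of the TSS to 500 bp 3′ of the
transcript end. Peak filtering is strict (> 4 fold-enrichment); promoter
subtraction removes the whole peak on ≥ 1 bp overlap (never truncates).
Joins use merged-interval binary search; results are algorithm-independent
and tested against quadratic brute force.

## 7. Enrichment statistics

* Catalog Fisher tests: background = deduplicated union of all catalog
  SNPs (whether multi-trait SNPs deduplicate was open; they do here);
  traits need ≥ 10 SNPs; one-sided hypergeometric tail; Bonferroni over
  tested traits. An LD-aware mode counts a catalog SNP as a hit when any
  proxy is in the query.
* Chromatin states: the 18-state (6-mark) vocabulary collapses to nine
  (TSS, Tx, Enh, EnhA, Het, EnhBiv, TssBiv, ReprPC, Quies) via a config
  table whose default merges flanking/weak variants into their parent
  state; adjacent same-label intervals merge. Fold-enrichment =
  (fraction of positions in state) / (state bp / genome bp).
* Local-shift test: per locus, the annotation restricted to ±window
  (default 5×10⁵ bp) around the lead variant is circularly shifted by a
  uniform offset, independently per locus and permutation (default 10⁴);
  the score counts loci where the lead or any LD proxy overlaps the
  annotation; p carries an add-one correction so p ∈ (0, 1]. An
  exhaustive mode enumerates every integer shift for single-locus toys
  and is checked against independent enumeration.

## 8. Deconvolution

Defaults: enhancer marks H3K27ac and H3K4me1 analysed separately and
labelled (active vs primed enhancers); promoter marks H3K4me3 and H3K27ac;
HLA exclusion chr6:25,000,000–35,000,000 (configurable — the exclusion is
standard, its coordinates a choice). The restricted re-mapping recomputes
its own permutation FDR within the restricted test set rather than reusing
genome-wide thresholds, and tests cis-window pairs by default (full
enhancer-SNP × active-gene mode available). Baseline gene sets: "closest
genes" takes the k nearest genes per SNP by distance to the gene locus
window (k = genes assigned by the main method; ties at rank k all
included and logged); "within 5000 bp" takes every gene whose locus is
≤ 5 kb from the SNP.

## 9. Network statistics

LCC and nearest-member BFS run on an adjacency-set representation.
The null for the LCC z-score samples node sets uniformly (default) or
within log2-degree bins (option, since hubs inflate the uniform null);
the choice is recorded in the output. Genes absent from the interactome
are dropped and counted. Empirical p uses add-one correction; if the null
SD is zero, z is reported as undefined alongside p.

## 10. Synthetic-data generator

The generator emulates a blood eQTL cohort with planted, recoverable
truth. Defaults: 377 samples; three chromosomes (20, 20, 40 Mb — the
third long enough to host an HLA-like exclusion region); 300 SNPs in a
repeating LD-block pattern (4 SNPs at r² 0.9, 3 at 0.5, 3 independent);
MAF ~ U(0.05, 0.5); 100 genes (2–20 kb, random strand); expression noise
SD 1.0; planted effect size 1.5 on the dosage scale (a strong cis-eQTL,
chosen so single-study recovery is decisive — the emulated study reports
no effect-size distribution, so this is a free parameter, not an
estimate).

LD blocks use a haplotype-copy scheme: each haplotype carries a latent
block "core" allele at the block frequency; each SNP copies the core with
probability θ = (target r²)^¼ and otherwise draws fresh. Allele–allele
correlation is then θ², so dosage r² concentrates on the target exactly
(θ = 1 duplicates columns; θ = 0 gives independence). Blocks never span
chromosomes; positions are strictly increasing with ≥ 100 bp spacing
enforced.

Confounding enters expression as k low-rank Gaussian factors with
N(0, scale²) loadings — exactly the structure PC removal is meant to
absorb, making the adjustment step testable. Peaks carry fold-enrichment
scores straddling 4 (U(0.5, 7.5), half removed by the filter); each cell
type draws a 20 % inactive gene fraction that receives no promoter peak
(planted eQTL target genes are always active); the segmentation tiles
each chromosome with the nine collapsed states without gaps. A planted
study (`make_planted_study`) wires complete chains — GWAS index SNP and
enhancer proxy from the same high-LD block, enhancer peak over the proxy,
cis target gene whose promoter the proxy avoids — plus decoys: HLA-region
index SNPs and inactive genes. Two generator rules keep planted truth
attributable: background peaks never cover SNP positions in a
GWAS-tagged LD block, and activity-mark background peaks avoid the
promoters of genes drawn inactive. All randomness flows from one integer
seed through fixed-index child generators, so identical configs reproduce
byte-identical artifacts.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: realistic allele-frequency spectra and
recombination (LD is block-wise, not coalescent), gene-density and
peak-width distributions of a real genome, expression count noise and
probe effects, and the magnitude/structure of real batch effects. Recovery
results demonstrate correctness of the machinery under the stated
generative model, not field performance.

## 11. Problem sizes

Test and acceptance runs use desk-scale cohorts chosen as the smallest
sizes at which the statistical claims are decisive: null calibration at
200 samples × 500 SNPs × 200 genes over 50 seeds; recovery at 300 samples
with 10 planted effects of β = 1 (≥ 1 expression SD) over 50 seeds;
network permutation checks at 10⁴ permutations (the headline z-score
default is 10⁵); the local-shift null calibration at 200 replicates ×
400 permutations. The acceptance script runs ~10 replicate cohorts per
quantity from a single command-line seed, deriving child seeds
deterministically.

## 12. Known limitations

* Pooled permutation FDR (not per-gene beta-approximated min-p); with few
  tests and a handful of extreme signals its threshold is coarse.
* Composite in-sample LD differs from phased-reference-panel LD; proxy
  sets computed here are not interchangeable with external panel lookups.
* The trans scan defaults to a candidate SNP list (full trans is a flag);
  no conditional/secondary-signal analysis; no colocalization testing of
  eQTL and GWAS signals (the framework links them by co-overlap only).
* Whether the emulated study tested HWE on all subjects or a founder
  subset is unknown; all subjects are used here.
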