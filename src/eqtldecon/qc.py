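"""Genotype QC: MAF and Hardy-Weinberg filters, and genotype principal
components used as population-stratification covariates in the eQTL scan.

SNPs enter the association scan only if bi-allelic, autosomal, with minor
allele frequency > 0.05 and Hardy-Weinberg chi-square p > 1e-6 (all strict).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import GenotypeMatrix

AUTOSOMES = {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}


@dataclass(frozen=True)
class QcThresholds:
    """SNP-level QC thresholds (all comparisons strict)."""

    maf_min: float = 0.05
    hwe_p_min: float = 1e-6
    require_biallelic: bool = True
    autosomes_only: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0, 0.5)")
        if not 0 <= self.hwe_p_min <= 1:
            raise ValueError("hwe_p_min must be in [0, 1]")


@dataclass
class StratificationCovariates:
    """Genotype PC scores used as covariates (samples x k).

    Columns are ordered by decreasing explained variance and mean-centred;
    sign is fixed so the largest-magnitude loading of each PC is positive.
    """

    scores: pd.DataFrame
    explained_variance: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def k(self) -> int:
        return self.scores.shape[1]


def compute_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency from dosages in {0, 1, 2}.

    Returns ``min(p, 1 - p)`` where ``p = sum(dosage) / (2 n)``.
    """
    d = np.asarray(dosages, dtype=float)
    if d.size == 0:
        raise ValueError("compute_maf: empty dosage vector")
    if np.isnan(d).any():
        raise ValueError("compute_maf: missing dosages not allowed "
                         "(impute at read time)")
    p = d.sum() / (2 * d.size)
    return float(min(p, 1 - p))


def hwe_chi2_p(counts: tuple[int, int, int]) -> float:
    """Hardy-Weinberg goodness-of-fit p-value (1-df chi-square).

    ``counts`` are genotype counts (n_AA, n_Aa, n_aa).  The expected counts
    come from the allele frequency estimated on the same sample; monomorphic
    SNPs return p = 1 by convention (no departure is testable).
    """
    n_aa, n_ab, n_bb = (int(c) for c in counts)
    n = n_aa + n_ab + n_bb
    if n <= 0:
        raise ValueError("hwe_chi2_p: empty genotype counts")
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    expected = np.array([p * p, 2 * p * (1 - p), (1 - p) ** 2]) * n
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    d = np.asarray(dosages)
    return (int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))


def filter_snps(geno: GenotypeMatrix,
                thresholds: QcThresholds = QcThresholds()
                ) -> tuple[GenotypeMatrix, pd.Series]:
    """Apply the SNP QC chain; returns the filtered matrix and per-criterion
    removal counts (a SNP is attributed to the first criterion it fails, in
    order biallelic -> autosomal -> MAF -> HWE).
    """
    snps = geno.snps
    dosages = geno.dosages
    n_snps = len(snps)
    removed = {"biallelic": 0, "autosomal": 0, "maf": 0, "hwe": 0}
    keep = np.ones(n_snps, dtype=bool)
    if n_snps == 0:
        return geno, pd.Series(removed, name="removed")

    if thresholds.require_biallelic and "n_alleles" in snps.columns:
        bad = (snps["n_alleles"].to_numpy() != 2) & keep
        removed["biallelic"] = int(bad.sum())
        keep &= ~bad
    if thresholds.autosomes_only:
        bad = ~snps["chrom"].astype(str).isin(AUTOSOMES).to_numpy() & keep
        removed["autosomal"] = int(bad.sum())
        keep &= ~bad

    mat = dosages.to_numpy(dtype=float)
    p = mat.sum(axis=0) / (2 * mat.shape[0]) if mat.shape[0] else np.zeros(n_snps)
    maf = np.minimum(p, 1 - p)
    bad = (maf <= thresholds.maf_min) & keep
    removed["maf"] = int(bad.sum())
    keep &= ~bad

    hwe_p = np.array([
        hwe_chi2_p(genotype_counts(mat[:, j])) if keep[j] else 1.0
        for j in range(n_snps)
    ])
    bad = (hwe_p <= thresholds.hwe_p_min) & keep
    removed["hwe"] = int(bad.sum())
    keep &= ~bad

    kept_ids = snps.index[keep]
    out = GenotypeMatrix(dosages=dosages.loc[:, kept_ids].copy(),
                         snps=snps.loc[kept_ids].copy())
    return out, pd.Series(removed, name="removed")


def genotype_pca(geno: GenotypeMatrix, k: int = 3) -> StratificationCovariates:
    """First ``k`` principal components of the column-standardised dosage
    matrix, as stratification covariates.

    Each SNP column is mean-centred and scaled to unit variance
    (monomorphic columns are dropped).  Scores are computed by SVD; the sign
    of each component is fixed so its largest-magnitude sample score is
    positive, making runs deterministic.
    """
    n = geno.n_samples
    if k >= n:
        raise ValueError(f"k={k} must be < n_samples={n}")
    if k == 0:
        empty = pd.DataFrame(index=geno.dosages.index)
        return StratificationCovariates(scores=empty)
    mat = geno.dosages.to_numpy(dtype=float)
    mat = mat - mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=0)
    keep = sd > 0
    mat = mat[:, keep] / sd[keep]
    u, s, _ = np.linalg.svd(mat, full_matrices=False)
    k_eff = min(k, len(s))
    scores = u[:, :k_eff] * s[:k_eff]
    for j in range(k_eff):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    cols = [f"PC{j + 1}" for j in range(k_eff)]
    explained = (s[:k_eff] ** 2) / max(n - 1, 1)
    return StratificationCovariates(
        scores=pd.DataFrame(scores, index=geno.dosages.index, columns=cols),
        explained_variance=explained,
    )
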