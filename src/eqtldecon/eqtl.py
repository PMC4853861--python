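"""Cis/trans eQTL scan: additive linear model per (SNP, gene) pair with
covariates, and a permutation-based false discovery rate.

The model for gene g and SNP s is

    expression_g = mu + beta * dosage_s + gamma' covariates + eps

with dosage coded 0/1/2 (alternate-allele count).  ``beta``, its t statistic
and the two-sided p-value come from ordinary least squares; the scan runs
all cis pairs (SNP within ``cis_window`` of the gene, strict, same
chromosome) and, optionally, trans pairs.  FDR is estimated by re-running
the scan on permuted expression (Freedman-Lane: residualize expression on
the covariates, permute the residual rows jointly across genes, re-add
fitted values) and comparing null and observed p-value tail counts,
separately for cis and trans.

Organised statsmodels-style: :class:`EqtlScan` is the model object built
from data; :meth:`EqtlScan.fit` returns :class:`EqtlScanResults` carrying
the association records, thresholds and a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import GenotypeMatrix, validate_annotation

logger = logging.getLogger(__name__)

#: smallest positive double; p-values are clamped here to avoid zeros in
#: FDR ratios when t statistics underflow the t distribution tail.
P_MIN = float(np.nextafter(0.0, 1.0))


@dataclass(frozen=True)
class EqtlScanConfig:
    """Scan settings.

    ``cis_window`` is the strict upper bound (bp) on SNP-to-gene distance
    for a cis pair.  ``trans_snps`` restricts trans testing to a candidate
    SNP list (e.g. GWAS SNPs); ``full_trans`` tests every cross pair
    instead.  With neither, only cis pairs are tested.
    """

    cis_window: int = 1_000_000
    fdr_level: float = 0.05
    n_permutations: int = 10
    seed: int = 0
    trans_snps: tuple[str, ...] | None = None
    full_trans: bool = False

    def __post_init__(self) -> None:
        if self.cis_window <= 0:
            raise ValueError("cis_window must be > 0")
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def classify_pair(snp_pos: tuple[str, int], gene: pd.Series,
                  window: int = 1_000_000) -> str:
    """Classify a (SNP, gene) pair as ``cis`` or ``trans``.

    Cis iff same chromosome and the distance from the SNP to the gene
    interval is strictly less than ``window``; distance is 0 when the SNP
    lies inside the interval.
    """
    chrom, pos = snp_pos
    if chrom is None or gene["chrom"] is None:
        raise ValueError("unknown chromosome")
    if str(chrom) != str(gene["chrom"]):
        return "trans"
    start, end = int(gene["start"]), int(gene["end"])
    if pos < start:
        dist = start - pos
    elif pos > end:
        dist = pos - end
    else:
        dist = 0
    return "cis" if dist < window else "trans"


def fit_association(dosage: np.ndarray, expr: np.ndarray,
                    covariates: np.ndarray | None = None
                    ) -> tuple[float, float, float]:
    """OLS of expression on dosage plus covariates; returns
    (beta, t, p) for the dosage term.

    Two-sided p from the t distribution with n - q - 2 degrees of freedom
    (q covariates, intercept and dosage estimated); p-values that underflow
    are clamped at the smallest positive double.
    """
    x = np.asarray(dosage, dtype=float)
    y = np.asarray(expr, dtype=float)
    n = x.size
    q = 0 if covariates is None else np.atleast_2d(covariates).reshape(n, -1).shape[1]
    if n < q + 3:
        raise ValueError(f"need n >= q + 3 (n={n}, q={q})")
    if np.std(x) == 0:
        raise ValueError("constant dosage: association undefined")
    if covariates is None:
        design = np.column_stack([np.ones(n), x])
    else:
        design = np.column_stack([np.ones(n),
                                  np.asarray(covariates, float).reshape(n, -1), x])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    df = n - q - 2
    rss = float(resid @ resid)
    xtx_inv = np.linalg.pinv(design.T @ design)
    se = np.sqrt(max(rss, 0.0) / df * xtx_inv[-1, -1])
    beta = float(coef[-1])
    if se == 0:
        t = np.inf if beta != 0 else 0.0
    else:
        t = beta / se
    p = 2 * stats.t.sf(abs(t), df)
    return beta, float(t), float(max(p, P_MIN))


def _residualize(mat: np.ndarray, design: np.ndarray) -> np.ndarray:
    coef, _, _, _ = np.linalg.lstsq(design, mat, rcond=None)
    return mat - design @ coef


class EqtlScan:
    """eQTL scan model: genotype dosages, expression and gene annotation
    with optional covariates.

    Parameters
    ----------
    geno : GenotypeMatrix
    expr : DataFrame, samples x genes (already adjusted/transformed).
    annotation : DataFrame indexed by gene id (chrom, start, end, strand, tss).
    covariates : DataFrame samples x q or None.  Typically subject age plus
        the first genotype PCs.
    config : EqtlScanConfig
    """

    def __init__(self, geno: GenotypeMatrix, expr: pd.DataFrame,
                 annotation: pd.DataFrame,
                 covariates: pd.DataFrame | None = None,
                 config: EqtlScanConfig = EqtlScanConfig()):
        if not geno.dosages.index.equals(expr.index):
            only_g = set(geno.dosages.index) - set(expr.index)
            only_e = set(expr.index) - set(geno.dosages.index)
            if only_g or only_e:
                raise ValueError(
                    "sample mismatch between genotypes and expression; "
                    f"genotype-only={sorted(only_g)[:5]}, "
                    f"expression-only={sorted(only_e)[:5]}")
            expr = expr.loc[geno.dosages.index]
        if covariates is not None and not covariates.index.equals(geno.dosages.index):
            covariates = covariates.loc[geno.dosages.index]
        self.geno = geno
        self.expr = expr
        self.annotation = validate_annotation(
            annotation.loc[annotation.index.intersection(expr.columns)])
        self.covariates = covariates
        self.config = config

    # -- geometry ---------------------------------------------------------
    def _pair_classes(self) -> np.ndarray:
        """S x G matrix of codes: 1 = cis, 2 = trans, 0 = untested."""
        cfg = self.config
        snps = self.geno.snps
        genes = self.annotation.loc[
            [g for g in self.expr.columns if g in self.annotation.index]]
        s_chrom = snps["chrom"].astype(str).to_numpy()
        s_pos = snps["pos"].to_numpy(np.int64)
        g_chrom = genes["chrom"].astype(str).to_numpy()
        g_start = genes["start"].to_numpy(np.int64)
        g_end = genes["end"].to_numpy(np.int64)
        same = s_chrom[:, None] == g_chrom[None, :]
        dist = np.maximum.reduce([
            g_start[None, :] - s_pos[:, None],
            s_pos[:, None] - g_end[None, :],
            np.zeros((len(s_pos), len(g_start)), dtype=np.int64),
        ])
        cis = same & (dist < cfg.cis_window)
        codes = np.where(cis, 1, 0).astype(np.int8)
        if cfg.full_trans:
            codes[~cis] = 2
        elif cfg.trans_snps is not None:
            snp_mask = snps.index.isin(cfg.trans_snps)
            codes[np.ix_(snp_mask, np.ones(len(g_start), bool))] = np.where(
                cis[snp_mask], 1, 2)
        return codes, genes.index

    # -- bulk statistics --------------------------------------------------
    def _bulk_stats(self, y_resid: np.ndarray, x_resid: np.ndarray,
                    df: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """beta, t, p matrices (S x G) from residualized dosage/expression."""
        xx = (x_resid ** 2).sum(axis=0)
        yy = (y_resid ** 2).sum(axis=0)
        xy = x_resid.T @ y_resid
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = xy / xx[:, None]
            rss = np.maximum(yy[None, :] - beta * xy, 0.0)
            t = beta * np.sqrt(df * xx[:, None] / np.where(rss > 0, rss, np.nan))
        t = np.where(np.isnan(t) & (np.abs(beta) > 0), np.inf * np.sign(beta), t)
        t = np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)
        p = np.maximum(2 * stats.t.sf(np.abs(t), df), P_MIN)
        return beta, t, p

    def fit(self) -> "EqtlScanResults":
        """Run the scan and the permutation FDR; return results."""
        cfg = self.config
        n = self.geno.n_samples
        gene_ids = [g for g in self.expr.columns if g in self.annotation.index]
        y = self.expr.loc[:, gene_ids].to_numpy(dtype=float)
        x = self.geno.dosages.to_numpy(dtype=float)
        if self.covariates is None or self.covariates.shape[1] == 0:
            design = np.ones((n, 1))
            q = 0
        else:
            cov = self.covariates.to_numpy(dtype=float)
            design = np.column_stack([np.ones(n), cov])
            q = cov.shape[1]
        df = n - q - 2
        if df < 1:
            raise ValueError("not enough samples for covariate count")

        x_sd = x.std(axis=0)
        constant = x_sd == 0
        if constant.any():
            logger.warning("skipping %d constant-dosage SNP(s)", constant.sum())

        fitted = design @ np.linalg.lstsq(design, y, rcond=None)[0]
        e_y = y - fitted                       # expression residuals
        x_resid = _residualize(x, design)
        codes, gene_index = self._pair_classes()
        codes[constant, :] = 0

        beta, t, p = self._bulk_stats(e_y, x_resid, df)

        rng = np.random.default_rng(cfg.seed)
        null_p = {1: [], 2: []}
        for _ in range(cfg.n_permutations):
            perm = rng.permutation(n)
            y_star = _residualize(fitted + e_y[perm], design)
            _, _, p_b = self._bulk_stats(y_star, x_resid, df)
            for cls in (1, 2):
                mask = codes == cls
                if mask.any():
                    null_p[cls].append(p_b[mask])

        records = self._build_records(codes, gene_index, beta, t, p, null_p)
        return EqtlScanResults(records=records, config=cfg, model=self)

    def _build_records(self, codes, gene_index, beta, t, p, null_p) -> pd.DataFrame:
        snps = self.geno.snps
        frames = []
        for cls, label in ((1, "cis"), (2, "trans")):
            si, gi = np.nonzero(codes == cls)
            if len(si) == 0:
                continue
            obs_p = p[si, gi]
            fdr, signif = _permutation_fdr_tail(
                obs_p, np.concatenate(null_p[cls]) if null_p[cls] else np.array([]),
                len(null_p[cls]), self.config.fdr_level)
            frames.append(pd.DataFrame({
                "snp": snps.index.to_numpy()[si],
                "chrom": snps["chrom"].to_numpy()[si],
                "pos": snps["pos"].to_numpy()[si],
                "gene": gene_index.to_numpy()[gi],
                "beta": beta[si, gi],
                "t": t[si, gi],
                "p": obs_p,
                "class": label,
                "fdr": fdr,
                "significant": signif,
            }))
        if not frames:
            return pd.DataFrame(columns=["snp", "chrom", "pos", "gene", "beta",
                                         "t", "p", "class", "fdr", "significant"])
        out = pd.concat(frames, ignore_index=True)
        out = out.sort_values(["chrom", "pos", "gene"],
                              kind="mergesort").reset_index(drop=True)
        return out


def _permutation_fdr_tail(obs_p: np.ndarray, null_p: np.ndarray, n_perm: int,
                          level: float) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-tail permutation FDR.

    For each observed p-value threshold t,
    ``FDR(t) = (mean over permutations of #{null p <= t}) / #{observed p <= t}``,
    then regularized to be monotone non-decreasing in t (q-value style
    running minimum from the largest threshold down).  Significance is the
    p-threshold set {p <= t*} with t* the largest threshold at FDR <= level.
    """
    m = len(obs_p)
    if m == 0:
        return np.array([]), np.array([], dtype=bool)
    order = np.argsort(obs_p, kind="mergesort")
    sorted_p = obs_p[order]
    # ties: every tied observation gets the count at the last tied position
    obs_counts = np.searchsorted(sorted_p, sorted_p, side="right").astype(float)
    if n_perm > 0 and len(null_p):
        null_sorted = np.sort(null_p)
        null_counts = np.searchsorted(null_sorted, sorted_p, side="right") / n_perm
    else:
        null_counts = np.zeros(m)
    fdr_raw = np.minimum(null_counts / obs_counts, 1.0)
    # running min from largest p down -> monotone non-decreasing in p
    fdr_reg = np.minimum.accumulate(fdr_raw[::-1])[::-1]
    passing = fdr_reg <= level
    if passing.any():
        t_star = sorted_p[np.flatnonzero(passing)[-1]]
    else:
        t_star = -np.inf
    fdr = np.empty(m)
    fdr[order] = fdr_reg
    signif = obs_p <= t_star
    return fdr, signif


@dataclass
class EqtlScanResults:
    """Fitted scan results.

    ``records`` has one row per tested (SNP, gene) pair with columns
    snp, chrom, pos, gene, beta, t, p, class, fdr, significant.
    """

    records: pd.DataFrame
    config: EqtlScanConfig
    model: EqtlScan | None = None

    def significant(self, cls: str | None = None) -> pd.DataFrame:
        rec = self.records[self.records["significant"]]
        if cls is not None:
            rec = rec[rec["class"] == cls]
        return rec

    def egenes(self, cls: str = "cis") -> set[str]:
        """Distinct genes with >= 1 significant record of the class."""
        return set(self.significant(cls)["gene"])

    def esnps(self, cls: str = "cis") -> set[str]:
        return set(self.significant(cls)["snp"])

    def summary(self) -> str:
        lines = ["eQTL scan summary", "=" * 40]
        for cls in ("cis", "trans"):
            sub = self.records[self.records["class"] == cls]
            if len(sub) == 0:
                continue
            sig = sub[sub["significant"]]
            lines += [
                f"{cls}: {len(sub)} pairs tested, "
                f"{len(sig)} significant at FDR {self.config.fdr_level:g}",
                f"     unique eSNPs: {sig['snp'].nunique()}, "
                f"unique egenes: {sig['gene'].nunique()}",
            ]
        lines.append(f"permutations: {self.config.n_permutations}, "
                     f"seed: {self.config.seed}")
        return "\n".join(lines)
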