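"""Expression adjustment before eQTL detection: removal of the leading
expression principal components (default ten) followed by a per-gene
rank-based inverse normal transform.

PC removal absorbs broad unwanted variation (batch, RNA quality, cell-type
composition, demographics); the inverse normal transform makes each gene's
values exactly Gaussian-ranked, robustifying the linear-model scan against
outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class AdjustmentConfig:
    n_pcs_remove: int = 10
    transform: str = "inverse_normal"  # or "none"

    def __post_init__(self) -> None:
        if self.transform not in ("inverse_normal", "none"):
            raise ValueError(f"unknown transform {self.transform!r}")


def remove_pcs(expr: pd.DataFrame, k: int) -> pd.DataFrame:
    """Subtract the rank-``k`` principal-component reconstruction of the
    samples x genes expression matrix.

    PCA is over samples (genes as features) of the gene-centred matrix; the
    residual is the input minus its projection onto the first ``k`` sample
    PCs, leaving gene-wise means at zero.  ``k = 0`` only mean-centres.
    """
    mat = expr.to_numpy(dtype=float)
    if not np.isfinite(mat).all():
        raise ValueError("expression must be finite")
    n = mat.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < n_samples={n}")
    centred = mat - mat.mean(axis=0)
    if k == 0:
        return pd.DataFrame(centred, index=expr.index, columns=expr.columns)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if len(s) else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    residual = centred - (u[:, :k] * s[:k]) @ vt[:k]
    return pd.DataFrame(residual, index=expr.index, columns=expr.columns)


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform, ties to mean rank.

    Maps value with rank r (1..n) to ``Phi^-1((r - 0.5) / n)``.  An all-tied
    vector maps to zeros.  Output order matches input order.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - 0.5) / v.size)


def adjust_expression(expr: pd.DataFrame,
                      config: AdjustmentConfig = AdjustmentConfig()
                      ) -> pd.DataFrame:
    """PC removal then (optionally) per-gene inverse normal transform."""
    out = remove_pcs(expr, config.n_pcs_remove)
    if config.transform == "inverse_normal":
        out = pd.DataFrame(
            np.apply_along_axis(inverse_normal_transform, 0, out.to_numpy()),
            index=out.index, columns=out.columns)
    return out
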