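"""Linkage disequilibrium from genotype dosages: pairwise composite r² and
expansion of index SNPs into proxy sets (r² >= threshold within a window).

r² here is the squared Pearson correlation of unphased dosage vectors
(composite LD), which converges to the haplotype r² under Hardy-Weinberg
equilibrium.  Proxy expansion replaces external phased-panel lookups: the
same genotype matrix that feeds the eQTL scan defines the LD structure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class LdExpansion:
    """Mapping index SNP id -> DataFrame of (proxy, r2, chrom, pos).

    Every index SNP that is present in the panel maps to itself with
    r² = 1; absent index SNPs get a self-only entry.
    """

    proxies: dict[str, pd.DataFrame] = field(default_factory=dict)
    missing_from_panel: list[str] = field(default_factory=list)

    def proxy_ids(self, index_snp: str) -> list[str]:
        df = self.proxies.get(index_snp)
        return [] if df is None else list(df["proxy"])

    def all_proxy_ids(self) -> set[str]:
        out: set[str] = set()
        for df in self.proxies.values():
            out.update(df["proxy"])
        return out

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for idx, df in self.proxies.items():
            d = df.copy()
            d.insert(0, "index_snp", idx)
            frames.append(d)
        if not frames:
            return pd.DataFrame(columns=["index_snp", "proxy", "r2", "chrom", "pos"])
        return pd.concat(frames, ignore_index=True)


def r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (composite LD)."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("dosage vectors must share length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("r2 undefined for constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def expand(index_snps: list[str], geno: GenotypeMatrix,
           r2_min: float = 0.8, search_window: int = 1_000_000) -> LdExpansion:
    """Expand each index SNP to all panel SNPs with r² >= ``r2_min``
    (inclusive) within ``search_window`` bp on the same chromosome.

    Index SNPs absent from the panel are reported and kept as self-only
    entries with r² = 1 but no position.  Constant-dosage panel SNPs are
    excluded from proxy candidacy (r² undefined).
    """
    result = LdExpansion()
    snps = geno.snps
    mat = geno.dosages.to_numpy(dtype=float)
    sds = mat.std(axis=0)
    col_of = {s: j for j, s in enumerate(geno.snp_ids)}
    for idx in index_snps:
        if idx not in col_of:
            result.missing_from_panel.append(idx)
            warnings.warn(f"index SNP {idx} absent from genotype panel; "
                          "kept as self-only", stacklevel=2)
            result.proxies[idx] = pd.DataFrame(
                [{"proxy": idx, "r2": 1.0, "chrom": None, "pos": None}])
            continue
        j = col_of[idx]
        chrom = snps["chrom"].iloc[j]
        pos = int(snps["pos"].iloc[j])
        in_window = ((snps["chrom"] == chrom)
                     & (np.abs(snps["pos"] - pos) <= search_window)).to_numpy()
        rows = [{"proxy": idx, "r2": 1.0, "chrom": chrom, "pos": pos}]
        if sds[j] > 0:
            cand = np.flatnonzero(in_window & (sds > 0))
            cand = cand[cand != j]
            if len(cand):
                x = (mat[:, j] - mat[:, j].mean()) / sds[j]
                y = (mat[:, cand] - mat[:, cand].mean(axis=0)) / sds[cand]
                r = x @ y / mat.shape[0]
                rr = r * r
                for c, val in zip(cand, rr):
                    # inclusive threshold with float-roundoff guard so that
                    # duplicated columns (r2 == 1) pass r2_min = 1.0
                    if val >= r2_min - 1e-12:
                        rows.append({"proxy": geno.snp_ids[c],
                                     "r2": float(val),
                                     "chrom": snps["chrom"].iloc[c],
                                     "pos": int(snps["pos"].iloc[c])})
        result.proxies[idx] = pd.DataFrame(rows)
    return result
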