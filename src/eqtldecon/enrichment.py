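"""Enrichment statistics: trait-catalog Fisher tests, chromatin-state
fold-enrichment, and a local-shift permutation test.

The state fold-enrichment of a variant set is the fraction of variants
falling in a state divided by the fraction of the genome the state covers.
The local-shift test builds its null by circularly shifting the annotation
intervals within a window around each locus independently, preserving local
annotation structure while randomising placement relative to the variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import IntervalSet, _merge

logger = logging.getLogger(__name__)

#: default collapse of the 18 ChromHMM states (6-mark model) to nine.
DEFAULT_STATE_COLLAPSE = {
    "TssA": "TSS", "TssFlnk": "TSS", "TssFlnkU": "TSS", "TssFlnkD": "TSS",
    "Tx": "Tx", "TxWk": "Tx",
    "EnhG1": "Enh", "EnhG2": "Enh", "EnhWk": "Enh",
    "EnhA1": "EnhA", "EnhA2": "EnhA",
    "ZNF-Rpts": "Het", "Het": "Het",
    "EnhBiv": "EnhBiv",
    "TssBiv": "TssBiv",
    "ReprPC": "ReprPC", "ReprPCWk": "ReprPC",
    "Quies": "Quies",
}


@dataclass
class EnrichmentResult:
    unit: str
    statistic: float
    p: float
    p_adjusted: float
    extra: dict | None = None


def collapse_states(seg18: IntervalSet,
                    mapping: dict[str, str] = DEFAULT_STATE_COLLAPSE
                    ) -> IntervalSet:
    """Relabel a segmentation through ``mapping`` and merge adjacent
    same-label intervals."""
    df = seg18.df
    labels = df["name"]
    unmapped = sorted(set(labels) - set(mapping))
    if unmapped:
        raise ValueError(f"states not in collapse mapping: {unmapped}")
    out = df.assign(name=labels.map(mapping))
    rows = []
    for _, grp in out.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        cur = None
        for rec in grp.itertuples(index=False):
            if (cur is not None and rec.name == cur["name"]
                    and rec.start <= cur["end"]):
                cur["end"] = max(cur["end"], rec.end)
            else:
                if cur is not None:
                    rows.append(cur)
                cur = {"chrom": rec.chrom, "start": rec.start,
                       "end": rec.end, "name": rec.name}
        if cur is not None:
            rows.append(cur)
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]))


def state_fold_enrichment(positions: pd.DataFrame, seg: IntervalSet,
                          genome_lengths: dict[str, int]) -> pd.Series:
    """Per-state fold-enrichment of a set of 1-based positions.

    fold(state) = (fraction of positions in the state)
                  / (state bp / total genome bp).
    States covering zero bp are reported as NaN.
    """
    total_bp = float(sum(genome_lengths.values()))
    n_pos = len(positions)
    if n_pos == 0:
        raise ValueError("no positions supplied")
    df = seg.df
    state_bp = df.groupby("name").apply(
        lambda g: float((g["end"] - g["start"]).sum()), include_groups=False)
    hits = {s: 0 for s in state_bp.index}
    by_chrom = {c: g for c, g in df.groupby("chrom")}
    for chrom, rows in positions.groupby("chrom"):
        sub = by_chrom.get(str(chrom))
        if sub is None:
            continue
        starts = sub["start"].to_numpy(np.int64)
        idx = np.searchsorted(starts, rows["pos"].to_numpy(np.int64) - 1,
                              side="right") - 1
        for i, base in zip(idx, rows["pos"].to_numpy(np.int64) - 1):
            if i >= 0 and sub["end"].iloc[i] > base:
                hits[sub["name"].iloc[i]] += 1
    out = {}
    for state, bp in state_bp.items():
        if bp == 0:
            out[state] = np.nan
        else:
            out[state] = (hits[state] / n_pos) / (bp / total_bp)
    return pd.Series(out, name="fold").sort_index()


def catalog_enrichment(query_snps: set[str], catalog: pd.DataFrame,
                       min_trait_size: int = 10,
                       ld: "dict[str, set[str]] | None" = None
                       ) -> pd.DataFrame:
    """One-sided Fisher enrichment of a query SNP set per catalog trait.

    The background is the deduplicated union of all catalog SNPs.  For each
    trait with >= ``min_trait_size`` SNPs, a 2x2 table of trait membership
    against query membership is tested one-sided (greater), Bonferroni
    adjusted over the tested traits.  With ``ld`` (catalog SNP -> proxy ids)
    a catalog SNP counts as a query hit if any proxy is in the query.

    Returns a DataFrame (trait, n_trait, n_overlap, p, p_adjusted) plus the
    skipped traits in ``.attrs['skipped']``.
    """
    background = set(catalog["snp"])
    if ld is not None:
        def in_query(s: str) -> bool:
            return s in query_snps or bool(ld.get(s, set()) & query_snps)
    else:
        def in_query(s: str) -> bool:
            return s in query_snps
    hit_bg = {s for s in background if in_query(s)}
    trait_sets = {t: set(g["snp"]) for t, g in catalog.groupby("trait")}
    tested = {t: s for t, s in trait_sets.items() if len(s) >= min_trait_size}
    skipped = sorted(set(trait_sets) - set(tested))
    if skipped:
        logger.info("catalog_enrichment: skipped %d trait(s) below size %d",
                    len(skipped), min_trait_size)
    n_tests = len(tested)
    rows = []
    big_n = len(background)
    n_hit = len(hit_bg)
    for trait, snps in sorted(tested.items()):
        k = len(snps & hit_bg)
        big_k = len(snps)
        # P(X >= k), X ~ Hypergeom(N=big_n, K=big_k, n=n_hit)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n_hit))
        rows.append({"trait": trait, "n_trait": big_k, "n_overlap": k,
                     "p": p, "p_adjusted": min(1.0, p * n_tests)})
    out = pd.DataFrame(rows, columns=["trait", "n_trait", "n_overlap",
                                      "p", "p_adjusted"])
    out.attrs["skipped"] = skipped
    return out


def local_shift_test(loci: pd.DataFrame, proxies: dict[str, list[int]] | None,
                     annotation: IntervalSet, window: int = 500_000,
                     n_perm: int = 10_000, seed: int = 0,
                     exhaustive: bool = False) -> dict:
    """Local-shift permutation enrichment of lead variants (plus LD
    proxies) in an annotation.

    Parameters
    ----------
    loci : DataFrame with columns ``chrom, pos`` (1-based), one lead
        variant per locus (e.g. the lowest-p eQTL per gene).
    proxies : optional mapping lead id (loci index) -> list of 1-based
        proxy positions on the same chromosome.
    annotation : IntervalSet to test.
    window : half-width of the locus window around the lead.
    exhaustive : enumerate every integer shift instead of sampling
        (only sensible for tiny windows); overrides ``n_perm``.

    Observed score = number of loci where the lead or any proxy overlaps
    the annotation.  Null: per locus independently, circularly shift the
    annotation restricted to [lead - window, lead + window) by a uniform
    offset and recompute.  p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    rng = np.random.default_rng(seed)
    ann_by_chrom = {c: g for c, g in annotation.df.groupby("chrom")}
    locus_data = []
    for lead_id, row in loci.iterrows():
        chrom = str(row["chrom"])
        lead = int(row["pos"])
        pos_list = [lead] + list(proxies.get(lead_id, []) if proxies else [])
        w_start = lead - 1 - window
        w_len = 2 * window
        sub = ann_by_chrom.get(chrom)
        if sub is None or len(sub) == 0:
            locus_data.append((np.array([]), np.array([], np.int64), w_len))
            continue
        starts = np.maximum(sub["start"].to_numpy(np.int64) - w_start, 0)
        ends = np.minimum(sub["end"].to_numpy(np.int64) - w_start, w_len)
        valid = starts < ends
        m_starts, m_ends = _merge(starts[valid], ends[valid])
        boundaries = np.empty(2 * len(m_starts), dtype=np.int64)
        boundaries[0::2] = m_starts
        boundaries[1::2] = m_ends
        rel = np.array([p - 1 - w_start for p in pos_list], dtype=np.int64)
        rel = rel[(rel >= 0) & (rel < w_len)]
        locus_data.append((boundaries, rel, w_len))

    def overlap(boundaries: np.ndarray, rel_pos: np.ndarray, shift: np.ndarray,
                w_len: int) -> np.ndarray:
        """Per shift: does any position fall in the shifted annotation?"""
        if len(boundaries) == 0 or len(rel_pos) == 0:
            return np.zeros(len(shift), dtype=bool)
        shifted = (rel_pos[None, :] - shift[:, None]) % w_len
        inside = np.searchsorted(boundaries, shifted, side="right") % 2 == 1
        return inside.any(axis=1)

    observed = sum(
        bool(overlap(b, r, np.array([0]), w)[0]) for b, r, w in locus_data)
    if exhaustive:
        # full cartesian enumeration is exponential; enumerate only when a
        # single locus is tested (the intended use of exhaustive mode)
        if len(locus_data) != 1:
            raise ValueError("exhaustive mode supports a single locus")
        b, r, w = locus_data[0]
        null = overlap(b, r, np.arange(w), w).astype(int)
        n_used = w
    else:
        null = np.zeros(n_perm, dtype=int)
        for b, r, w in locus_data:
            shifts = rng.integers(0, w, size=n_perm)
            null += overlap(b, r, shifts, w)
        n_used = n_perm
    p = (1 + int((null >= observed).sum())) / (1 + n_used)
    return {"observed": int(observed), "p": float(p), "n_perm": int(n_used),
            "null_mean": float(null.mean()) if len(null) else np.nan}
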