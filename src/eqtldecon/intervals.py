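"""Genomic interval arithmetic: promoter/gene-locus windows, peak filtering,
SNP-in-interval overlap.

Coordinate conventions
----------------------
All intervals are 0-based half-open ``[start, end)`` (BED native).  SNP
positions are 1-based (VCF native); a SNP at 1-based position ``p`` occupies
the 0-based base ``p - 1`` and hits an interval iff ``start <= p - 1 < end``.
Readers convert at the boundary so every in-memory operation sees one
convention only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass
class IntervalSet:
    """A named set of genomic intervals, 0-based half-open, sorted.

    Parameters
    ----------
    df : pandas.DataFrame
        Columns ``chrom, start, end`` required; ``name`` (label),
        ``score`` (e.g. ChIP peak fold-enrichment) and ``strand``
        optional.  Stored sorted by (chrom, start, end).
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "start", "end"]))

    def __post_init__(self) -> None:
        df = self.df
        missing = {"chrom", "start", "end"} - set(df.columns)
        if missing:
            raise ValueError(f"IntervalSet missing columns: {sorted(missing)}")
        if len(df) and not (df["start"] < df["end"]).all():
            bad = df[~(df["start"] < df["end"])]
            raise ValueError(f"start < end violated for {len(bad)} interval(s)")
        self.df = df.sort_values(["chrom", "start", "end"],
                                 kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def has_scores(self) -> bool:
        return "score" in self.df.columns and self.df["score"].notna().all()

    def by_chrom(self) -> dict[str, pd.DataFrame]:
        return {str(c): g for c, g in self.df.groupby("chrom", sort=True)}

    def total_bp(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())


def promoter_windows(annotation: pd.DataFrame, upstream: int = 1500,
                     downstream: int = 500,
                     chrom_lengths: dict[str, int] | None = None) -> IntervalSet:
    """Strand-aware promoter windows around each gene's TSS.

    The window spans ``upstream`` bp 5' of the TSS to ``downstream`` bp 3' of
    it: ``[tss - upstream, tss + downstream)`` on the + strand and the mirror
    image ``[tss - downstream, tss + upstream)`` on the - strand.  Windows are
    clamped to ``[0, chrom length)`` when lengths are given.

    Parameters
    ----------
    annotation : DataFrame indexed by gene id with columns
        ``chrom, start, end, strand, tss`` (tss is a 0-based coordinate).
    """
    _require_annotation(annotation, need_tss=True)
    tss = annotation["tss"].to_numpy(dtype=np.int64)
    plus = (annotation["strand"] == "+").to_numpy()
    start = np.where(plus, tss - upstream, tss - downstream)
    end = np.where(plus, tss + downstream, tss + upstream)
    return _clamped(annotation, start, end, chrom_lengths)


def gene_locus_windows(annotation: pd.DataFrame, upstream: int = 1500,
                       downstream: int = 500,
                       chrom_lengths: dict[str, int] | None = None) -> IntervalSet:
    """Gene-body windows from ``upstream`` bp 5' of the TSS to ``downstream``
    bp 3' of the transcript termination site, strand-aware.

    On the + strand: ``[start - upstream, end + downstream)``; on the
    - strand the mirror ``[start - downstream, end + upstream)``.
    """
    _require_annotation(annotation)
    if (annotation["start"] >= annotation["end"]).any():
        raise ValueError("zero- or negative-length transcript in annotation")
    g_start = annotation["start"].to_numpy(dtype=np.int64)
    g_end = annotation["end"].to_numpy(dtype=np.int64)
    plus = (annotation["strand"] == "+").to_numpy()
    start = np.where(plus, g_start - upstream, g_start - downstream)
    end = np.where(plus, g_end + downstream, g_end + upstream)
    return _clamped(annotation, start, end, chrom_lengths)


def filter_peaks(peaks: IntervalSet, min_fold: float = 4.0) -> IntervalSet:
    """Keep peaks with fold-enrichment strictly greater than ``min_fold``.

    A peak scoring exactly ``min_fold`` is removed.
    """
    if len(peaks) == 0:
        return IntervalSet(peaks.df.copy())
    if "score" not in peaks.df.columns or peaks.df["score"].isna().any():
        raise ValueError("filter_peaks requires a score on every peak")
    return IntervalSet(peaks.df[peaks.df["score"] > min_fold].copy())


def subtract_overlapping(peaks: IntervalSet, windows: IntervalSet) -> IntervalSet:
    """Remove every peak that shares >= 1 bp with any window.

    Whole-peak removal, never truncation.  Half-open abutment
    (``peak.start == window.end``) is not overlap.
    """
    if len(peaks) == 0 or len(windows) == 0:
        return IntervalSet(peaks.df.copy())
    keep = ~_overlaps_any(peaks.df, windows)
    return IntervalSet(peaks.df[keep].copy())


def _overlaps_any(query: pd.DataFrame, subject: IntervalSet) -> np.ndarray:
    """Boolean per query row: does it overlap any subject interval?"""
    out = np.zeros(len(query), dtype=bool)
    subj = subject.by_chrom()
    for chrom, rows in query.groupby("chrom", sort=False):
        s = subj.get(str(chrom))
        if s is None:
            continue
        # merged subject intervals per chrom -> boundary stabbing
        starts, ends = _merge(s["start"].to_numpy(np.int64),
                              s["end"].to_numpy(np.int64))
        qs = rows["start"].to_numpy(np.int64)
        qe = rows["end"].to_numpy(np.int64)
        # overlap iff some merged [s_i, e_i) has s_i < qe and e_i > qs:
        # find first merged interval with end > qs, check its start < qe
        idx = np.searchsorted(ends, qs, side="right")
        hit = (idx < len(starts)) & (starts[np.minimum(idx, len(starts) - 1)] < qe)
        out[query.index.get_indexer(rows.index)] = hit
    return out


def _merge(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge sorted intervals (touching intervals kept separate is fine for
    stabbing; we merge overlapping-or-touching for simplicity)."""
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="mergesort")
    starts, ends = starts[order], ends[order]
    m_starts, m_ends = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= m_ends[-1]:
            m_ends[-1] = max(m_ends[-1], e)
        else:
            m_starts.append(s)
            m_ends.append(e)
    return np.asarray(m_starts), np.asarray(m_ends)


def snps_in_intervals(snps: pd.DataFrame, intervals: IntervalSet) -> pd.DataFrame:
    """All (SNP, interval) overlap pairs.

    Parameters
    ----------
    snps : DataFrame indexed by snp id with columns ``chrom, pos``
        (pos 1-based).

    Returns
    -------
    DataFrame with columns ``snp, chrom, pos, interval_index, start, end``
    plus ``name``/``score`` if present on the intervals;
    ``interval_index`` indexes into ``intervals.df``.
    """
    hits: list[dict] = []
    by_chrom = intervals.by_chrom()
    for chrom, rows in snps.groupby("chrom", sort=False):
        sub = by_chrom.get(str(chrom))
        if sub is None:
            continue
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        order = np.argsort(starts, kind="mergesort")
        starts_sorted = starts[order]
        for snp_id, pos in zip(rows.index, rows["pos"].to_numpy(np.int64)):
            base = pos - 1  # 1-based -> 0-based
            # candidates: intervals with start <= base; intervals are sorted
            # by start but ends are not nested-monotone, so scan candidates.
            hi = np.searchsorted(starts_sorted, base, side="right")
            for j in order[:hi]:
                if ends[j] > base:
                    rec = {"snp": snp_id, "chrom": chrom, "pos": int(pos),
                           "interval_index": int(sub.index[j]),
                           "start": int(starts[j]), "end": int(ends[j])}
                    for col in ("name", "score", "strand"):
                        if col in sub.columns:
                            rec[col] = sub[col].iloc[j]
                    hits.append(rec)
    cols = ["snp", "chrom", "pos", "interval_index", "start", "end"]
    for col in ("name", "score", "strand"):
        if col in intervals.df.columns:
            cols.append(col)
    return pd.DataFrame(hits, columns=cols)


def _require_annotation(annotation: pd.DataFrame, need_tss: bool = False) -> None:
    need = {"chrom", "start", "end", "strand"} | ({"tss"} if need_tss else set())
    missing = need - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    if not annotation["strand"].isin(["+", "-"]).all():
        bad = annotation.index[~annotation["strand"].isin(["+", "-"])]
        raise ValueError(f"missing/invalid strand for genes: {list(bad)[:5]}")


def _clamped(annotation: pd.DataFrame, start: np.ndarray, end: np.ndarray,
             chrom_lengths: dict[str, int] | None) -> IntervalSet:
    start = np.maximum(start, 0)
    if chrom_lengths is not None:
        limits = annotation["chrom"].map(chrom_lengths).to_numpy(dtype=np.int64)
        end = np.minimum(end, limits)
    df = pd.DataFrame({
        "chrom": annotation["chrom"].to_numpy(),
        "start": start.astype(np.int64),
        "end": end.astype(np.int64),
        "name": annotation.index.to_numpy(),
        "strand": annotation["strand"].to_numpy(),
    })
    return IntervalSet(df)
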