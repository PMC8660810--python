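"""Peak post-processing: summit extension, replicate reproducibility filtering,
and cross-cell-type classification into shared / condition-specific sets.

The classification rule: a peak is *shared* iff its best single-partner overlap
with the other condition's peak set is at least ``overlap_min`` bases (default
10 bp), otherwise it is unique to its condition. Overlap is per best partner
(the maximum single overlap), not summed across partners, matching BEDtools
``-f``-style semantics. Bookended intervals (overlap 0) are never shared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import GenomicInterval, Peak, ValidationError


class _ChromIndex:
    """Sorted-start interval index with a cumulative-max end for pruning scans."""

    def __init__(self, intervals: list[tuple[int, int, int]]):
        # (start, end, original index), sorted by start
        self.items = sorted(intervals)
        self.starts = np.array([s for s, _, _ in self.items], dtype=np.int64)
        ends = np.array([e for _, e, _ in self.items], dtype=np.int64)
        self.cummax_end = np.maximum.accumulate(ends) if len(ends) else ends

    def max_overlap(self, start: int, end: int) -> tuple[int, int]:
        """Return (max single overlap, index of that partner); (0, -1) if none."""
        if len(self.items) == 0:
            return 0, -1
        hi = int(np.searchsorted(self.starts, end, side="left"))
        lo = int(np.searchsorted(self.cummax_end[:hi], start, side="right"))
        best, best_idx = 0, -1
        for s, e, idx in self.items[lo:hi]:
            ov = min(end, e) - max(start, s)
            if ov > best:
                best, best_idx = ov, idx
        return best, best_idx


def _index_peaks(peaks: list[Peak]) -> dict[str, _ChromIndex]:
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, p in enumerate(peaks):
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end, i))
    return {c: _ChromIndex(v) for c, v in by_chrom.items()}


def _index_intervals(intervals: list[GenomicInterval]) -> dict[str, _ChromIndex]:
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, iv in enumerate(intervals):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, i))
    return {c: _ChromIndex(v) for c, v in by_chrom.items()}


def extend_summits(
    peaks: list[Peak], flank: int = 100, chrom_sizes: dict[str, int] | None = None
) -> list[Peak]:
    """Replace each peak interval with ``[summit - flank, summit + flank)``,
    clipped to the chromosome (default width 200 bp)."""
    if chrom_sizes is None:
        raise ValidationError("chrom_sizes is required for clipping")
    out = []
    for p in peaks:
        if p.chrom not in chrom_sizes:
            raise ValidationError(f"unknown chromosome {p.chrom}")
        size = chrom_sizes[p.chrom]
        if not (0 <= p.summit < size):
            raise ValidationError(f"summit {p.summit} outside {p.chrom} (length {size})")
        iv = GenomicInterval(
            chrom=p.chrom,
            start=max(0, p.summit - flank),
            end=min(size, p.summit + flank),
            strand=p.interval.strand,
            name=p.name,
        )
        out.append(Peak(interval=iv, summit=p.summit, score=p.score, zscore=p.zscore))
    return out


def _merge_union(peaks: list[Peak]) -> list[Peak]:
    """Union-merge overlapping or bookended peak intervals per chromosome.

    Merged regions get summit = interval midpoint and score = max constituent
    score (the merge discards individual summits).
    """
    merged: list[Peak] = []
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda p: (p.start, p.end))
        cur_start, cur_end = group[0].start, group[0].end
        cur_score = group[0].score
        for p in group[1:]:
            if p.start <= cur_end:  # overlapping or bookended
                cur_end = max(cur_end, p.end)
                cur_score = max(cur_score, p.score)
            else:
                iv = GenomicInterval(chrom=chrom, start=cur_start, end=cur_end)
                merged.append(Peak(interval=iv, summit=(cur_start + cur_end) // 2, score=cur_score))
                cur_start, cur_end, cur_score = p.start, p.end, p.score
        iv = GenomicInterval(chrom=chrom, start=cur_start, end=cur_end)
        merged.append(Peak(interval=iv, summit=(cur_start + cur_end) // 2, score=cur_score))
    return merged


def reproducible_peaks(
    rep1: list[Peak],
    rep2: list[Peak],
    min_frac: float = 0.5,
    anchor: str = "union",
) -> list[Peak]:
    """High-confidence peaks: regions reproducible across two replicates.

    A peak from either replicate is retained iff at least ``min_frac`` of its
    own length is covered by its best single partner in the other replicate.
    With ``anchor='union'`` (default) the retained peaks from both replicates
    are union-merged; ``anchor='rep1'`` returns the surviving replicate-1 peaks
    unmerged.
    """
    if anchor not in ("union", "rep1"):
        raise ValidationError("anchor must be 'union' or 'rep1'")
    if not rep1 or not rep2:
        warnings.warn("empty replicate: no reproducible peaks", stacklevel=2)
        return []
    idx1, idx2 = _index_peaks(rep1), _index_peaks(rep2)

    def survivors(peaks: list[Peak], other: dict[str, _ChromIndex]) -> list[Peak]:
        kept = []
        for p in peaks:
            index = other.get(p.chrom)
            ov = index.max_overlap(p.start, p.end)[0] if index else 0
            if ov >= min_frac * len(p.interval):
                kept.append(p)
        return kept

    kept1 = survivors(rep1, idx2)
    if anchor == "rep1":
        return kept1
    kept2 = survivors(rep2, idx1)
    if not kept1 and not kept2:
        return []
    return _merge_union(kept1 + kept2)


@dataclass
class ClassifiedPeaks:
    """Exhaustive, disjoint partition of two peak sets into shared and unique.

    ``pairs`` lists each shared condition-A peak with its best-overlap partner
    in B. ``shared_a`` / ``shared_b`` are the shared peaks of each set, so every
    input peak appears in exactly one of shared/unique for its condition.
    """

    shared_a: list[Peak]
    shared_b: list[Peak]
    unique_a: list[Peak]
    unique_b: list[Peak]
    pairs: list[tuple[Peak, Peak]]
    label_a: str = "A"
    label_b: str = "B"
    overlap_min: int = 10

    @property
    def n_shared_a(self) -> int:
        return len(self.shared_a)

    @property
    def n_shared_b(self) -> int:
        return len(self.shared_b)

    def summary(self) -> str:
        return (
            f"{self.label_a}: {self.n_shared_a} shared, {len(self.unique_a)} unique | "
            f"{self.label_b}: {self.n_shared_b} shared, {len(self.unique_b)} unique "
            f"(>= {self.overlap_min} bp best-partner overlap)"
        )


def classify_cross_condition(
    set_a: list[Peak],
    set_b: list[Peak],
    overlap_min: int = 10,
    label_a: str = "A",
    label_b: str = "B",
) -> ClassifiedPeaks:
    """Partition two conditions' peaks into shared (>= ``overlap_min`` bp best
    single-peak overlap with the other set) and condition-unique."""
    overlap_min = max(overlap_min, 1)  # bookended intervals (overlap 0) are never shared
    idx_a, idx_b = _index_peaks(set_a), _index_peaks(set_b)
    shared_a, unique_a, pairs = [], [], []
    for p in set_a:
        index = idx_b.get(p.chrom)
        ov, j = index.max_overlap(p.start, p.end) if index else (0, -1)
        if ov >= overlap_min:
            shared_a.append(p)
            pairs.append((p, set_b[j]))
        else:
            unique_a.append(p)
    shared_b, unique_b = [], []
    for p in set_b:
        index = idx_a.get(p.chrom)
        ov = index.max_overlap(p.start, p.end)[0] if index else 0
        (shared_b if ov >= overlap_min else unique_b).append(p)
    return ClassifiedPeaks(
        shared_a=shared_a, shared_b=shared_b, unique_a=unique_a, unique_b=unique_b,
        pairs=pairs, label_a=label_a, label_b=label_b, overlap_min=overlap_min,
    )


def overlap_fraction_with_set(
    query: list[Peak], reference: list[GenomicInterval]
) -> float:
    """Fraction of query peaks overlapping (>= 1 bp) any reference interval."""
    if not query:
        raise ValidationError("empty query peak set")
    idx = _index_intervals(reference)
    hits = 0
    for p in query:
        index = idx.get(p.chrom)
        if index is not None and index.max_overlap(p.start, p.end)[0] >= 1:
            hits += 1
    return hits / len(query)
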