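"""Consensus benchmark construction by per-base majority vote.

Each contributing algorithm is cut to its top-N most significant peaks and
votes once per base (internal overlaps within one algorithm are merged
first). Maximal runs of bases supported by a strict majority (> k/2) of the
k algorithms form the benchmark intervals; each carries the maximum depth
reached inside the run as its support count. Base-level voting is used
because it is order-independent and needs no cross-algorithm peak identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .intervals import (
    GenomicInterval,
    PeakSet,
    ValidationError,
    merge_intervals,
    overlap_bp_per_interval,
    select_top_n,
)

__all__ = ["BenchmarkSet", "build_consensus", "common_peaks", "algorithm_specific_peaks"]


@dataclass
class BenchmarkSet:
    """Non-overlapping consensus intervals with per-interval algorithm support."""

    intervals: list[GenomicInterval]
    support: list[int]
    k_algorithms: int

    def __post_init__(self) -> None:
        if len(self.intervals) != len(self.support):
            raise ValidationError("support length mismatch")
        for s in self.support:
            if not (self.k_algorithms / 2 < s <= self.k_algorithms):
                raise ValidationError(
                    f"support {s} violates strict majority of {self.k_algorithms}"
                )
        for a, b in zip(self.intervals, self.intervals[1:]):
            if a.sort_key() > b.sort_key() or a.overlaps(b):
                raise ValidationError("benchmark intervals must be sorted and disjoint")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def as_peakset(self, label: str = "benchmark") -> PeakSet:
        return PeakSet(
            [
                GenomicInterval(iv.chrom, iv.start, iv.end,
                                name=f"{label}_{i + 1}", score=float(s))
                for i, (iv, s) in enumerate(zip(self.intervals, self.support))
            ],
            label=label,
            merged=True,
        )

    def total_bp(self) -> int:
        return sum(iv.width for iv in self.intervals)


def _depth_runs(peaksets: Sequence[PeakSet]):
    """Yield (chrom, start, end, depth) for maximal constant-depth runs of
    per-base algorithm coverage depth (each set votes at most once per base)."""
    events: dict[str, list[tuple[int, int]]] = {}
    for ps in peaksets:
        for iv in merge_intervals(list(ps)):
            events.setdefault(iv.chrom, []).append((iv.start, +1))
            events[iv.chrom].append((iv.end, -1))
    for chrom in sorted(events):
        evs = sorted(events[chrom])
        depth = 0
        prev_pos = None
        i = 0
        while i < len(evs):
            pos = evs[i][0]
            if prev_pos is not None and depth > 0 and pos > prev_pos:
                yield chrom, prev_pos, pos, depth
            while i < len(evs) and evs[i][0] == pos:
                depth += evs[i][1]
                i += 1
            prev_pos = pos


def build_consensus(
    peaksets: Sequence[PeakSet], top_n: int = 10_000, min_width: int = 1
) -> BenchmarkSet:
    """Majority-vote consensus benchmark over >= 2 ranked peak sets.

    Each set is cut to its ``top_n`` most significant peaks (requires
    significance values); bases covered by strictly more than half of the
    sets are emitted as benchmark intervals. Runs shorter than ``min_width``
    are dropped. Support per interval is the maximum vote depth inside it.
    """
    k = len(peaksets)
    if k < 2:
        raise ValidationError("consensus requires >= 2 peak sets (no majority otherwise)")
    cut = [select_top_n(ps, top_n) for ps in peaksets]
    half = k / 2.0
    intervals: list[GenomicInterval] = []
    support: list[int] = []
    # coalesce adjacent qualifying runs, tracking max depth
    cur: Optional[list] = None  # [chrom, start, end, max_depth]
    for chrom, start, end, depth in _depth_runs(cut):
        if depth > half:
            if cur is not None and cur[0] == chrom and cur[2] == start:
                cur[2] = end
                cur[3] = max(cur[3], depth)
            else:
                if cur is not None:
                    intervals.append(GenomicInterval(cur[0], cur[1], cur[2]))
                    support.append(cur[3])
                cur = [chrom, start, end, depth]
        else:
            if cur is not None:
                intervals.append(GenomicInterval(cur[0], cur[1], cur[2]))
                support.append(cur[3])
                cur = None
    if cur is not None:
        intervals.append(GenomicInterval(cur[0], cur[1], cur[2]))
        support.append(cur[3])
    if min_width > 1:
        keep = [i for i, iv in enumerate(intervals) if iv.width >= min_width]
        intervals = [intervals[i] for i in keep]
        support = [support[i] for i in keep]
    return BenchmarkSet(intervals, support, k)


def common_peaks(peaksets: Sequence[PeakSet]) -> PeakSet:
    """Maximal base runs covered by ALL peak sets, merged into intervals."""
    k = len(peaksets)
    if k < 2:
        raise ValidationError("common peaks require >= 2 peak sets")
    runs = [
        GenomicInterval(chrom, s, e)
        for chrom, s, e, depth in _depth_runs(peaksets)
        if depth == k
    ]
    return PeakSet(merge_intervals(runs), label="common", merged=True)


def algorithm_specific_peaks(peaks: PeakSet, common: PeakSet) -> PeakSet:
    """Peaks with zero overlapping bases with the common set (whole-peak removal)."""
    if len(common) == 0:
        return PeakSet(list(peaks), label=f"{peaks.label}_specific")
    ov = overlap_bp_per_interval(list(peaks), list(common))
    kept = [iv for iv, o in zip(peaks, ov) if o == 0]
    return PeakSet(kept, label=f"{peaks.label}_specific")
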