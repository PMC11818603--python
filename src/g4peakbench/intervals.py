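"""Genomic interval types and exact interval algebra.

Coordinates are 0-based, half-open throughout (BED convention): an interval
``(start, end)`` covers bases ``start .. end-1`` and has width ``end - start``.
Chromosome names are matched by exact string equality (no "chr" aliasing).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "merge_intervals",
    "intersect_bp",
    "count_overlapping",
    "overlap_bp_per_interval",
    "select_top_n",
]


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


@dataclass(frozen=True)
class GenomicInterval:
    """A located genomic feature with optional significance.

    ``pvalue`` is a plain probability in [0, 1]; callers reporting
    -log10-transformed significance must convert before construction.
    """

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    pvalue: Optional[float] = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got {self.chrom}:{self.start}-{self.end}"
            )
        if self.pvalue is not None and not (0.0 <= self.pvalue <= 1.0):
            raise ValidationError(f"pvalue {self.pvalue} outside [0, 1]")
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"strand must be one of +, -, . (got {self.strand!r})")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class PeakSet:
    """A named, ordered collection of intervals from one source algorithm.

    Construction normalizes order to (chrom, start, end). A PeakSet may
    contain overlapping intervals unless produced by :func:`merge_intervals`.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        label: str = "",
        merged: bool = False,
    ) -> None:
        self.label = label
        self.intervals: list[GenomicInterval] = sorted(intervals, key=GenomicInterval.sort_key)
        self.merged = merged
        if merged:
            for a, b in itertools.pairwise(self.intervals):
                if a.overlaps(b):
                    raise ValidationError(
                        f"merged PeakSet contains overlapping intervals {a} / {b}"
                    )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __repr__(self) -> str:
        return f"PeakSet(label={self.label!r}, n={len(self)})"

    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def total_bp(self) -> int:
        """Union base-pair coverage (internal overlaps counted once)."""
        return sum(iv.width for iv in merge_intervals(self.intervals))

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def relabel(self, label: str) -> "PeakSet":
        ps = PeakSet(self.intervals, label=label, merged=self.merged)
        return ps


def merge_intervals(
    intervals: Sequence[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Merge same-chromosome intervals separated by at most ``max_gap`` bases.

    With ``max_gap=0``, overlapping and book-ended (touching) intervals merge;
    total covered base count is preserved. Output is sorted and disjoint.
    Names/scores/significance are dropped from merged products.
    """
    if max_gap < 0:
        raise ValidationError("max_gap must be >= 0")
    ivs = sorted(intervals, key=GenomicInterval.sort_key)
    out: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = None, 0, 0
    for iv in ivs:
        if iv.chrom == cur_chrom and iv.start - cur_end <= max_gap:
            cur_end = max(cur_end, iv.end)
        else:
            if cur_chrom is not None:
                out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    if cur_chrom is not None:
        out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return out


def _union_arrays(intervals: Iterable[GenomicInterval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (starts, ends) arrays of the merged union."""
    merged = merge_intervals(list(intervals))
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    chrom_ivs: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        chrom_ivs.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in chrom_ivs.items():
        out[chrom] = (
            np.array([iv.start for iv in ivs], dtype=np.int64),
            np.array([iv.end for iv in ivs], dtype=np.int64),
        )
    return out


def overlap_bp_per_interval(
    intervals: Sequence[GenomicInterval], reference: Iterable[GenomicInterval]
) -> np.ndarray:
    """Base pairs of overlap of each interval with the union of ``reference``.

    The reference is merged internally; each query interval's overlap is
    computed against the disjoint union, so shared reference bases are never
    double counted within one query.
    """
    union = _union_arrays(reference)
    out = np.zeros(len(intervals), dtype=np.int64)
    for idx, iv in enumerate(intervals):
        if iv.chrom not in union:
            continue
        starts, ends = union[iv.chrom]
        # cumulative covered bp up to union interval i
        widths = ends - starts
        cum = np.concatenate([[0], np.cumsum(widths)])
        lo = np.searchsorted(ends, iv.start, side="right")
        hi = np.searchsorted(starts, iv.end, side="left")
        if lo >= hi:
            continue
        total = cum[hi] - cum[lo]
        # trim partial overlap at both flanks
        total -= max(0, iv.start - starts[lo])
        total -= max(0, ends[hi - 1] - iv.end)
        out[idx] = total
    return out


def intersect_bp(a: PeakSet | Sequence[GenomicInterval], b: PeakSet | Sequence[GenomicInterval]) -> int:
    """Total bases covered by both ``a`` and ``b`` (each merged internally)."""
    a_ivs = list(a)
    b_union = merge_intervals(list(b))
    a_union = merge_intervals(a_ivs)
    return int(overlap_bp_per_interval(a_union, b_union).sum())


def count_overlapping(
    a: PeakSet | Sequence[GenomicInterval],
    b: PeakSet | Sequence[GenomicInterval],
    min_bp: int = 1,
) -> int:
    """Number of intervals of ``a`` with >= ``min_bp`` bases overlapping the union of ``b``."""
    if min_bp < 1:
        raise ValidationError("min_bp must be >= 1")
    a_ivs = list(a)
    if not a_ivs:
        return 0
    ov = overlap_bp_per_interval(a_ivs, list(b))
    return int((ov >= min_bp).sum())


def select_top_n(peaks: PeakSet, n: int) -> PeakSet:
    """The ``min(n, |peaks|)`` most significant peaks, re-sorted by coordinate.

    Every interval must carry a significance value; ties in significance are
    broken by (chrom, start, end) so top-N cuts are deterministic.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    missing = [iv for iv in peaks if iv.pvalue is None]
    if missing:
        raise ValidationError(
            f"{len(missing)} interval(s) lack a significance value (first: {missing[0]})"
        )
    ranked = sorted(peaks, key=lambda iv: (iv.pvalue, iv.chrom, iv.start, iv.end))
    return PeakSet(ranked[:n], label=peaks.label)
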