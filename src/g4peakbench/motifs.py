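"""G-quadruplex motif scanning.

Two sequence patterns are implemented:

* the *typical* putative-G4 (pG4) motif — four G-runs of length >= ``min_run``
  (default 3, unbounded above) separated by three loops of 1..``max_loop``
  (default 7) arbitrary bases;
* the *negative-filter* pattern used to purge candidate negative regions —
  the same architecture with G-runs capped at exactly 3–5.

The scanner reports *merged* hits: the union of every substring matching the
pattern, coalesced into maximal loci. Because loops may themselves contain
G's, matches starting at nearby offsets overlap heavily; a greedy
single-pass regex would miss alternative parses, so the scanner instead
computes, for every start position, the furthest reachable match end by
dynamic programming over G-run/loop decompositions. The union of
``[start, furthest_end)`` over all starts equals the union of all matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .intervals import GenomicInterval, PeakSet, ValidationError, merge_intervals

__all__ = [
    "MotifHit",
    "scan_typical_pg4",
    "scan_negative_filter",
    "scan_genome",
    "reverse_complement",
]

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

N_TRACTS = 4  # four G-runs per quadruplex


@dataclass(frozen=True)
class MotifHit:
    """A merged motif locus on one strand, 0-based on the scanned sequence."""

    start: int
    end: int
    strand: str
    pattern_id: str
    n_tracts: int

    @property
    def width(self) -> int:
        return self.end - self.start


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _check_alphabet(seq: str) -> str:
    s = seq.upper()
    bad = set(s) - _VALID
    if bad:
        raise ValidationError(f"invalid nucleotide characters: {sorted(bad)}")
    return s


def _g_run_lengths(s: str) -> np.ndarray:
    """grun[i] = length of the maximal G-run starting at position i (0 if s[i] != G)."""
    is_g = np.frombuffer(s.encode(), dtype=np.uint8) == ord("G")
    L = len(s)
    if L == 0:
        return np.zeros(0, dtype=np.int64)
    # distance from each position to the next non-G position
    pos = np.arange(L, dtype=np.int64)
    next_non_g = np.full(L, L, dtype=np.int64)
    non_g = np.flatnonzero(~is_g)
    if len(non_g):
        idx = np.searchsorted(non_g, pos, side="left")
        has = idx < len(non_g)
        next_non_g[has] = non_g[idx[has]]
    grun = np.where(is_g, next_non_g - pos, 0)
    return grun


def _match_spans(
    s: str, min_run: int, max_loop: int, max_run: Optional[int]
) -> list[tuple[int, int]]:
    """(start, furthest_end) for every position where a full 4-tract match starts."""
    L = len(s)
    grun = _g_run_lengths(s)
    anchors = np.flatnonzero(grun >= min_run)
    if len(anchors) == 0:
        return []
    anchor_set = set(int(a) for a in anchors)
    # best[t][i]: max end of (G-run + loop) * (t-1) + G-run starting at i, -1 if none
    best_prev: dict[int, int] = {}
    for i in anchor_set:
        cap = grun[i] if max_run is None else min(grun[i], max_run)
        best_prev[i] = i + int(cap)
    for _t in range(2, N_TRACTS + 1):
        best_cur: dict[int, int] = {}
        for i in anchor_set:
            cap = int(grun[i] if max_run is None else min(grun[i], max_run))
            e = -1
            for r in range(min_run, cap + 1):
                for loop in range(1, max_loop + 1):
                    j = i + r + loop
                    if j in best_prev:
                        if best_prev[j] > e:
                            e = best_prev[j]
            if e >= 0:
                best_cur[i] = e
        best_prev = best_cur
        if not best_prev:
            return []
    return sorted((i, e) for i, e in best_prev.items())


def _count_tracts(s: str, start: int, end: int, min_run: int) -> int:
    """Maximal G-runs of length >= min_run inside [start, end)."""
    n = 0
    run = 0
    for ch in s[start:end]:
        if ch == "G":
            run += 1
        else:
            if run >= min_run:
                n += 1
            run = 0
    if run >= min_run:
        n += 1
    return n


def _scan(
    seq: str,
    min_run: int,
    max_loop: int,
    max_run: Optional[int],
    pattern_id: str,
    strand: str = "+",
) -> list[MotifHit]:
    s = _check_alphabet(seq)
    spans = _match_spans(s, min_run, max_loop, max_run)
    if not spans:
        return []
    merged = merge_intervals([GenomicInterval("_", a, b) for a, b in spans])
    return [
        MotifHit(iv.start, iv.end, strand, pattern_id,
                 _count_tracts(s, iv.start, iv.end, min_run))
        for iv in merged
    ]


def scan_typical_pg4(sequence: str, min_run: int = 3, max_loop: int = 7) -> list[MotifHit]:
    """Merged typical-pG4 motif hits on the given strand of ``sequence``.

    Pattern: G-run (>= ``min_run``, unbounded above) followed by three
    repetitions of (loop of 1..``max_loop`` arbitrary bases, G-run).
    """
    if min_run < 1 or max_loop < 1:
        raise ValidationError("min_run and max_loop must be >= 1")
    return _scan(sequence, min_run, max_loop, None, "typical_pG4")


def scan_negative_filter(sequence: str) -> bool:
    """True iff either strand contains the G(3-5) N(1-7) x4 exclusion pattern.

    Used to EXCLUDE candidate negative regions whose sequence could still
    form a quadruplex.
    """
    s = _check_alphabet(sequence)
    for strand_seq in (s, reverse_complement(s)):
        if _match_spans(strand_seq, 3, 7, 5):
            return True
    return False


def scan_genome(
    genome: dict[str, str],
    pattern_id: str = "typical_pG4",
    min_run: int = 3,
    max_loop: int = 7,
) -> PeakSet:
    """Scan both strands of every chromosome for merged motif hits.

    ``genome`` maps chromosome name to sequence (use
    :func:`g4peakbench.io_fasta.load_fasta` for FASTA files). Reverse-strand
    hits are reported in forward coordinates with strand '-'.
    """
    if pattern_id != "typical_pG4":
        raise ValidationError(f"unknown pattern_id {pattern_id!r}")
    intervals: list[GenomicInterval] = []
    for chrom in sorted(genome):
        seq = str(genome[chrom])
        L = len(seq)
        for k, hit in enumerate(scan_typical_pg4(seq, min_run, max_loop)):
            intervals.append(
                GenomicInterval(chrom, hit.start, hit.end,
                                name=f"{pattern_id}_{chrom}_fwd_{k}",
                                score=float(hit.n_tracts), strand="+")
            )
        rc = reverse_complement(seq)
        for k, hit in enumerate(scan_typical_pg4(rc, min_run, max_loop)):
            intervals.append(
                GenomicInterval(chrom, L - hit.end, L - hit.start,
                                name=f"{pattern_id}_{chrom}_rev_{k}",
                                score=float(hit.n_tracts), strand="-")
            )
    if not intervals:
        import warnings

        warnings.warn("genome scan produced no motif hits")
    return PeakSet(intervals, label=pattern_id)
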