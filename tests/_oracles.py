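"""Independent brute-force oracles used to check the interval algebra,
motif scanner and tail probabilities. These deliberately avoid the package's
own code paths: coverage is computed with per-base boolean vectors, motif
matching with exhaustive anchored regex, and tail probabilities with direct
pmf summation."""

from __future__ import annotations

import math
import re

import numpy as np


def coverage_vector(intervals, chrom: str, length: int) -> np.ndarray:
    cov = np.zeros(length, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            cov[iv.start : iv.end] = True
    return cov


def depth_vector(peaksets, chrom: str, length: int) -> np.ndarray:
    depth = np.zeros(length, dtype=np.int64)
    for ps in peaksets:
        depth += coverage_vector(ps, chrom, length)
    return depth


def bf_intersect_bp(a, b, sizes: dict[str, int]) -> int:
    total = 0
    for chrom, L in sizes.items():
        total += int((coverage_vector(a, chrom, L) & coverage_vector(b, chrom, L)).sum())
    return total


def bf_count_overlapping(a, b, min_bp: int = 1) -> int:
    n = 0
    for iv in a:
        bp = 0
        covered = set()
        for other in b:
            if other.chrom != iv.chrom:
                continue
            lo, hi = max(iv.start, other.start), min(iv.end, other.end)
            covered.update(range(lo, hi))
        if len(covered) >= min_bp:
            n += 1
    return n


def runs_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, end) of maximal True runs."""
    out = []
    in_run = False
    start = 0
    for i, v in enumerate(mask):
        if v and not in_run:
            in_run, start = True, i
        elif not v and in_run:
            out.append((start, i))
            in_run = False
    if in_run:
        out.append((start, len(mask)))
    return out


def bf_motif_union(seq: str, min_run: int = 3, max_loop: int = 7,
                   max_run: int | None = None) -> list[tuple[int, int]]:
    """Union of ALL substrings matching the 4-tract pattern, as merged runs.

    Exhaustive: anchors a fullmatch at every (start, end) pair up to the
    longest possible match length.
    """
    run = f"{{{min_run},}}" if max_run is None else f"{{{min_run},{max_run}}}"
    pat = re.compile(f"G{run}(?:[ACGTN]{{1,{max_loop}}}G{run}){{3}}")
    L = len(seq)
    longest_g = max((len(m.group()) for m in re.finditer("G+", seq)), default=0)
    cap_run = longest_g if max_run is None else min(max_run, longest_g)
    max_len = 4 * cap_run + 3 * max_loop
    mask = np.zeros(L, dtype=bool)
    for i in range(L):
        for j in range(i + 4 * min_run + 3, min(L, i + max_len) + 1):
            if pat.fullmatch(seq, i, j):
                mask[i:j] = True
    return runs_from_mask(mask)


def poisson_sf_sum(x: int, lam: float) -> float:
    """P(X >= x) by direct pmf summation of the lower tail."""
    if x <= 0:
        return 1.0
    term = math.exp(-lam)
    total = [term]
    for k in range(1, x):
        term *= lam / k
        total.append(term)
    return 1.0 - math.fsum(total)


def binom_sf_sum(x: int, n: int, p: float) -> float:
    """P(X >= x) by direct pmf summation of the complementary lower tail
    (k = 0 .. x-1; at most x terms, so precision does not degrade with n)."""
    if x <= 0:
        return 1.0
    term = (1.0 - p) ** n  # pmf at k = 0
    terms = [term]
    for k in range(1, x):
        term *= (n - k + 1) / k * (p / (1.0 - p))
        terms.append(term)
    return 1.0 - math.fsum(terms)


def random_intervals(rng, n: int, length: int, chroms=("chrA", "chrB"),
                     max_width: int = 400, cls=None, with_pvalues: bool = False):
    from g4peakbench.intervals import GenomicInterval

    out = []
    for i in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, length - 2))
        width = int(rng.integers(1, max_width))
        end = min(length, start + width)
        pv = float(rng.random()) if with_pvalues else None
        out.append(GenomicInterval(chrom, start, end, name=f"iv{i}", pvalue=pv))
    return out
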