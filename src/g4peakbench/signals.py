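"""Per-base signal tracks and the replicate-consistency distance statistic.

The distance between two replicate coverage vectors taken from the same
1000-bp window is ``1 - Pearson correlation``, ranging from 0 (identical
fragment distribution) to 2 (perfect anti-correlation); windows where either
vector has zero variance are reported as missing rather than imputed.
Benchmark peaks are anchored to the nearest G4 motif midpoint before the
window is placed, and uniformly random in-bounds windows provide the null
control group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .benchmark import BenchmarkSet
from .intervals import GenomicInterval, PeakSet, ValidationError

__all__ = [
    "SignalTrack",
    "DistanceRecord",
    "WindowOutOfBounds",
    "read_track",
    "extract_window",
    "nearest_motif",
    "replicate_distance",
    "benchmark_distance_profile",
    "random_window_distances",
    "compare_groups_ranksum",
    "signal_over_peaks",
    "kruskal_groups",
]


class WindowOutOfBounds(ValueError):
    """A requested window does not fit inside its chromosome."""


class SignalTrack:
    """Dense per-base non-negative coverage, one array per chromosome."""

    def __init__(self, values: dict[str, np.ndarray], library_size: Optional[float] = None):
        self.values: dict[str, np.ndarray] = {}
        for chrom, arr in values.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.ndim != 1:
                raise ValidationError(f"{chrom}: track values must be 1-D")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValidationError(f"{chrom}: track values must be finite and >= 0")
            self.values[chrom] = arr
        self.library_size = float(library_size) if library_size is not None else float(
            sum(arr.sum() for arr in self.values.values())
        )
        self._cumsums: dict[str, np.ndarray] = {}

    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.values.items()}

    def genome_length(self) -> int:
        return sum(len(a) for a in self.values.values())

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.values.values()))

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of values over [start, end), O(1) via cached cumulative sums."""
        if chrom not in self.values:
            raise ValidationError(f"unknown chromosome {chrom!r}")
        if chrom not in self._cumsums:
            self._cumsums[chrom] = np.concatenate([[0.0], np.cumsum(self.values[chrom])])
        L = len(self.values[chrom])
        start, end = max(0, start), min(L, end)
        if start >= end:
            return 0.0
        cs = self._cumsums[chrom]
        return float(cs[end] - cs[start])


def read_track(path, sizes: dict[str, int], format: str = "bedGraph") -> SignalTrack:
    """Read a coverage track into dense per-base arrays (uncovered bases = 0).

    bedGraph records must be non-overlapping and within chromosome bounds.
    bigWig input requires the optional pyBigWig dependency.
    """
    values = {chrom: np.zeros(n, dtype=np.float64) for chrom, n in sizes.items()}
    if format == "bedGraph":
        df = pd.read_csv(
            path, sep=r"\s+", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": np.float64},
        ) if _nonempty(path) else pd.DataFrame(columns=["chrom", "start", "end", "value"])
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in values:
                raise ValidationError(f"{path}: chromosome {chrom!r} not in sizes table")
            sub = sub.sort_values(["start", "end"])
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if np.any(starts >= ends) or starts[0] < 0 or ends[-1] > len(values[chrom]):
                bad = sub[(starts >= ends)].head(1)
                raise ValidationError(f"{path}: record out of bounds or empty on {chrom} {bad}")
            if np.any(starts[1:] < ends[:-1]):
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise ValidationError(
                    f"{path}: overlapping bedGraph records on {chrom} near {starts[i + 1]}"
                )
            for s, e, v in zip(starts, ends, sub["value"].to_numpy()):
                values[chrom][s:e] = v
    elif format == "bigWig":
        try:
            import pyBigWig
        except ImportError as exc:  # pragma: no cover - optional feature
            raise ValidationError("bigWig support requires pyBigWig") from exc
        bw = pyBigWig.open(str(path))
        for chrom, n in sizes.items():
            if chrom in bw.chroms():
                arr = np.nan_to_num(np.asarray(bw.values(chrom, 0, min(n, bw.chroms()[chrom]))))
                values[chrom][: len(arr)] = arr
        bw.close()
    else:
        raise ValidationError(f"unknown track format {format!r}")
    return SignalTrack(values)


def _nonempty(path) -> bool:
    import os

    return os.path.getsize(path) > 0


def write_bedgraph(track: SignalTrack, path) -> None:
    """Write a track as run-length-compressed bedGraph (zero runs included)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            arr = track.values[chrom]
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            for s, e in zip(starts, ends):
                v = arr[s]
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def extract_window(track: SignalTrack, chrom: str, center: int, width: int = 1000) -> np.ndarray:
    """Exactly ``width`` per-base values centred on ``center``.

    The window is [center - width//2, center - width//2 + width); odd widths
    place the extra base on the right. Windows that do not fit inside the
    chromosome raise :class:`WindowOutOfBounds` (callers skip and record).
    """
    if chrom not in track.values:
        raise WindowOutOfBounds(f"unknown chromosome {chrom!r}")
    start = center - width // 2
    end = start + width
    if start < 0 or end > len(track.values[chrom]):
        raise WindowOutOfBounds(f"{chrom}:{start}-{end} outside chromosome")
    return track.values[chrom][start:end].copy()


def nearest_motif(peak: GenomicInterval, motifs: PeakSet) -> GenomicInterval:
    """Motif whose midpoint is closest to the peak midpoint (same chromosome);
    ties resolve to the leftmost motif."""
    candidates = [m for m in motifs if m.chrom == peak.chrom]
    if not candidates:
        raise ValidationError(f"no motif on chromosome {peak.chrom}")
    center = peak.midpoint
    return min(candidates, key=lambda m: (abs(m.midpoint - center), m.start, m.end))


def replicate_distance(vec1: np.ndarray, vec2: np.ndarray) -> Optional[float]:
    """1 - Pearson correlation of two equal-length signal vectors, in [0, 2].

    Returns None (missing) when either vector has zero variance, where the
    correlation is undefined.
    """
    v1 = np.asarray(vec1, dtype=np.float64)
    v2 = np.asarray(vec2, dtype=np.float64)
    if v1.shape != v2.shape:
        raise ValidationError(f"length mismatch: {v1.shape} vs {v2.shape}")
    if v1.size < 2:
        raise ValidationError("vectors must have length >= 2")
    if np.ptp(v1) == 0.0 or np.ptp(v2) == 0.0:
        return None
    r = np.corrcoef(v1, v2)[0, 1]
    return float(np.clip(1.0 - r, 0.0, 2.0))


@dataclass(frozen=True)
class DistanceRecord:
    anchor: GenomicInterval
    distance: Optional[float]
    source_peak: str


@dataclass
class SkipReport:
    out_of_bounds: int = 0
    zero_variance: int = 0
    no_motif: int = 0

    def total(self) -> int:
        return self.out_of_bounds + self.zero_variance + self.no_motif


def benchmark_distance_profile(
    benchmark,
    motifs: PeakSet,
    rep1: SignalTrack,
    rep2: SignalTrack,
    width: int = 1000,
) -> tuple[list[DistanceRecord], SkipReport]:
    """Replicate distance at the motif-anchored window of every benchmark peak.

    Each benchmark peak is attributed to the motif nearest its centre; the
    window of ``width`` bases is centred on the motif midpoint. Skipped
    anchors (no motif on the chromosome, window out of bounds, zero-variance
    signal) are tallied in the returned report.
    """
    peaks = benchmark.intervals if isinstance(benchmark, BenchmarkSet) else list(benchmark)
    records: list[DistanceRecord] = []
    skips = SkipReport()
    for i, peak in enumerate(peaks):
        source = peak.name or f"benchmark_{i + 1}"
        try:
            motif = nearest_motif(peak, motifs)
        except ValidationError:
            skips.no_motif += 1
            continue
        center = motif.midpoint
        try:
            v1 = extract_window(rep1, motif.chrom, center, width)
            v2 = extract_window(rep2, motif.chrom, center, width)
        except WindowOutOfBounds:
            skips.out_of_bounds += 1
            continue
        d = replicate_distance(v1, v2)
        if d is None:
            skips.zero_variance += 1
            continue
        anchor = GenomicInterval(
            motif.chrom, center - width // 2, center - width // 2 + width
        )
        records.append(DistanceRecord(anchor, d, source))
    return records, skips


def random_window_distances(
    rep1: SignalTrack,
    rep2: SignalTrack,
    n: int = 10_000,
    width: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, SkipReport]:
    """Replicate distances over ``n`` uniformly random in-bounds windows.

    Windows are drawn uniformly over all valid window start positions across
    chromosomes; zero-variance windows are skipped and tallied. Reproducible
    for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    sizes = rep1.chrom_sizes()
    chroms = [c for c in sorted(sizes) if sizes[c] >= width]
    if not chroms:
        raise ValidationError(f"no chromosome can host a {width}-bp window")
    n_positions = np.array([sizes[c] - width + 1 for c in chroms], dtype=np.float64)
    probs = n_positions / n_positions.sum()
    out = []
    skips = SkipReport()
    chosen = rng.choice(len(chroms), size=n, p=probs)
    for ci in chosen:
        chrom = chroms[ci]
        start = int(rng.integers(0, sizes[chrom] - width + 1))
        v1 = rep1.values[chrom][start : start + width]
        v2 = rep2.values[chrom][start : start + width]
        d = replicate_distance(v1, v2)
        if d is None:
            skips.zero_variance += 1
        else:
            out.append(d)
    return np.asarray(out), skips


def compare_groups_ranksum(
    a: Sequence[float], b: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U) comparison of two value groups.

    ``alternative='less'`` tests whether values in ``a`` are stochastically
    smaller than those in ``b``. Fully tied input yields p = 1 with a warning.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    alt = {"two_sided": "two-sided"}.get(alternative, alternative)
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0.0:
        warnings.warn("all values tied across groups; rank-sum test is degenerate")
        return float("nan"), 1.0
    res = stats.mannwhitneyu(a, b, alternative=alt)
    return float(res.statistic), float(res.pvalue)


def signal_over_peaks(
    track: SignalTrack, peaks: PeakSet, transform: str = "log1p",
    normalize_cpm: bool = False,
) -> tuple[np.ndarray, SkipReport]:
    """Mean signal per peak, log-transformed; one value per usable peak.

    ``transform`` is 'log1p' (natural log of 1 + mean) or 'log10p'
    (log10 of 1 + mean). With ``normalize_cpm`` the per-peak means are
    scaled to counts-per-million by the track's library size before the log
    transform. Peaks outside the track are skipped and tallied.
    """
    if transform not in ("log1p", "log10p"):
        raise ValidationError(f"unknown transform {transform!r}")
    sizes = track.chrom_sizes()
    vals = []
    skips = SkipReport()
    for iv in peaks:
        if iv.chrom not in sizes or iv.start < 0 or iv.end > sizes[iv.chrom]:
            skips.out_of_bounds += 1
            continue
        mean = track.window_sum(iv.chrom, iv.start, iv.end) / iv.width
        vals.append(mean)
    arr = np.asarray(vals, dtype=np.float64)
    if normalize_cpm:
        if not track.library_size:
            raise ValidationError("CPM normalization requires a positive library size")
        arr = arr * (1e6 / track.library_size)
    if transform == "log1p":
        arr = np.log1p(arr)
    else:
        arr = np.log10(1.0 + arr)
    return arr, skips


def kruskal_groups(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H test across >= 2 non-empty value groups."""
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(arr.size == 0 for arr in arrays):
        raise ValidationError("all groups must be non-empty")
    res = stats.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


def distance_table(records: list[DistanceRecord]) -> pd.DataFrame:
    rows = [
        {
            "chrom": r.anchor.chrom,
            "window_start": r.anchor.start,
            "window_end": r.anchor.end,
            "distance": r.distance,
            "source_peak": r.source_peak,
        }
        for r in records
    ]
    return pd.DataFrame(rows)
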