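"""Precision / recall / harmonic-mean scoring against a consensus benchmark.

The two sides of the score are deliberately asymmetric, following the
benchmark's definition: *precision* is base-pair-level (fraction of
algorithm-called bases that fall inside benchmark intervals), while *recall*
is peak-level (fraction of benchmark intervals touched by at least one
called base). A peak-level precision variant is available as a clearly
non-default switch for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .benchmark import BenchmarkSet
from .intervals import (
    PeakSet,
    ValidationError,
    count_overlapping,
    intersect_bp,
    select_top_n,
)

__all__ = [
    "EvalResult",
    "precision_bp",
    "precision_peaks",
    "recall_peaks",
    "hm_score",
    "hm_curve",
    "overlap_proportion",
    "false_positive_rate",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = (100, 1_000, 10_000, 100_000, 1_000_000)


@dataclass(frozen=True)
class EvalResult:
    precision: float
    recall: float
    hm: float
    n_peaks_evaluated: int


def _benchmark_intervals(benchmark) -> list:
    if isinstance(benchmark, BenchmarkSet):
        return list(benchmark.intervals)
    return list(benchmark)


def precision_bp(identified: PeakSet, benchmark) -> Optional[float]:
    """Fraction of identified bases (union) overlapping the benchmark.

    Returns None (explicit no-data marker) for an empty identified set.
    """
    if len(identified) == 0:
        return None
    bench = _benchmark_intervals(benchmark)
    total = identified.total_bp()
    return intersect_bp(identified, bench) / total


def precision_peaks(identified: PeakSet, benchmark) -> Optional[float]:
    """Non-default peak-level precision: fraction of identified intervals
    overlapping the benchmark by >= 1 bp."""
    if len(identified) == 0:
        return None
    bench = _benchmark_intervals(benchmark)
    return count_overlapping(identified, bench) / len(identified)


def recall_peaks(identified: PeakSet, benchmark) -> float:
    """Fraction of benchmark intervals overlapped (>= 1 bp) by identified peaks."""
    bench = _benchmark_intervals(benchmark)
    if not bench:
        raise ValidationError("benchmark is empty")
    return count_overlapping(bench, list(identified)) / len(bench)


def hm_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when either is 0)."""
    for v, nm in ((precision, "precision"), (recall, "recall")):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"{nm} {v} outside [0, 1]")
    if precision == 0.0 or recall == 0.0:
        return 0.0
    return 2.0 / (1.0 / precision + 1.0 / recall)


def evaluate(identified: PeakSet, benchmark, peak_level_precision: bool = False) -> EvalResult:
    prec_fn = precision_peaks if peak_level_precision else precision_bp
    p = prec_fn(identified, benchmark)
    if p is None:
        raise ValidationError("cannot evaluate an empty peak set")
    r = recall_peaks(identified, benchmark)
    return EvalResult(p, r, hm_score(p, r), len(identified))


def hm_curve(
    ranked: PeakSet,
    benchmark,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    peak_level_precision: bool = False,
) -> list[tuple[int, EvalResult]]:
    """Precision/recall/HM at each top-N threshold of a ranked peak set.

    Thresholds exceeding the number of available peaks evaluate the full set
    (the curve flattens/truncates, as for callers with short output lists).
    """
    thresholds = list(thresholds)
    if any(t <= 0 for t in thresholds) or sorted(thresholds) != thresholds:
        raise ValidationError("thresholds must be positive and increasing")
    out = []
    for t in thresholds:
        subset = select_top_n(ranked, t)
        out.append((t, evaluate(subset, benchmark, peak_level_precision)))
    return out


def hm_curve_table(curves: dict[str, list[tuple[int, EvalResult]]]) -> pd.DataFrame:
    """Tidy table of HM curves keyed by algorithm label."""
    rows = []
    for label, curve in curves.items():
        for t, res in curve:
            rows.append(
                {
                    "algorithm": label,
                    "threshold": t,
                    "n_evaluated": res.n_peaks_evaluated,
                    "precision": res.precision,
                    "recall": res.recall,
                    "hm": res.hm,
                }
            )
    return pd.DataFrame(rows)


def overlap_proportion(peaks: PeakSet, reference: PeakSet, min_bp: int = 1) -> Optional[float]:
    """Fraction of ``peaks`` overlapping the reference set by >= ``min_bp``.

    Returns None for an empty peak set (no-data marker).
    """
    if len(peaks) == 0:
        return None
    return count_overlapping(peaks, list(reference), min_bp) / len(peaks)


def false_positive_rate(tp: int, fp: int) -> Optional[float]:
    """FP / (TP + FP); None when no calls were made at the threshold."""
    if tp < 0 or fp < 0:
        raise ValidationError("counts must be non-negative")
    if tp + fp == 0:
        return None
    return fp / (tp + fp)
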