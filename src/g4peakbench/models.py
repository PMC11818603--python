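"""Fragment-distribution models for peak significance and their FPR comparison.

Three hypothesis-testing kernels used by published peak callers are
implemented on upper-tail (enrichment-only) p-values:

* plain Poisson — X ~ Pois(lambda) with lambda the control fragment count at
  the same site (the SICER/HOMER kernel);
* dynamic Poisson — lambda_dynamic = max(b, lambda_1k, ..., lambda_1000k,
  lambda_all), the maximum of the site-level control count and control rates
  over centred windows of increasing span, rescaled to the candidate-region
  width (the MACS2 kernel);
* binomial — X ~ B(n, p) with n the depth-scaled control fragment total and
  p the mean control count over all candidate regions divided by n (the
  GoPeaks/PeakRanger kernel).

A to-be-tested dataset couples benchmark peaks (positives) with filtered,
motif-free candidate regions (negatives); false-positive-rate curves over a
p-value grid compare the three models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .benchmark import BenchmarkSet
from .intervals import (
    GenomicInterval,
    PeakSet,
    ValidationError,
    overlap_bp_per_interval,
)
from .metrics import false_positive_rate
from .motifs import scan_negative_filter
from .signals import SignalTrack

__all__ = [
    "RegionCounts",
    "DynamicLambda",
    "TBTDataset",
    "FPRCurve",
    "count_fragments",
    "poisson_pvalue",
    "dynamic_lambda",
    "dynamic_poisson_pvalue",
    "binomial_params",
    "binomial_pvalue",
    "build_tbt_dataset",
    "evaluate_models",
    "DEFAULT_SCALES_KB",
    "DEFAULT_PVALUE_GRID",
    "MIN_LAMBDA",
]

DEFAULT_SCALES_KB = (1, 5, 10, 50, 100, 500, 1000)
DEFAULT_PVALUE_GRID = (1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 0.5, 1.0)
MIN_LAMBDA = 1e-6  # floor for degenerate zero-control regions


@dataclass(frozen=True)
class RegionCounts:
    region: GenomicInterval
    treat_count: int
    ctrl_count: int

    def __post_init__(self):
        if self.treat_count < 0 or self.ctrl_count < 0:
            raise ValidationError("fragment counts must be non-negative")


@dataclass(frozen=True)
class DynamicLambda:
    """Components of the dynamic background rate for one candidate region."""

    lambda_region: float
    lambda_by_scale: dict[int, float]  # keyed by window span in kb
    lambda_all: float

    @property
    def lambda_dynamic(self) -> float:
        return max(self.lambda_region, self.lambda_all, *self.lambda_by_scale.values())


@dataclass
class TBTDataset:
    """Labeled positive/negative intervals for hypothesis-model evaluation."""

    positives: list[GenomicInterval]
    negatives: list[GenomicInterval]
    seed: int

    def __post_init__(self):
        ov = overlap_bp_per_interval(self.negatives, self.positives)
        if len(ov) and ov.max() > 0:
            raise ValidationError("negatives overlap positives")


@dataclass
class FPRCurve:
    model_id: str
    points: list[tuple[float, Optional[float], int]]  # (threshold, fpr, n_calls)

    def as_dict(self) -> dict[float, Optional[float]]:
        return {t: f for t, f, _ in self.points}


def count_fragments(source, region: GenomicInterval) -> int:
    """Fragments overlapping a region.

    ``source`` may be a :class:`SignalTrack` of per-base fragment counts (the
    rounded sum over the region) or an iterable of fragment intervals
    (any-overlap counting).
    """
    if isinstance(source, SignalTrack):
        sizes = source.chrom_sizes()
        if region.chrom not in sizes or region.start < 0 or region.end > sizes[region.chrom]:
            raise ValidationError(f"region {region} outside track bounds")
        return int(round(source.window_sum(region.chrom, region.start, region.end)))
    n = 0
    for frag in source:
        if frag.overlaps(region):
            n += 1
    return n


def poisson_pvalue(x, lam) -> float:
    """Upper-tail P(X >= x) under Poisson(lam)."""
    x = np.asarray(x)
    lam_arr = np.asarray(lam, dtype=np.float64)
    if np.any(x < 0):
        raise ValidationError("x must be >= 0")
    if np.any(lam_arr <= 0):
        raise ValidationError("lambda must be > 0")
    p = stats.poisson.sf(x - 1, lam_arr)
    return float(p) if p.ndim == 0 else p


def dynamic_lambda(
    ctrl: SignalTrack,
    region: GenomicInterval,
    scales_kb: Sequence[int] = DEFAULT_SCALES_KB,
    mode: str = "centered",
) -> DynamicLambda:
    """Dynamic background rate components for one candidate region.

    For each scale ``s`` a window of total span ``s`` kb is placed around the
    region midpoint ('centered' mode; 'flanks' excludes the region itself)
    and clipped at chromosome ends; the control fragment count in the window
    is rescaled to the region width. The genome-wide rate lambda_all is
    rescaled likewise. The dynamic rate is the maximum of the region-level
    control count and all window/global rates.
    """
    if mode not in ("centered", "flanks"):
        raise ValidationError(f"unknown mode {mode!r}")
    sizes = ctrl.chrom_sizes()
    if region.chrom not in sizes:
        raise ValidationError(f"unknown chromosome {region.chrom}")
    L = sizes[region.chrom]
    width = region.width
    b = float(count_fragments(ctrl, region))
    mid = region.midpoint
    by_scale: dict[int, float] = {}
    for s in scales_kb:
        span = int(s) * 1000
        start = max(0, mid - span // 2)
        end = min(L, start + span)
        start = max(0, end - span)  # keep full span where possible
        win = ctrl.window_sum(region.chrom, start, end)
        win_width = end - start
        if mode == "flanks":
            inner = ctrl.window_sum(region.chrom, max(start, region.start), min(end, region.end))
            inner_w = max(0, min(end, region.end) - max(start, region.start))
            win -= inner
            win_width -= inner_w
        if win_width <= 0:
            continue
        by_scale[int(s)] = win / win_width * width
    lam_all = ctrl.total() / ctrl.genome_length() * width
    return DynamicLambda(b, by_scale, lam_all)


def dynamic_poisson_pvalue(x: int, dl: DynamicLambda) -> float:
    lam = max(dl.lambda_dynamic, MIN_LAMBDA)
    return poisson_pvalue(x, lam)


def binomial_params(
    ctrl_total: int, candidate_regions: Sequence[RegionCounts], depth_ratio: float = 1.0
) -> tuple[int, float]:
    """(n, p) of the binomial kernel from control totals and candidate counts.

    n is the depth-scaled control fragment total; p is the mean control
    count over candidate regions divided by n, so n*p is invariant to the
    depth scaling.
    """
    if ctrl_total <= 0:
        raise ValidationError("ctrl_total must be > 0")
    if not candidate_regions:
        raise ValidationError("candidate_regions must be non-empty")
    if depth_ratio <= 0:
        raise ValidationError("depth_ratio must be > 0")
    n = int(round(ctrl_total * depth_ratio))
    mean_ctrl = float(np.mean([rc.ctrl_count for rc in candidate_regions]))
    p = mean_ctrl / n
    if p >= 1.0:
        raise ValidationError(f"binomial p = {p} >= 1 (library too small)")
    if p <= 0.0:
        raise ValidationError("binomial p = 0 (no control fragments in candidate regions)")
    return n, p


def binomial_pvalue(x, n: int, p: float) -> float:
    """Upper-tail P(X >= x) under Binomial(n, p)."""
    x_arr = np.asarray(x)
    if np.any(x_arr < 0) or np.any(x_arr > n):
        raise ValidationError("require 0 <= x <= n")
    if not (0.0 < p < 1.0):
        raise ValidationError("require 0 < p < 1")
    out = stats.binom.sf(x_arr - 1, n, p)
    return float(out) if out.ndim == 0 else out


def build_tbt_dataset(
    candidate_pool: PeakSet,
    benchmark,
    genome: dict[str, str],
    exclusion_beds: Sequence[PeakSet] = (),
    n_neg: int = 10_000,
    seed: int = 0,
) -> TBTDataset:
    """Construct the to-be-tested dataset: benchmark positives + filtered negatives.

    Candidate intervals are excluded from the negative pool when they overlap
    (>= 1 bp) the benchmark or any exclusion set, or when their genomic
    sequence on either strand matches the G(3-5) N(1-7) x4 quadruplex
    pattern. ``n_neg`` negatives are sampled uniformly without replacement;
    if the filtered pool is smaller, the whole pool is used with a warning.
    """
    if len(candidate_pool) == 0:
        raise ValidationError("candidate pool is empty")
    positives = list(benchmark.intervals if isinstance(benchmark, BenchmarkSet) else benchmark)
    pool = list(candidate_pool)
    excl = list(positives)
    for ps in exclusion_beds:
        excl.extend(ps)
    ov = overlap_bp_per_interval(pool, excl)
    pool = [iv for iv, o in zip(pool, ov) if o == 0]
    survivors = []
    for iv in pool:
        seq = genome[iv.chrom][iv.start : iv.end]
        if not scan_negative_filter(seq):
            survivors.append(iv)
    rng = np.random.default_rng(seed)
    if len(survivors) <= n_neg:
        if len(survivors) < n_neg:
            warnings.warn(
                f"filtered negative pool ({len(survivors)}) smaller than requested "
                f"{n_neg}; using the whole pool"
            )
        negatives = survivors
    else:
        idx = rng.choice(len(survivors), size=n_neg, replace=False)
        negatives = [survivors[i] for i in sorted(idx)]
    negatives = sorted(negatives, key=GenomicInterval.sort_key)
    return TBTDataset(positives=positives, negatives=negatives, seed=seed)


def region_pvalues(
    tbt: TBTDataset,
    treat: SignalTrack,
    ctrl: SignalTrack,
    models: Sequence[str] = ("poisson", "dynamic_poisson", "binomial"),
    scales_kb: Sequence[int] = DEFAULT_SCALES_KB,
) -> pd.DataFrame:
    """Per-region fragment counts, lambda components and model p-values."""
    known = {"poisson", "dynamic_poisson", "binomial"}
    bad = set(models) - known
    if bad:
        raise ValidationError(f"unknown model(s) {sorted(bad)}")
    regions = [(iv, True) for iv in tbt.positives] + [(iv, False) for iv in tbt.negatives]
    lam_all_rate = ctrl.total() / ctrl.genome_length()
    rows = []
    for iv, is_pos in regions:
        x = count_fragments(treat, iv)
        c = count_fragments(ctrl, iv)
        rows.append({
            "chrom": iv.chrom, "start": iv.start, "end": iv.end,
            "label": "positive" if is_pos else "negative",
            "treat_count": x, "ctrl_count": c,
        })
    df = pd.DataFrame(rows)
    x = df["treat_count"].to_numpy()
    if "poisson" in models:
        lam = df["ctrl_count"].to_numpy(dtype=np.float64)
        widths = (df["end"] - df["start"]).to_numpy()
        fallback = np.maximum(lam_all_rate * widths, MIN_LAMBDA)
        lam = np.where(lam > 0, lam, fallback)
        df["lambda_poisson"] = lam
        df["p_poisson"] = stats.poisson.sf(x - 1, lam)
    if "dynamic_poisson" in models:
        lam_dyn = np.empty(len(df))
        for i, (iv, _) in enumerate(regions):
            dl = dynamic_lambda(ctrl, iv, scales_kb)
            lam_dyn[i] = max(dl.lambda_dynamic, MIN_LAMBDA)
        df["lambda_dynamic"] = lam_dyn
        df["p_dynamic_poisson"] = stats.poisson.sf(x - 1, lam_dyn)
    if "binomial" in models:
        ctrl_total = int(round(ctrl.total()))
        depth_ratio = treat.library_size / ctrl.library_size
        rcs = [RegionCounts(iv, int(tx), int(cx))
               for (iv, _), tx, cx in zip(regions, df["treat_count"], df["ctrl_count"])]
        n, p = binomial_params(ctrl_total, rcs, depth_ratio)
        x_clip = np.minimum(x, n)
        df["p_binomial"] = stats.binom.sf(x_clip - 1, n, p)
    return df


def evaluate_models(
    tbt: TBTDataset,
    treat: SignalTrack,
    ctrl: SignalTrack,
    thresholds: Sequence[float] = DEFAULT_PVALUE_GRID,
    models: Sequence[str] = ("poisson", "dynamic_poisson", "binomial"),
    scales_kb: Sequence[int] = DEFAULT_SCALES_KB,
) -> tuple[list[FPRCurve], pd.DataFrame]:
    """False-positive-rate curves of each model over a p-value threshold grid.

    At each threshold every to-be-tested region with p <= threshold is
    called; TP are called positives, FP called negatives, and
    FPR = FP / (TP + FP). Thresholds with zero calls yield a missing point.
    Returns the curves and the per-region p-value table.
    """
    thresholds = list(thresholds)
    if sorted(thresholds) != thresholds or len(set(thresholds)) != len(thresholds):
        raise ValidationError("thresholds must be strictly increasing")
    df = region_pvalues(tbt, treat, ctrl, models=models, scales_kb=scales_kb)
    is_pos = (df["label"] == "positive").to_numpy()
    curves = []
    for model in models:
        pvals = df[f"p_{model}"].to_numpy()
        points = []
        for t in thresholds:
            called = pvals <= t
            tp = int(np.sum(called & is_pos))
            fp = int(np.sum(called & ~is_pos))
            points.append((t, false_positive_rate(tp, fp), tp + fp))
        curves.append(FPRCurve(model, points))
    return curves, df
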