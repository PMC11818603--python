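import math

import numpy as np
import pytest

from g4peakbench.benchmark import build_consensus
from g4peakbench.intervals import GenomicInterval, PeakSet, ValidationError
from g4peakbench.models import (
    DynamicLambda,
    RegionCounts,
    binomial_params,
    binomial_pvalue,
    build_tbt_dataset,
    count_fragments,
    dynamic_lambda,
    dynamic_poisson_pvalue,
    evaluate_models,
    poisson_pvalue,
)
from g4peakbench.signals import SignalTrack

from _oracles import binom_sf_sum, poisson_sf_sum


def track(arr, chrom="chr1"):
    return SignalTrack({chrom: np.asarray(arr, dtype=float)})


class TestCountFragments:
    def test_track_sum(self):
        arr = np.zeros(100)
        arr[10:20] = 2.0
        t = track(arr)
        assert count_fragments(t, GenomicInterval("chr1", 5, 15)) == 10

    def test_fragment_list_any_overlap(self):
        frags = [
            GenomicInterval("chr1", 0, 50),
            GenomicInterval("chr1", 95, 105),  # straddles the boundary: counted
            GenomicInterval("chr1", 200, 250),
        ]
        region = GenomicInterval("chr1", 40, 100)
        assert count_fragments(frags, region) == 2

    def test_out_of_bounds_region(self):
        t = track(np.zeros(50))
        with pytest.raises(ValidationError):
            count_fragments(t, GenomicInterval("chr1", 40, 60))

    def test_brute_force_agreement(self, rng):
        frags = [
            GenomicInterval("chr1", int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 5_000, 300), rng.integers(1, 200, 300))
        ]
        for _ in range(50):
            s = int(rng.integers(0, 4_000))
            region = GenomicInterval("chr1", s, s + int(rng.integers(1, 500)))
            expected = sum(
                1 for f in frags if f.start < region.end and region.start < f.end
            )
            assert count_fragments(frags, region) == expected


class TestPoissonPvalue:
    def test_x_zero_is_one(self):
        assert poisson_pvalue(0, 5.0) == 1.0

    def test_known_value_lam_one(self):
        assert poisson_pvalue(5, 1.0) == pytest.approx(0.00365984, abs=1e-8)

    def test_upper_tail_at_mean(self):
        assert poisson_pvalue(20, 20.0) == pytest.approx(0.5297, abs=5e-4)

    def test_invalid_lambda(self):
        with pytest.raises(ValidationError):
            poisson_pvalue(3, 0.0)

    def test_pmf_summation_oracle(self, rng):
        for _ in range(100):
            x = int(rng.integers(0, 51))
            lam = float(rng.uniform(0.01, 40.0))
            assert poisson_pvalue(x, lam) == pytest.approx(
                poisson_sf_sum(x, lam), abs=1e-12
            )

    def test_monotone_in_x_and_lambda(self):
        lam = 4.0
        ps = [poisson_pvalue(x, lam) for x in range(30)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        x = 7
        ps = [poisson_pvalue(x, lam) for lam in np.linspace(0.5, 20, 40)]
        assert all(a <= b for a, b in zip(ps, ps[1:]))


class TestDynamicLambda:
    def test_max_of_components(self):
        dl = DynamicLambda(1.0, {1: 2.0, 5: 3.0, 10: 2.5}, 0.5)
        assert dl.lambda_dynamic == 3.0

    def test_homogeneous_control(self):
        t = track(np.full(200_000, 2.0))
        region = GenomicInterval("chr1", 100_000, 100_100)
        dl = dynamic_lambda(t, region, scales_kb=[1, 5, 10])
        expected = 2.0 * region.width
        assert dl.lambda_all == pytest.approx(expected)
        for lam in dl.lambda_by_scale.values():
            assert lam == pytest.approx(expected)
        assert dl.lambda_dynamic == pytest.approx(expected)

    def test_hot_local_background_dominates(self):
        arr = np.full(200_000, 1.0)
        arr[97_500:102_500] = 5.0  # 5 kb hot region around the candidate
        t = track(arr)
        region = GenomicInterval("chr1", 99_950, 100_050)  # width 100
        dl = dynamic_lambda(t, region, scales_kb=[1, 5, 100])
        assert dl.lambda_by_scale[1] == pytest.approx(500.0)  # fully hot window
        assert dl.lambda_by_scale[5] == pytest.approx(500.0)
        # 100 kb window: 5 kb hot of 100 kb
        assert dl.lambda_by_scale[100] == pytest.approx((95_000 + 5_000 * 5) / 100_000 * 100)
        assert dl.lambda_dynamic == pytest.approx(500.0)

    def test_window_clipping_at_chromosome_edge(self):
        t = track(np.full(2_000, 1.0))
        region = GenomicInterval("chr1", 0, 100)
        dl = dynamic_lambda(t, region, scales_kb=[1])
        # the 1 kb window is shifted to stay in bounds, rate unchanged
        assert dl.lambda_by_scale[1] == pytest.approx(100.0)

    def test_dynamic_poisson_reduces_to_plain_when_homogeneous(self):
        t = track(np.full(100_000, 1.5))
        region = GenomicInterval("chr1", 50_000, 50_200)
        dl = dynamic_lambda(t, region)
        x = 400
        # region-level control count is a Poisson draw... here the track is
        # deterministic, so every component equals the plain lambda
        assert dynamic_poisson_pvalue(x, dl) == pytest.approx(
            poisson_pvalue(x, 1.5 * region.width)
        )

    def test_dynamic_more_conservative(self, rng):
        """p_dynamic >= p_plain whenever lambda_dynamic >= lambda (same x)."""
        for _ in range(50):
            lam = float(rng.uniform(0.5, 10))
            extra = float(rng.uniform(0, 10))
            x = int(rng.integers(0, 30))
            dl = DynamicLambda(lam, {1: lam + extra}, lam / 2)
            assert dynamic_poisson_pvalue(x, dl) >= poisson_pvalue(x, lam) - 1e-15


class TestBinomial:
    def test_params_direct_arithmetic(self):
        regions = [
            RegionCounts(GenomicInterval("chr1", i * 100, i * 100 + 50), 0, 5)
            for i in range(4)
        ]
        n, p = binomial_params(10_000, regions, depth_ratio=1.0)
        assert n == 10_000
        assert p == pytest.approx(5e-4)

    def test_depth_scaling_identity(self):
        regions = [RegionCounts(GenomicInterval("chr1", 0, 50), 0, 5)]
        n1, p1 = binomial_params(10_000, regions, depth_ratio=1.0)
        n2, p2 = binomial_params(10_000, regions, depth_ratio=2.0)
        assert n2 == 2 * n1
        assert p2 == pytest.approx(p1 / 2)
        assert n1 * p1 == pytest.approx(n2 * p2)

    def test_degenerate_p_rejected(self):
        regions = [RegionCounts(GenomicInterval("chr1", 0, 50), 0, 5)]
        with pytest.raises(ValidationError):
            binomial_params(2, regions)

    def test_pvalue_x_zero(self):
        assert binomial_pvalue(0, 10, 0.5) == 1.0

    def test_pvalue_all_successes(self):
        assert binomial_pvalue(10, 10, 0.5) == pytest.approx(2**-10)

    def test_x_beyond_n_rejected(self):
        with pytest.raises(ValidationError):
            binomial_pvalue(11, 10, 0.5)

    def test_pmf_summation_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 1001))
            x = int(rng.integers(0, min(n, 50) + 1))
            p = float(rng.uniform(0.001, 0.5))
            assert binomial_pvalue(x, n, p) == pytest.approx(
                binom_sf_sum(x, n, p), abs=1e-12
            )

    def test_poisson_limit(self):
        """B(n, p) upper tail approaches Pois(np) for large n, small p."""
        n, p, x = 100_000, 1e-4, 25
        b = binomial_pvalue(x, n, p)
        po = poisson_pvalue(x, n * p)
        assert b == pytest.approx(po, rel=0.01)


class TestTBTDataset:
    def _pool_and_bench(self):
        bench = PeakSet([GenomicInterval("chr1", 1_000, 1_300)])
        pool = PeakSet(
            [
                GenomicInterval("chr1", 1_299, 1_400),  # 1 bp overlap -> excluded
                GenomicInterval("chr1", 2_000, 2_015),  # motif sequence -> excluded
                GenomicInterval("chr1", 3_000, 3_100),  # survivor
                GenomicInterval("chr1", 4_000, 4_100),  # survivor
            ],
            label="pool",
        )
        seq = ["A"] * 5_000
        seq[2_000:2_015] = list("GGGTGGGTGGGTGGG")
        genome = {"chr1": "".join(seq)}
        return pool, bench, genome

    def test_filters_applied(self):
        pool, bench, genome = self._pool_and_bench()
        with pytest.warns(UserWarning, match="smaller than requested"):
            tbt = build_tbt_dataset(pool, bench, genome, n_neg=10, seed=1)
        starts = sorted(iv.start for iv in tbt.negatives)
        assert starts == [3_000, 4_000]

    def test_exclusion_bed(self):
        pool, bench, genome = self._pool_and_bench()
        excl = PeakSet([GenomicInterval("chr1", 3_050, 3_060)])
        with pytest.warns(UserWarning):
            tbt = build_tbt_dataset(pool, bench, genome, [excl], n_neg=10, seed=1)
        assert [iv.start for iv in tbt.negatives] == [4_000]

    def test_sampling_reproducible(self, rng):
        genome = {"chr1": "A" * 100_000}
        pool = PeakSet(
            [
                GenomicInterval("chr1", int(s), int(s) + 50)
                for s in rng.integers(0, 99_000, size=500)
            ]
        )
        bench = PeakSet([GenomicInterval("chr1", 99_900, 99_950)])
        t1 = build_tbt_dataset(pool, bench, genome, n_neg=100, seed=9)
        t2 = build_tbt_dataset(pool, bench, genome, n_neg=100, seed=9)
        assert t1.negatives == t2.negatives
        assert len(t1.negatives) == 100


class TestEvaluateModels:
    def test_threshold_one_calls_everything(self, default_sim):
        sim, tracks, peaksets = default_sim
        bench = build_consensus(peaksets, top_n=10_000)
        pool = PeakSet([iv for ps in peaksets for iv in ps], label="pool")
        with pytest.warns(UserWarning):
            tbt = build_tbt_dataset(pool, bench, sim.sequences, n_neg=10_000, seed=1)
        curves, table = evaluate_models(tbt, tracks.rep1, tracks.control)
        n_pos, n_neg = len(tbt.positives), len(tbt.negatives)
        for curve in curves:
            t, fpr, n_calls = curve.points[-1]
            assert t == 1.0
            assert n_calls == n_pos + n_neg
            assert fpr == pytest.approx(n_neg / (n_pos + n_neg))

    def test_dynamic_at_or_below_plain_at_stringent_thresholds(self, default_sim):
        sim, tracks, peaksets = default_sim
        bench = build_consensus(peaksets, top_n=10_000)
        pool = PeakSet([iv for ps in peaksets for iv in ps], label="pool")
        with pytest.warns(UserWarning):
            tbt = build_tbt_dataset(pool, bench, sim.sequences, n_neg=10_000, seed=1)
        curves, _ = evaluate_models(tbt, tracks.rep1, tracks.control)
        by_model = {c.model_id: c.as_dict() for c in curves}
        for t in (1e-6, 1e-5, 1e-4, 1e-3):
            assert by_model["dynamic_poisson"][t] <= by_model["poisson"][t] + 1e-12
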