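# g4peakbench

A benchmarking framework for **peak calling on intracellular G-quadruplex (G4)
sequencing data** (BG4/G4P ChIP-seq and CUT&Tag). G4s form at guanine-rich
motifs and produce much narrower enrichment signals than histone marks or
transcription-factor binding, so peak callers developed for those assays
behave very differently on G4 data. This package implements the full
evaluation machinery a methods study of such callers needs, with a
synthetic-data generator standing in for real sequencing datasets so that
every analysis is reproducible from a seed on a laptop:

* **Consensus benchmark construction** — each caller's candidate peaks are
  ranked by significance, cut to the top 10,000, and every base supported by
  a strict majority (> k/2 of k algorithms) enters the benchmark.
* **Replicate-distance validation** — each benchmark peak is anchored to the
  nearest G4 motif and the signal vectors of two treatment replicates in a
  1000-bp window are compared with

  `distance = 1 − r(signal_rep1, signal_rep2)` (Pearson r; range 0–2),

  against 10,000 uniformly random windows as the null group
  (Wilcoxon rank-sum).
* **Precision / recall / HM scoring** — precision is the fraction of called
  *base pairs* inside the benchmark; recall is the fraction of benchmark
  *intervals* overlapped; HM = 2 / (1/precision + 1/recall), evaluated along
  a top-N threshold grid {10², …, 10⁶}.
* **Motif validation** — a two-strand scanner for the typical pG4 motif
  G≥3 N1–7 G≥3 N1–7 G≥3 N1–7 G≥3, plus the stricter G3–5 exclusion pattern
  used to purge candidate negative regions.
* **Hypothesis-model comparison** — the three fragment-distribution kernels
  used by published callers, on upper-tail p-values:
  plain Poisson (X ~ Pois(λ), λ = control count at the site), dynamic
  Poisson (λ_dyn = max(b, λ₁ₖ, λ₅ₖ, λ₁₀ₖ, λ₅₀ₖ, λ₁₀₀ₖ, λ₅₀₀ₖ, λ₁₀₀₀ₖ, λ_all))
  and binomial (X ~ B(n, p) with depth-scaled control total n and global
  candidate-region rate p), compared by false positive rate
  FPR = FP / (TP + FP) over a p-value threshold grid on a labeled
  positive/negative ("to-be-tested") dataset.

Coordinates are 0-based half-open (BED convention) throughout, and
chromosome names are matched by exact string equality (no "chr" aliasing).

## Worked example

```python
from g4peakbench import (SimConfig, generate_genome, generate_tracks, generate_peaksets,
                         build_consensus, hm_curve, scan_genome,
                         benchmark_distance_profile, random_window_distances,
                         compare_groups_ranksum, build_tbt_dataset, evaluate_models, PeakSet)
import numpy as np

cfg = SimConfig(seed=1)                       # 1 Mb, 200 true G4 peaks
sim = generate_genome(cfg)                    # genome + implanted motifs
tracks = generate_tracks(sim)                 # control, treatment rep1/rep2
callers = generate_peaksets(sim.peaks, cfg)   # five simulated peak callers

bench = build_consensus(callers, top_n=10_000)
for t, res in hm_curve(callers[0], bench, thresholds=[100, 200, 1000]):
    print(f"top {t:>5}: precision={res.precision:.3f} recall={res.recall:.3f} HM={res.hm:.3f}")

motifs = scan_genome(sim.sequences)
records, _ = benchmark_distance_profile(bench, motifs, tracks.rep1, tracks.rep2)
d = np.array([r.distance for r in records])
rand, _ = random_window_distances(tracks.rep1, tracks.rep2, n=10_000, seed=1)
_, p = compare_groups_ranksum(d, rand, alternative="less")
print(f"distance: benchmark mean={d.mean():.3f}, random mean={rand.mean():.3f}, p={p:.2e}")

pool = PeakSet([iv for ps in callers for iv in ps], label="pool")
tbt = build_tbt_dataset(pool, bench, sim.sequences, n_neg=10_000, seed=1)
curves, _ = evaluate_models(tbt, tracks.rep1, tracks.control)
for c in curves:
    fpr = c.as_dict()
    print(f"{c.model_id:>15}: FPR@1e-3={fpr[1e-3]:.4f}  FPR@0.1={fpr[0.1]:.4f}")
```

prints

```
top   100: precision=0.837 recall=0.500 HM=0.626
top   200: precision=0.769 recall=0.905 HM=0.832
top  1000: precision=0.767 recall=0.905 HM=0.830
distance: benchmark mean=0.271, random mean=0.830, p=5.13e-80
        poisson: FPR@1e-3=0.0051  FPR@0.1=0.0476
dynamic_poisson: FPR@1e-3=0.0000  FPR@0.1=0.0000
       binomial: FPR@1e-3=0.0000  FPR@0.1=0.0000
```

Reading the output: the consensus benchmark recovers the 200 implanted loci;
the HM curve peaks once the top-N threshold reaches the benchmark size
(recall saturates at 0.905 because the evaluated caller misses ~10% of true
peaks by construction) and precision decays slowly as lower-ranked false
calls enter. Benchmark-anchored replicate distances (mean 0.27) sit far
below random windows (mean 0.83 — near 1, i.e. uncorrelated), confirming
the benchmark marks reproducible signal. On regions with a regionally
elevated control background, the plain Poisson kernel — whose per-site λ is
a single noisy control count — produces the highest false positive rate at
every threshold, while the max-window dynamic λ and the global binomial
rate stay conservative: the mechanism behind the relative performance of
callers built on each kernel.

## Command-line pipeline

The same stages are scriptable via the `g4peakbench` command
(`simulate`, `benchmark`, `evaluate`, `models`); every subcommand writes a
`manifest.json` with parameters, seeds and SHA-256 digests of its outputs,
and identical seeds give byte-identical BED/TSV/bedGraph output:

```
g4peakbench simulate  --out-dir sim --seed 7
g4peakbench benchmark --peaks sim/sim_caller_1.narrowPeak ... --out-dir bench
g4peakbench evaluate  --benchmark bench/benchmark.bed --peaks ... \
    --rep1 sim/treat_rep1.bedGraph --rep2 sim/treat_rep2.bedGraph \
    --sizes sim/genome.sizes --motifs sim/truth_motifs.bed --out-dir eval
g4peakbench models    --benchmark bench/benchmark.bed --pool ... \
    --fasta sim/genome.fa --treat sim/treat_rep1.bedGraph \
    --ctrl sim/control.bedGraph --sizes sim/genome.sizes --out-dir models
```

External peak sets (BED / narrowPeak), coverage tracks (bedGraph, optionally
bigWig) and reference G4 interval sets (e.g. pqsfinder or G4Hunter output as
BED) plug into the same commands in place of the simulated files.

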