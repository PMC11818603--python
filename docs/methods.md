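# Methods

This note documents the statistical procedures implemented in `g4peakbench`,
the choices made where a procedure admits more than one reading, and what the
synthetic-data generator does and does not emulate.

## Interval conventions

All coordinates are 0-based, half-open; an interval's width is `end − start`.
Chromosome names are compared by exact string equality. Significance ranking
is ascending by p-value; FDR columns supplied in place of p-values are
treated identically. Ties in significance are broken by genomic order
(chrom, start, end) so that top-N cuts are deterministic. A p-value of
exactly 0 (emitted by some callers) sorts before any positive value and is
serialized to narrowPeak as a −log10(p) cap of 500.

## Consensus benchmark

Each of k ranked peak sets is cut to its top-N (default 10,000) most
significant intervals; overlaps within one set are merged so a set votes at
most once per base. The benchmark is the set of maximal base runs whose vote
depth strictly exceeds k/2 (so 3-of-5 passes and 2-of-4 fails), each
carrying the maximum depth inside the run as its support. Voting at base
resolution is the only formulation that is order-independent and requires no
cross-algorithm notion of peak identity; the consequence is that benchmark
intervals are voted *sub-regions*, not whole source peaks. A `min_width`
filter exists but defaults to 1 (no silent filtering). "Common" peaks are
the depth = k runs; an algorithm's "specific" peaks are its intervals with
zero bases overlapping the common set (whole-peak removal on any overlap).

The top-N cut is integral to the construction, not a convenience: when
candidate lists are much longer than N, the cut confines voting to each
algorithm's high-confidence fraction. Without it (or with lists shorter than
N), dense low-confidence candidates from independent algorithms can reach
strict majority by chance alone; the consensus is only as meaningful as the
per-algorithm ranking feeding it.

## Replicate-distance validation

Each benchmark peak is attributed to the motif whose midpoint is nearest the
peak midpoint on the same chromosome (ties to the leftmost). The per-base
signal vectors of two treatment replicates in a `width`-bp window (default
1000; the window is `[c − w//2, c − w//2 + w)`, odd widths extending right)
centred on the motif midpoint give

    distance = 1 − Pearson(v1, v2)  ∈ [0, 2].

Windows that do not fit in the chromosome, anchors with no motif on their
chromosome, and zero-variance windows (where the correlation is undefined)
are skipped and tallied, never imputed — imputing any value would bias the
group comparison. The null group is 10,000 windows drawn uniformly over all
in-bounds start positions (chromosomes weighted by the number of valid
starts); groups are compared with a one-sided Wilcoxon rank-sum test.
Signal vectors are used per base; Pearson correlation is invariant to
positive affine rescaling, so per-window library-size normalization would
not change the distance (a CPM option exists for the per-peak signal
summaries, where scale does matter).

## Precision, recall, HM

Precision is base-pair-level: covered bases of the evaluated set (union;
internal overlaps counted once) that fall inside benchmark intervals,
divided by the set's covered bases. Recall is interval-level: benchmark
intervals overlapped by ≥ 1 bp, divided by the benchmark size. This
asymmetry is deliberate and matches the benchmark's definition of true/false
positives; a peak-level precision variant is available as an explicitly
non-default switch. HM = 2/(1/P + 1/R), defined as 0 when either side is 0.
Threshold curves evaluate the top-N cut at each grid point (default
{10², 10³, 10⁴, 10⁵, 10⁶}); thresholds beyond the list length evaluate the
full set, so short caller outputs yield flat/truncated curves. An empty
evaluated set yields an explicit no-data marker (`None`), never a 0.

## Motif scanning

The typical pG4 pattern is a G-run of length ≥ `min_run` (default 3,
unbounded above) followed by three repetitions of a 1–`max_loop` base loop
(default 7; any base, including N) and another G-run. The negative-filter
pattern caps runs at exactly 3–5 and is applied to both strands of a
candidate sequence. Because loops may themselves contain G's, pattern
matches overlap heavily and a single greedy regex pass does not enumerate
them; the scanner instead computes, per start position, the furthest
reachable match end by dynamic programming over G-run/loop decompositions,
and reports the merged union of all matches as maximal hits. Consequences:

* hit *count* is not monotone in the parameters (relaxing `max_loop` can
  coalesce two hits into one); the monotone invariant is covered base pairs;
* `n_tracts` (maximal G-runs of length ≥ `min_run` inside a hit) can be
  less than 4 when loops are themselves G-runs (e.g. a single run of ≥ 15
  G's is one maximal run yet a valid match).

Reverse-strand hits are reported in forward coordinates with strand "−".
The scanner substitutes for external pG4 predictors that score imperfect or
overlapping G4s; user-supplied BED files of external predictions are
accepted everywhere a motif set is consumed.

## Hypothesis-testing kernels

All three models test enrichment only (upper-tail p = P(X ≥ x)), with x the
treatment fragment count in the candidate region; per-base coverage tracks
are summed over the region and rounded (the generator emits per-base
fragment counts, so the sum is the fragment count).

* **Plain Poisson**: λ is the control count in the same region. λ = 0 is
  replaced by the genome-wide rate scaled to the region width, floored at
  1e-6 — a zero rate would make any observation infinitely significant.
* **Dynamic Poisson**: windows of total span 1, 5, 10, 50, 100, 500 and
  1000 kb are centred on the region midpoint (shifted, not shrunk, at
  chromosome ends; a flanks-only mode excluding the region itself is
  available as an option), and each window's control count is rescaled to
  the region width; λ_dyn is the maximum of the region-level count, all
  window rates, and the genome-wide rate. λ_dyn ≥ λ_plain always, so the
  dynamic p-value is uniformly ≥ the plain one at the same x — the
  structural reason its false positive rate cannot exceed the plain model's
  when true positives are strongly enriched.
* **Binomial**: n = round(control total × depth ratio), with depth ratio =
  treatment library size / control library size; p = mean control count over
  all candidate regions / n (so n·p is invariant to the depth scaling).
  One global (n, p) serves all regions; p ∉ (0, 1) is a validation error.

The to-be-tested dataset takes the benchmark intervals as positives;
negatives are drawn (seeded, without replacement, default 10,000) from the
pooled unfiltered candidate peaks after removing any interval overlapping
the benchmark or a user-supplied exclusion set by ≥ 1 bp and any interval
whose sequence matches the G3–5 exclusion pattern on either strand. A pool
smaller than the request is used whole, with a warning. FPR = FP/(TP+FP) is
evaluated per model over the p-value grid {1e-6 … 1e-1, 0.5, 1}; thresholds
with zero calls yield a missing point. No multiple-testing correction is
applied: raw thresholds are themselves the object of study.

## Synthetic-data generator

Defaults (the conditions under which the test suite's qualitative findings
are stated): one 1-Mb chromosome; 200 true peaks, width ~ Normal(300, 60) bp
(floored at 60), non-overlapping, ≥ 1 kb from chromosome ends so anchor
windows always fit; a typical pG4 motif (runs of 3–5 G, loops of 1–7 A/C/T
bases) implanted at each peak centre; background sequence with every G- and
C-run capped at two bases, so every quadruplex motif on either strand was
implanted deliberately. Control coverage is per-base Poisson at 0.02
fragments/bp, elevated 5-fold inside 10 hot regions of 20 kb (slot-placed
across the genome). Hot regions model input-channel bias (accessibility /
copy-number artifacts): they elevate the *control* only, while treatment is
flat background outside peaks and 8× the local control rate inside peaks.
The two treatment replicates share a per-base latent Gamma rate inside peaks
with shape k = μ(1−ρ)/ρ, giving negative-binomial marginals with count
correlation ρ (default 0.8) at peaks; outside peaks the replicates are
independent. Simulated callers detect each truth peak with probability
1 − fnr (default 0.9), jitter its centre by Normal(0, 50 bp) and its width
by a exp(Normal(0, 0.15)) factor, add round(fpr × n_true) false peaks at
truth-free loci, and assign log-uniform p-values in [1e-10, 1e-4] to
detected-true peaks and [1e-4, 1e-1] to false ones, so ranking is
informative. Every stage is a pure function of the configuration seed.

Two scaled configurations appear in the acceptance suite as their own study
conditions: an *unfiltered-caller* setting at the full study scale for the HM-curve
shape (10,000 true peaks on 30 Mb, per-caller fpr 9.0, so each caller emits
~10× more candidates than true sites and the top-10,000 benchmark cut is
active), and a *large-pool* setting for negative-set construction (500 true
peaks on 5 Mb, one caller with fpr 60, giving > 10,000 filter survivors).

What the generator does **not** emulate: read-level artifacts (PCR
duplicates, mappability, GC bias), fragment-length structure (fragments are
per-base counts), chromatin-state correlation between treatment and control
beyond the hot regions, caller-specific systematic biases (boundary
refinement, window quantization), and realistic genome composition.
Passing tests therefore demonstrate the correctness and internal logic of
the evaluation machinery under its stated statistical assumptions, not the
field performance of any particular peak caller on real data.

## Numerical choices

* Poisson/binomial tails via `scipy.stats` survival functions; unit tests
  pin them to independent direct pmf summation (1e-12 absolute, x ≤ 50,
  n ≤ 1000) and to the Poisson limit of the binomial (1% at n = 1e5,
  p = 1e-4).
* Pearson correlation via `numpy.corrcoef`; distances clipped to [0, 2]
  against rounding excursions.
* bedGraph records must be non-overlapping and in-bounds (validation error
  otherwise); tracks expand to dense per-base float64 arrays with cached
  cumulative sums for O(1) window counts. bigWig input is feature-gated on
  pyBigWig being installed.
* Degenerate inputs yield explicit outcomes: empty evaluated peak set →
  no-data marker; zero-variance window → missing distance; all-tied
  rank-sum input → p = 1 with a warning; empty benchmark, x > n, p ∉ (0,1),
  λ ≤ 0 → validation errors.

## Limitations

The benchmark's majority vote assumes the contributing algorithms err
quasi-independently; correlated failure modes (e.g. shared blacklist
regions) would enter the benchmark unchallenged. Base-level voting emits
voted sub-regions, which are narrower than any single caller's peaks; recall
(interval-level) is insensitive to this, but base-pair precision of a caller
against its own consensus is bounded below 1 by construction. The binomial
kernel's single global rate makes it sensitive to the composition of the
candidate-region set from which p is estimated. The dynamic-λ definition
interprets the region-level term b as the control count in the candidate
region itself, consistent with the local-λ approach it descends from.
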