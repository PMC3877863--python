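# Methods

## Expression quantification

Expression of a locus is its base coverage: the sum of read lengths of all
retained reads assigned to it. The retention rule is strict — a read is
kept only if (i) it aligns to exactly one locus tag across all of its
alignment lines, (ii) its aligned span equals its full read length, and
(iii) its CIGAR contains no soft/hard clips and no insertions or
deletions. The three conditions operationalize "mapped completely to a
single locus tag": a deletion-only alignment leaves the aligned span equal
to the read length, so indels are tracked as their own disqualifier rather
than folded into the span test. A read with several alignments to the
*same* locus counts as one locus hit and is counted once. Mates of a pair
are treated as independent reads.

Normalization divides coverage by locus length (mRNA or CDS length, taken
from the annotation FASTA sequence lengths or a locus/length TSV) and by
the experiment's total counted bases, then multiplies by a scale constant,
default 10⁹ (a per-base, per-kilobase-per-gigabase analog). Under the log2
transform the constant is a pure additive shift: it cannot change the
shape, peak count, or Zipf gradient of the distribution, only the axis
labels. The identity Σ_g norm(g)·length(g) = scale_constant holds exactly
and is asserted in tests. Loci with zero coverage are excluded before any
downstream analysis; all mixture weights and rank statistics therefore
refer to fractions of *expressed* (nonzero-coverage) genes.

RPKM (reads·10⁹ / (length·total reads)) is implemented alongside so the
robustness of modality classification to the quantification measure can be
checked; with uniform read length the two measures are exactly
proportional and the mixture machinery is shift-equivariant in log space,
so agreement is a designed invariant, not an accident of tuning.

## Mixture model and EM

The log2 expression vector is modelled as a K-component univariate normal
mixture. Two variance families are fitted: component-specific variances
("V", 3K−1 free parameters) and a single pooled variance ("E", 2K). The
E-step computes responsibilities r_ik ∝ w_k N(x_i; μ_k, σ_k²), normalized
in log space with a max-shift (log-sum-exp); the M-step uses the standard
weighted updates, with the E-family variance pooled across components.

**Initialization** is deterministic: component k starts at the (k−0.5)/K
sample quantile with equal weights and the sample variance. This makes
fits independent of input order (asserted to 1e-9 under permutation) and
reproducible without a seed; optional jittered restarts (`n_starts`,
seeded) can be layered on top but default to zero. Model-based
agglomerative initialization — the classical choice in model-based
clustering — was deliberately not reproduced; for one-dimensional data
quantile starts reach the same optima, which a 200-restart brute-force
oracle and an independent reference implementation (scikit-learn, tests
only) both confirm.

**Convergence.** Iteration stops when the absolute log-likelihood change
falls below tol·(1+|logL|), tol = 1e-8, or when Aitken extrapolation of
the geometric tail projects the remaining gain below the same bound, or at
1000 iterations. The Aitken rule matters only for deliberately overfit K,
where plain EM creeps for thousands of iterations toward a ridge; it never
fires before the plain criterion is within tolerance of the same limit.
Per-iteration log-likelihood is recorded on the model (`loglik_trace`) and
asserted non-decreasing (slack 1e-8) for every fit in the test suite.

**Degenerate data and collapse.** An all-constant input (sample variance
below 1e-20·(1+mean²), i.e. numerical noise) is reported as a single
component at the variance floor and flagged `degenerate`. During EM,
variances are floored at 1e-6 of the sample variance; a fit that needs the
floor on two iterations is flagged `collapsed` and excluded from model
selection. Fits that merely exhaust `max_iter` remain eligible — they sit
on flat overfit ridges whose BIC is already far below the winner.

**Selection.** Every (K, family) in K = 1…9 × {E, V} is fitted and the
argmax-BIC model returned, BIC = 2·logL − p·ln n (maximize convention).
Ties break toward smaller K, then family E; at K = 1 the two families are
the same two-parameter model and E wins the tie by construction. The K
range tops out at 9 because observed expression distributions run up to
five components and selection must be free to overshoot. The full BIC
table is returned for reporting.

## Modality classification

Peaks are identified with mixture components; overlapping components need
not be distinct density modes, and a separate diagnostic
(`count_density_modes`) counts true modes on a grid for comparison. A
component is a main peak iff its weight is ≥ the main threshold, default
0.15, *inclusive* — a component at exactly 15% counts. `n_main_peaks` is
non-increasing in the threshold (property-tested). Labels: ≥3 main peaks
multimodal, 2 bimodal, otherwise unimodal. The per-dataset summary row is
(sample, condition, n_peaks, n_main_peaks).

## Zipf test

Genes are sorted by descending log2 expression; ties break by locus tag
lexicographically so ranks are always the integers 1…n and log2(rank) is
well defined. OLS of log2 value on log2 rank gives the gradient (−s for an
exact power law with exponent s, base-invariant) and intercept
(base-dependent); a second OLS adds a squared-rank term whose coefficient
diagnoses curvature. The published analyses judged linearity by eye; the
numeric operationalization here — R² ≥ 0.98 and |quadratic coefficient| ≤
0.01, evaluated over the central 90% of ranks with the full-range fit
reported alongside — was chosen so that exact power laws pass and
mixture-shaped data clearly fails, and both thresholds are exposed in the
API and CLI. "Linear over the middle but not overall" is reported as its
own state (`middle_only`), since yeast-like distributions show exactly
that.

## Synthetic data

The generators define the study conditions. The 3-component benchmark
(weights 0.2/0.5/0.3, means −4/0/4, sd 1, n = 10,000) drives the recovery
checks; preset scenarios provide shape templates: `unimodal`; `yeast_like`
(weights 0.15/0.85 — one predominant peak holding ≥ 70% of expressed
genes); `bimodal_metazoan` (0.40/0.60, well-separated low/high classes);
`ncrassa_like` (five components, three of weight ≥ 0.15); `zipf_s1` (exact
power law, s = 1, C = 1024). Component means are separated by ≥ 3 within-
component standard deviations so recovery at n = 10,000 is comfortable
rather than borderline. SAM fixtures place uniform-length, error-free,
gapless reads at seeded random positions; the six-read default fixture
exercises each filter branch (clean / multi-locus / clipped) and the
two-class fixture (~60 loci, ~7,600 reads, low and high read-count
classes) produces a clearly bimodal log2 vector with every read retained.

What the generators do **not** emulate: sequencing error and quality
variation, read-length heterogeneity, positional and GC bias, spliced or
clipped true alignments, overdispersed biological replicate structure, and
partially overlapping mixture components. Passing tests therefore
establish correctness of the computation and recoverability under clean,
well-separated conditions — not performance on borderline real datasets,
where component separation, not the algorithm, is the binding constraint.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng` seeded from the
  spec or CLI `--seed`; no global RNG state. Same seed ⇒ byte-identical
  tabular outputs, and run manifests carry no timestamps so reruns compare
  equal at the byte level.
- Log base 2 everywhere, matching the field's convention for expression
  ratios; only intercepts depend on the base.
- Rank regression uses `numpy.linalg.lstsq` on the [1, x] and [1, x, x²]
  designs; R² is clipped to [0, 1].
- Histogram bin width for density-overlay figures defaults to 0.25 log2
  units; plots are headless (Agg) and optional — tabular outputs are the
  contract.
- Problem sizes in the test suite and acceptance script (n = 10,000
  vectors, 20 replicate seeds, 200 oracle restarts at n ≤ 50) were chosen
  as the smallest sizes at which the statistical checks are comfortably
  away from their decision boundaries.

## Known limitations

- The EM is univariate by design; no multivariate or non-normal components.
- Peak counting equates peaks with components, so heavily overlapping
  components inflate the peak count relative to density modes; the mode
  diagnostic quantifies this but the headline statistic follows the
  component convention.
- Zipf consistency is a thresholded OLS diagnostic, not a formal power-law
  hypothesis test (no maximum-likelihood exponent estimation, no
  goodness-of-fit p-value).
- BAM input works wherever pysam can read it, but the text SAM path is the
  tested surface.
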