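# Methods

## Model and assumptions

The data model is a per-cell fluorescence measurement (AGV, average grey
value, arbitrary units from 16-bit imagery; values are not clamped to the
camera range) drawn from a two-component mixture: a large "OFF"
subpopulation and a small "ON" subpopulation, each approximately normal.
The quantity of interest is the ON fraction as a percentage of the total —
a dimensionless, scale-free readout. All splitting methods assume:

- the OFF component is the majority, so the central half of the pooled
  data is essentially pure OFF;
- components may overlap, so any cutoff-based split is an approximation —
  near the cutoff individual cells cannot be assigned with certainty;
- within-image cells are exchangeable; systematic whole-image shifts are
  acquisition artifacts handled by QC, not biology.

No mixture model is fitted (no EM); the methods are deliberately simple,
deterministic given the data, and robust to the exact ON-component shape.

## Splitters

All four place a cutoff and count cells **strictly above** it (boundary
ties stay in the large subpopulation).

**Q-Q regression ("default").** Sorted values are plotted against
standard-normal quantiles of their plotting positions, `(i − 0.5)/n` for
n > 10 and `(i − 3/8)/(n + 1/4)` for n ≤ 10 (the usual normal-scores
convention; at the n ≥ 1000 scale these conventions are
indistinguishable). An OLS fit of sorted values on theoretical quantiles,
restricted to points inside a value-space *regression region*, estimates
the OFF-component SD as the slope. The region is either user-supplied
(reproducing a hand-placed band) or `"auto"`: the band between the 25th
and 75th percentiles of the pooled data, which approximates the OFF
component's IQR whenever the ON fraction is a minority. The cutoff is
`median + z(p_conf) · slope` with the **full-data** median and
`p_conf = 0.995` (z = 2.576), i.e. the one-sided 1% point of the fitted
OFF distribution. The full-data median and the OFF median coincide to
within sampling noise for minority ON fractions; the full-data median is
used because it requires no component assignment. On a pure normal sample
the expected estimate is therefore 0.5% — the method's intrinsic false
positive floor. Degenerate inputs are rejected: fewer than 20 values,
fewer than 10 in-region points, or a non-positive slope (constant or
non-monotone region).

**Boxplot fences.** `cutoff = Q3 + k · IQR`, with quartiles taken as Tukey
hinges (medians of the sorted halves, each half including the overall
median position when n is odd — the `fivenum`/boxplot-statistics rule; a
config-free choice since for n ≥ 1000 it differs negligibly from
interpolated quartiles). k = 1.5 flags mild outliers (asymptotic fence
μ + 2.698σ on pure normal data, upper-tail mass ≈ 0.35%), k = 3 extreme
outliers (fence ≈ μ + 4.72σ, mass ≈ 1e-4%). Requires n ≥ 4. These are the
only fully automatic methods and the ones used for large simulation
sweeps.

**Manual.** An explicit numeric cutoff, replacing interactive cursor
placement; kept for parity and for datasets where the Q-Q pattern is a
smooth curve rather than two lines.

All splitters are translation/scale equivariant, so results are
independent of gain/offset of the acquisition chain.

## Descriptors

Four distribution-free summaries retained for comparison only — they do
not estimate a subpopulation size: mean; 95th percentile (linear
interpolation of order statistics, `h = (n−1)p + 1`); boosted mean (mean
of values between the 75th and 95th percentiles, bounds inclusive — the
inclusivity choice is immaterial for continuous data); mean of the top
`ceil(0.05·n)` values. A percentile-wise profile
`100·(Q_treat(p) − Q_ctrl(p))/Q_ctrl(p)` on a 1–99% grid (step 1) supports
whole-distribution treatment/control comparison.

## Bootstrap confidence intervals

Replicates resample the data with replacement and re-apply the estimator
with parameters (cutoff, region) held fixed — replication of a manual
workflow per replicate is out of scope, a deliberate divergence from
interactive practice. Two flavors: normal approximation
(`mean ± z((1+level)/2)·SD`, sample SD) and percentile (empirical
(1±level)/2 quantiles, linear interpolation). By default the flavor
follows the replicate count (normal ≤ 30 reps, percentile otherwise);
historically the flavor was tied to whether a method needed manual
intervention, a workflow-cost artifact we decouple. A replicate on which
the estimator fails (e.g. degenerate regression on a resample) is recorded
as missing; more than 20% missing aborts, since the interval would no
longer describe the stated estimator.

## Per-image QC

Whole-image acquisition errors shift every cell in an image. Each image is
summarized by median and Tukey hinges; an image is flagged when its median
deviates from the grand median of per-image medians by more than
`k · MAD` (MAD scaled by 1.4826 for normal consistency; default k = 3).
This operationalizes a visual per-image boxplot screen as a numeric rule —
robust, scale-free, and reducing to "the obviously dim image" in the
motivating scenario. There is no field-standard numeric criterion for this
screen; k is configurable and the flag report records all inputs to the
decision. With all-equal medians the MAD is 0 and the strict inequality
flags nothing. Flagging is idempotent: after removal, the rule re-applied
to the survivors flags nothing new in the tested scenarios.

## Simulation benchmark

`simulate_mixture` draws `round(pct/100 · n)` ON cells from
`Normal(small_mean, small_sd)` and the remainder from
`Normal(large_mean, large_sd)`; rounding keeps the tested truths exact at
n = 2000. Defaults emulate measured reporter populations: OFF mean 63, SD
3.9; ON mean 127.3, SD 37.7 (AGV units). Grid sweeps cover ON SD 10–50,
ON mean 65–200 and proportions 0.1–40% (or 0.1–1.2% for the
very-small-proportion sweep) at total sizes 2000, 20000 or 200000, with
axes spaced equidistantly inclusive of endpoints. Per-cell seeds derive
deterministically from (grid seed, cell index) via `SeedSequence`, making
grids reproducible cell-by-cell and embarrassingly parallel. Accuracy is
`100·(est − true)/true`; an estimate of 0 gives exactly −100 and
`detected = False`; a splitter failure leaves the cell's estimate missing.

What the generator does *not* emulate: non-normal ON components, per-image
batch structure, detector saturation, segmentation errors, or correlated
cell-to-cell variation. Passing benchmarks therefore demonstrate
correctness of the estimators under the stated mixture model, not
performance on arbitrary real data.

Known behavior reproduced by the benchmark: boxplot fences collapse once
the "small" component exceeds ~25% of the total (the fence chases the
mixture's upper quartile into the ON component and the estimate falls
toward 0, accuracy → −100); boxplot3 underestimates by a stable ≈ −9.5%
in the very-small-proportion regime (mean difference 67.8, ON SD 37.7)
while boxplot1.5 overshoots explosively below ~1% because its fence sits
in the OFF tail (≈ +340% at 0.1%). A closed-form oracle — mixture
quartiles by root-finding on the exact mixture CDF, expected estimate =
mixture mass above the fence — anchors these numbers analytically in the
test suite.

## Numerical and design choices

- Quantile interpolation everywhere (descriptors, percentile CI,
  regression-region bounds) is the linear order-statistic rule, numpy's
  default.
- The default-method regression uses all points inside the value bounds
  (not a rank window).
- Problem sizes in tests and the acceptance script: 3 repetitions at
  N = 2000 for the estimated-vs-true table; 20 replicate mixtures per
  proportion at N = 200000 for the small-proportion sweep (a single
  mixture at 0.1% holds only 200 ON cells, so per-mixture binomial noise
  is ±2 accuracy points; averaging makes max-over-proportions statistics
  stable). Property checks on pure normal samples use 5 × 100000 draws.
- Seeds are explicit parameters on every stochastic operation; identical
  inputs give identical outputs.

## Limitations

Cutoff-based splitting is an approximation by construction: as components
overlap, the per-cell assignment near the cutoff is arbitrary, and each
method carries a predictable bias (default: +0.5 percentage points of OFF
tail mass; boxplot3: ≈ −10% relative in the small-proportion regime;
boxplot1.5: large relative overshoot below 1%). Boxplot methods are
unusable above ~25% ON fraction. The bootstrap quantifies sampling
variability only, not these structural biases. The QC rule needs ≥ 2
images and is a heuristic, not a gold-standard artifact detector.
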