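# Methods

This note records the models, parameter choices and numerical decisions
behind `biopsim`, and what the synthetic conditions do and do not show
about real hospital data.

## Random variates

Normal deviates come from the Box-Muller sine branch,
x = sqrt(−2 ln U₁)·sin(2π U₂), consuming exactly two fresh uniforms per
deviate; a classic paired (sin, cos) mode is available but nothing in the
package depends on it. The uniform source is a 64-bit PCG64 generator
whose raw [0, 1) draws are nudged to the open interval (a draw of exactly
0 is mapped to the smallest positive double) because ln(0) diverges.
Batch draws consume the identical stream as scalar draws, so vectorized
and loop-based callers agree bit for bit at the same seed.

Service times are physical durations, so samplers offer `positive_only`
**rejection** resampling (never clamping, which would distort the shape on
the positive support). For the default mixture parameters the truncation
bias is small but not nil: the fast analysis mode N(9.2571, 4.3069)
restricted to (0, ∞) has mean 9.4304 (+1.9 % of μ); the other three modes
shift by ≤ 0.15 %. Capacity totals computed with positive-only draws
therefore sit ≈ 0.7 % above the untruncated closed-form expectation;
tests compare Monte-Carlo output against the truncated-normal mean, the
correct oracle for what is actually sampled.

## Service-time mixtures and classification

Cutting and analysis are two-component normal mixtures (parameters in the
README). Two parameterizations of the weights circulate: the per-sample
split (90.9/9.1 cutting, 64.8/35.2 analysis) and the split implied by the
annual combination counts (96.1/3.9 and 83.7/16.3). They are not
consistent with each other; the package takes weights and counts as
explicit, separate inputs (`weights_from_counts` converts counts when
wanted) and does not resolve which view is "true".

`classify_bimodal` reproduces the empirical procedure that found the
analysis modes: a threshold split (fast < 16 min, slow > 20 min) followed
by per-group moments — deliberately *not* EM, which would be a different
method. Values inside the 16–20 min gap (possible in synthetic data,
absent in the original sample) go to the nearer threshold's group, ties
to group 1; this preserves the 2:1 fast:slow ratio on gap-free data.
Threshold classification recovers mixture parameters only when the modes
barely overlap: for the analysis model the component overlap across the
thresholds is negligible and 5,000 draws recover means within 0.5 min and
proportions within 0.05. The cutting modes (1.2 vs 30 min, SD 10) overlap
the 16/20 rule badly, so its round-trip test uses thresholds suited to
that geometry (3/5 min). A conditional-mean bias of order
σ·φ/Φ remains whenever a mode's tail crosses the threshold; it is a
property of the method being modelled, not a bug.

One external restatement of the fast-analysis SD as 7.307 conflicts with
the tabulated 4.3069; the tabulated value is used throughout.

## Inference

- **Chi-square GOF**: Pearson Σ(o−e)²/e with ν = k − 1 where k is the
  number of **cells**. (A text source defines k as "the total number of
  data"; that reading makes ν meaningless for binned tests and is not
  used.) Continuous samples are binned into equal-probability cells under
  the fitted normal, k = max(2, min(20, n/5)), keeping expected counts
  ≥ 5.
- **Normality**: Anderson-Darling with estimated parameters, delegated to
  `statsmodels.stats.diagnostic.normal_ad`; acceptance means p > α.
  Constant samples raise an error rather than returning a verdict.
- **Model validation**: the paired interval
  (X̄ − Ȳ) ∓ t_{ν−1, 1−α}·sqrt(σ²_d/ν) with σ²_d the sample variance of
  the paired differences — the standard paired form; the model is "not
  rejected" when the interval contains zero. The one-sided 1−α quantile
  is used, matching the procedure being reproduced.
- **Power**: exact noncentral-t for the two-sided one-sample test,
  iterating n upward; no normal approximation. This yields minimal n = 29
  at (δ=3, SD=4.30) and n = 21 at (δ=5, SD=6.001), α = 0.05, power 0.95.

## Process model and fixture

The department fixture reconstructs the 36-activity chain from a
published 40-hour reference run that completed 239 units: per-unit
minutes = printed busy hours × 60 / 239. Five activities (1, 2, 6, 35,
36) have no published duration anywhere and carry a flagged 0.5-minute
placeholder; they are fast clerical/transport steps and do not affect the
bottleneck structure. By construction per-unit × 239 / 60 round-trips
every printed cell to three decimals.

Category bookkeeping: the printed per-category hour totals sum exactly to
the 31 printed rows (219.258 h), but no assignment of rows to categories
reproduces the individual operations/transport/storage splits (e.g. the
four storage-described rows sum to 78.6 h against a printed 42.7). Only
the inspection total (activities 3 + 12 = 4.676 h) reconciles, and only
it is asserted; the fixture assigns categories by activity description.
Similarly, the prose names the ≥ 90 % constraints as 19, 33, 34 while the
printed utilizations mark 19, 32, 33; the fixture follows the printed
numbers.

Each fixture activity is its own single-slot station (the reference run's
utilizations are per-activity, busy ÷ 40 h); staff resources are attached
as the operators of those stations. `sd_fraction` (default 0, documented
choice 0.2 for stochastic runs) sets each activity's SD as a fraction of
its mean — the per-activity SDs were never published legibly.

## Simulation engine

The clock runs in cumulative **on-shift working hours** under a single
department calendar (8 h/day × 5 days; the published week is 40 working
hours). Under a common calendar this is exactly equivalent to wall-clock
simulation with overnight pause-and-resume, and it keeps every quantity
(horizon, busy hours, utilization) in the units the reports use. The cost
is that per-resource calendars that *differ* are not modelled; the biopsy
flow's resources all share the 07:00–16:00 shift, so nothing in scope is
lost. A resource with zero FTE or zero shift hours raises a configuration
error before the run starts.

Arrivals: weekly counts from the demand normal (rounded half-up, floored
at 0), spread over the week's working hours — evenly when the demand SD
is 0 (making capacity-load runs fully deterministic), uniformly at random
otherwise. Queues are FIFO per resource; no preemption; activities
without a resource are pure delays. Utilization is busy hours ÷ horizon
per activity; services still in progress at the horizon contribute their
elapsed portion. A 1e-12 relative tolerance at the horizon keeps a
service ending exactly at the boundary from being lost to float error.

Fed at its capacity load (239/week, deterministic), the reconstructed
chain completes ≈ 234 units in 40 h (the last arrivals cannot clear the
~55-minute pipeline latency) and reports bottleneck utilizations within
0.02–0.03 of the published 99.78 / 93.71 / 92.38 % — the published
figures correspond to all 239 units clearing every activity, which a true
event-driven trace cannot quite achieve inside the same week. Replicate r
of a run uses seed + r, so a (config, seed) pair reproduces its event log
bit for bit.

## Capacity, staffing, economics

Annual pathologist hours: for each cut × analysis combination, draw one
cutting and one analysis duration per biopsy (positive-only), sum, and
average over replicates (default 10). Combination counts
(6,748 / 1,242 / 210 / 112) are inputs, not derived from mixture weights
(see the inconsistency above). Closed-form expectation with truncation:
≈ 2,027 h grand total, ≈ 1,191 h for C1A1. Staffing divides by 1,776
productive hours per FTE-year; the 50-week demand year is back-derived
from annual ÷ weekly volume (≈ 7,576 / 151.55 ≈ 50). Hours and FTE are
reported to 2 decimals.

Scenario costs are exact cent arithmetic: total = fixed + overtime,
cost per biopsy = total ÷ annual output, rounded to cents. The default
overtime rate (7.603 US$/h) is back-derived from a 320-hour block costing
2,433.03 and can be overridden; the current plan's overtime is an
explicit cost, not hours × rate. Backlog clearance is stock ÷ monthly
surplus; the reference plans' 7- and 3-month adjustment times are
calibrations given as inputs, not derived outputs. Ranking sorts by
(diagnosis days, total cost). Note the reference rows do not all survive
a single rounding rule to the printed cent (51,631.23 / 4,850 = 10.6456
prints as 10.64 while 46,225 / 8,300 = 5.5693 prints as 5.57); the
package uses standard rounding and its tests compare at one-cent
precision.

## Synthetic data

The generator emulates the accession log's statistical skeleton: weekly
arrivals N(151.55, 18.45) (rounded half-up, floored at 0); specialty
drawn from a top-4 block (gynecology, general surgery, gastroenterology,
minor surgery) holding 81.24 % of volume — split 4:3:2:1 within the
block, a modelling choice since only the block total is published — plus
an 18.76 % remainder; provenance 87 % own hospital / 13 % network; stage
durations from the mixtures with generating-component identity recorded.
Diagnoses are assigned FIFO against a weekly capacity that is
unconstrained before the backlog onset week (default 24) and constant
(default 28/week) afterwards — the simplest mechanism that opens a
received-vs-diagnosed gap at the onset week and, over a 43-week horizon
(≈ 6,500 receipts), leaves ≈ 38 % pending, matching the reported
shortfall. The 28/week default is back-derived from exactly that
condition and fixed once.

What passing tests show: the estimators recover what this generator puts
in. What they do not show: real logs have calendar effects (holidays,
within-week patterns), correlated specialty/duration structure,
non-constant capacity, and re-cut/re-stain rework loops, none of which
the generator produces; batch processing (histology racks) and priority
classes are likewise out of scope.

## Problem sizes

Defaults were chosen so the entire suite runs in seconds on one core:
distributional checks at n = 10⁵ draws, mixture recovery at n = 5,000,
capacity at 10 replicates of ~16.6 k draws, demand at 100 replicates of
50 draws, normality repetition checks at 20–60 seeds, and 40–400-hour
engine horizons. Each is large enough that its Monte-Carlo error is a
small fraction of the tolerance it is tested against (tests use ~3
standard errors, or 2 binomial standard errors for acceptance-rate
checks).
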