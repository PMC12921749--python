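# Methods

## The endemic channel

For each epidemiological week *w* = 1..52, the channel is the (25, 50, 75)
percentile triple of the counts observed at that same week across the
baseline years — the same time point compared across years, so the channel
carries the seasonal shape directly rather than through a model. The
baseline defaults to six years (2014–2019): long enough to average over
year-to-year variation, short enough to avoid major secular changes in
surveillance practice.

With only six values per week, the percentile definition is not a detail:
linear interpolation of order statistics (the common spreadsheet and
statistics-package default, `numpy` method `"linear"`, i.e. position
h = (n−1)q) is the default, with `"nearest"` and `"midpoint"` selectable.
For six baseline values the three rules can differ by a substantial
fraction of the inter-year spread, which is why the choice is explicit,
configurable, and recorded in the run log. No smoothing is applied by
default: the channel is the raw weekly percentiles.

Zone classification uses a left-closed boundary convention — a count
exactly equal to a percentile takes the lower-activity zone (count = P25 →
*safety*, count = P50 → *safety*, count = P75 → *alert*). The convention is
arbitrary at measure-zero boundaries for continuous data but matters for
counts, where exact ties with small-sample percentiles are common; it is
fixed, documented, and asserted in tests.

## Excess / deficit and its bounds

The deviation of any scope is linear in the counts:
point = Σ obs − Σ P50, lower = Σ obs − Σ P75, upper = Σ obs − Σ P25,
summed over the weeks in scope. The bounds are *channel-derived*, not
sampling intervals: they answer "how would the verdict change if expected
activity were read at the channel's edges rather than its centre", so a
period whose `upper` is negative has a deficit certified even against the
most conservative expectation. No bootstrap or Poisson interval is
attached — the uncertainty communicated is the channel's own width.

Because every scope is a sum, period = Σ annual = Σ weekly exactly; the
test suite asserts this to 1e-9 absolute.

Missing weeks are never imputed: deviation sums skip them and flag the
result `partial`. Epidemiological week 53, which long years produce, is
merged into week 52 by default (conserving the annual total; a `drop`
policy is available) so that all downstream arithmetic sees exactly 52
weeks per year — an 11-year span is then 572 weeks.

## Percent change

Between two periods, medians are taken over *all* weekly counts pooled
within each period (not medians of annual medians — the pooled reading is
what "weekly median cases" of a multi-year period means), and
change% = 100 (m₂ − m₁)/m₁, reported to one decimal. A zero baseline
median raises an explicit undefined-change error rather than dividing by
zero.

## Supporting statistics

* **Shapiro–Wilk** screens weekly counts for normality (3 ≤ n ≤ 5000,
  non-constant). Seasonal counts fail it decisively, which motivates the
  rank-based period comparison.
* **Mann–Whitney U**, two-tailed, compares baseline-period and
  comparison-period weekly counts. The exact null distribution is used
  when the smaller sample has ≤ 8 values and the samples share no ties;
  otherwise the midrank normal approximation with tie-corrected variance,
  without continuity correction, so the z statistic is the classical
  tie-corrected one. Period samples here are large (312 vs 260 weeks), so
  the asymptotic path is the operative one; the exact path is verified
  against full enumeration of all label arrangements for n₁, n₂ ≤ 5.
* **Seasonality** is assessed by the sample ACF to lag 52 (the standard
  biased, mean-subtracted estimator) with a Ljung–Box portmanteau p-value
  at the annual lag and per-lag Bartlett bands for plotting. For an
  exactly period-52 series of length 572 the lag-52 sample ACF is
  (572−52)/572 ≈ 0.909 in closed form, which the tests pin down. At lag 52
  with n = 572 the Ljung–Box test is mildly anti-conservative: its
  empirical level at nominal 5% is ≈ 6.5% (measured over 1000 white-noise
  seeds, Gaussian and negative-binomial alike) — a finite-sample property
  of portmanteau tests when n/lag is modest, worth knowing when reading
  borderline p-values, and irrelevant for the decisive rejections
  (p < 10⁻⁴) that genuinely seasonal series produce.

No multiple-testing correction is applied across diseases; results are
reported per disease. This is a deliberate limitation.

## The synthetic generator

Weekly counts are negative-binomial draws with mean

    mu[y, w] = base_rate · exp(trend·(y−y₀))
               · exp(A·cos(2π(w − peak_week)/52))
               · m  (inside the disruption window, else 1)

and size parameter `dispersion` (variance mu + mu²/size; `inf` recovers
Poisson). One harmonic only — the target regime has single annual peaks.
A single integer seed determines the series; replicate *r* of an
experiment uses seed + r.

Defaults describe the study conditions: an 11-year span 2014–2024 (572
weeks), base rate 100 cases/week, strong seasonality (A = 0.8, peak week
2, i.e. winter peaks at the turn of the year), no trend, negative-binomial
size 10 (realistic overdispersion for bulletin counts), and a one-year 50%
reporting collapse covering 2020.

What the generator emulates: seasonality, secular drift, overdispersion,
and an abrupt multiplicative reporting disruption. What it does not:
mechanistic transmission (susceptible dynamics, rebound epidemics),
reporting-delay artifacts, holiday-week dips, multi-harmonic seasonal
shapes, or gradual recovery of reporting. Passing the recovery experiment
therefore shows the *estimator arithmetic* is sound under the stated
statistical structure — not that real post-disruption surveillance behaves
like the generator.

## The recovery experiment and its validation scenario

Each replicate simulates a series, builds the channel on the pre-disruption
years, estimates the disruption-period deviation, and compares it with the
generator's true deficit Σ(disrupted mean − undisrupted mean). Reported:
bias, Monte-Carlo 95% band, coverage of the channel bounds, sign rate.

One structural caveat drives the scenario design: the estimator subtracts
summed baseline *medians*, while the ground truth is defined through
*means*. For right-skewed counts the median of six draws sits below the
mean (for NB size 10 at rate 100, by ≈ 2.5%), so under strong
overdispersion the null estimate has a small positive bias — visible in
`analysis/05_recovery_experiment.py`, which runs both regimes. The
estimator is therefore validated where it is designed to be read: the
low-skew regime. The validation default (`default_recovery_config`) keeps
the strong seasonality and one-year 50% collapse but uses base rate 300
with NB size 400 — skewness ≈ 0.1, effectively Poisson — where the null
bias is an order of magnitude below the Monte-Carlo noise floor of 200
replicates. Under that scenario, 200 replicates estimate a one-year halving
with the truth inside the Monte-Carlo 95% band, 100% negative signs, and a
null (multiplier 1) mean within 3 standard errors of zero.

## Numerical and interface choices

* Channels require every week to have ≥ 2 baseline observations; the
  error names the week and the missing years. Weeks observed in fewer than
  all baseline years use the years available.
* Constant samples and constant series raise degenerate-input errors
  rather than returning NaNs.
* Report tables round percentages to one decimal and case counts to
  integers; internal computation is unrounded.
* The CLI records percentile method, week-53 policy and the zone boundary
  convention in `run_log.json`; identical input, config and seed give
  byte-identical tables.
* Problem sizes in the test and acceptance runs — 572-week series, 1,040
  random baseline weeks per percentile method, 100 calibration seeds, 200
  recovery replicates — were chosen to hold Monte-Carlo noise comfortably
  below the asserted margins while keeping a full run in tens of seconds.

## Known limitations

* The channel-median deviation estimator is biased for mean-defined
  deficits under strong skew (quantified above); read its point estimate
  as "cases relative to the historical median", not a mean-model fit.
* Baselines of six years make the channel percentiles noisy; the p25–p75
  band understates tail uncertainty.
* Week numbering is taken as given; no ISO/MMWR calendar conversion is
  attempted, and week-53 handling is a policy, not an inference.
* No aberration-detection machinery (Farrington-style expected-count
  regression) — the channel is a descriptive norm, not an alarm system.
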