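# Methods

This note records the modelling choices behind `dietshift`: the
estimator, its assumptions, the defaults and why they were chosen, what
the synthetic generator does and does not emulate, and the numerical
decisions a maintainer would want written down.

## The difference-in-discontinuities estimator

The core estimand is the multiplicative change in a weekly
search-interest series attributable to the onset of reduced mobility.  A
plain interrupted-time-series or RDD fit on 2020 alone would confound the
shock with seasonality (Easter baking, summer barbecue, end-of-year
holidays).  The design therefore stacks the same calendar weeks of a
control year (2019) into the regression and places a "fake"
discontinuity at the same week-of-year; the treatment-year interaction
block (α, β, γ) then measures the discontinuity net of whatever happens
in those weeks of a normal year.

Assumptions worth stating:

* **Common seasonality.** The 2019 weeks act as a counterfactual; the
  identification assumes the seasonal profile would have repeated in 2020
  absent the shock.  The 2019↔2020 week alignment is by week-of-year
  index on a 52-week grid (week 53 never enters; input rows labelled week
  53 are dropped with a log message).
* **Multiplicative structure.** All outcomes are natural-log volumes, so
  coefficients compose multiplicatively and effects are reported as
  `e^a − 1` percentages.  Volumes must be strictly positive inside the
  fit window; a zero volume is a hard error for that series (recorded and
  skipped at the study level), never imputed, because silent imputation
  would bias the polynomial terms.
* **Local polynomial adequacy.** The quadratic form is the primary
  specification; constant and linear forms are fitted alongside as
  sensitivity checks.  Bandwidths default to `t_min = 10` (the cutoff
  falls at most ten weeks into the year) and `t_max = 30` (long enough to
  measure reversion, short enough to stay clear of second-wave shocks),
  giving the canonical 82-row design.  When a country's cutoff sits too
  close to the year edge the pipeline truncates the bandwidth to fit the
  grid and logs it.

Inference uses classical (homoskedastic) OLS standard errors, 95%
intervals of ±2·SE, and two-sided t tests with `n − p` degrees of
freedom.  Counterfactual-gap intervals are pointwise mean-response
intervals computed from the coefficient covariance (`x·Cov·xᵀ`), not
prediction intervals: the question is whether the *modeled mean* interest
differs, not whether single noisy weeks do.

**Reversion time** is the smallest `t ≥ 1` at which the 2020 and 2019
intervals overlap *and keep overlapping through `t_max`*.  Requiring
sustained overlap prevents a single-week flicker from being called
reversion; runs where the first-overlap and sustained-overlap answers
differ are logged.  `never_differed` (overlap already at t = 1) and
`not_reverted` (still separated at t_max) are reported as distinct
outcomes rather than numbers.

**Share outcome.** Fitting the week-wise share of total food interest
(`outcome="log_share"`) asks whether a category grew relative to overall
food interest rather than in absolute volume; shares of a partition sum
to 1 by construction, which the tests verify.

**Dose-response scale.** The cross-country severity-vs-effect analysis
correlates peak severity with the *log-scale* coefficient α by default.
The model is multiplicative, so the log scale is its natural parameter
space and a linear severity coupling is linear there; correlating the
back-transformed `e^α − 1` (available via `scale="linear"`) mixes the
coupling with the convexity of the exponential.  Outlier exclusion is an
explicit user-supplied list, always recorded in the result, never
inferred.

## Mobility changepoints

The daily residential series is smoothed with a centered 7-day rolling
mean (centered to avoid biasing the detected onset in either direction;
edge days use at least 4 days of window).  The onset is the first day the
smoothed series reaches the +10% threshold, read as an absolute level of
Google's percent-change-from-baseline scale.  The decreased-mobility
period ends at the first *sustained* drop below threshold: sub-threshold
dips shorter than 3 days are ignored (and logged) so that daily noise
around the threshold does not fragment a period; a below-run that reaches
the end of the series counts regardless of length.  Severity is the
maximum of the smoothed series within the period.  Countries whose
mobility barely or never crosses the threshold are retained and reported
(short or absent periods are informative contrast cases, not data
errors).  The cutoff week for the regression is the week containing the
onset date; that week itself is t = 0 and untreated.

## Surplus of interest

A series is standardized by its 2019 mean and sample SD (ddof = 1); the
transform is invariant to positive affine rescalings of the volumes, so
it does not depend on the calibration scale.  Reference weeks are mapped
to the grid as the week containing December 25, 2019 (week 52) and the
week containing the fourth Thursday of November 2019 (week 48).  "First
half of 2020" is weeks 1–26.  The cumulative surplus sums *signed*
z-values (below-baseline weeks subtract), reading "total surplus" as a
net quantity, and the peak is the raw weekly maximum, unsmoothed; both
choices were genuinely open and are centralized in `metrics.py`.

## Correlations

Weekly mobility (mean of available daily values per week) is correlated
with the year-over-year relative interest change using Spearman rank
correlation with average ranks for ties; the default window is the first
full week of February through the end of December 2020 (weeks 6–51, 46
weeks).  Significance is the two-sided t test
`t = ρ·√((n−2)/(1−ρ²))`.  No multiple-comparison adjustment is applied
anywhere; the study manifest records the total number of tests run so a
reader can apply their own.

## The synthetic generator

The generator exists so that every downstream stage has a ground truth.
Interest series are lognormal-multiplicative: a log-scale baseline,
optional linear trend, holiday bumps applied identically in both years,
and a post-cutoff shock `α + β·t + γ·t²` added only in 2020, plus
Gaussian noise on the log scale.  Because both years share the seasonal
component and the shock is exactly the fitted interaction block, the
generative model is *nested* in the regression: a noiseless series is
recovered with zero residuals and the injected (α, β, γ) are returned to
machine precision — the basis of the exact-recovery tests.  Noise is
lognormal (Gaussian on the log scale) by our choice, matching the fitted
error model so that CI-coverage tests are well specified.

Mobility series are a smoothstep rise to an exact peak, a plateau, a
smoothstep recovery, an optional second wave, and Gaussian noise.  The
multi-country panel spreads severities evenly over a range (default
10.1–31.6%, spanning mild to severe lockdowns) and couples each country's
base shock linearly to severity on the log scale
(`α = slope·severity/100`, default slope 2.0, i.e. roughly +20% interest
per 10 points of severity — mid-range for the effect sizes this kind of
data shows); access-mode groups receive sign-flipped multiples of the
base shock (home cooking and delivery up, eating out down).  The panel's
interest cutoff is the week the country's noiseless mobility first
reaches +10%, i.e. the same event the changepoint detector estimates, so
recorded truth and pipeline output refer to the same quantity.

What the generator does **not** emulate: search-volume integer rounding
and renormalization, calibration error between entities, week-53
artifacts, data gaps, holidays that shift between years, and
non-lognormal noise.  Passing tests therefore demonstrate correctness of
the estimator and pipeline mechanics under the stated model, not
robustness to every artifact of real search data.

## Problem sizes and numerics

Test and acceptance runs use deliberately small problem sizes chosen to
exercise every code path: 82-row designs, 500-replicate coverage runs,
1000-replicate null calibration at n = 46, 18-country noiseless
dose-response panels, and 6-country noisy end-to-end studies.  OLS is
solved via statsmodels (SVD/pinv); test oracles re-solve the normal
equations independently in extended precision.  Exact-recovery
assertions use 1e−8 absolute tolerance on coefficients; identity-type
invariants use 1e−9 to 1e−12.  Degenerate inputs fail loudly: zero 2019
variance, zero volumes in a fit window, rank-deficient designs, empty
aggregation lists, and non-positive surplus reference weeks are all hard
errors naming the offending series or week.

## Known limitations

* The design estimates the effect of *whatever changed at the cutoff*;
  attributing it solely to mobility assumes no other country-level shock
  at the same week, which no statistical control here can guarantee.
* Classical SEs ignore weekly autocorrelation of residuals; with 82
  observations and a local window this follows the original inference
  convention but likely understates uncertainty somewhat.
* Reversion times are resolution-limited: with small noise the CIs are
  narrow and reversion is detected late; with large noise, early.  The
  acceptance check therefore compares against an oracle computed from the
  same noise level.
* The 2×2 access-mode grouping and the category taxonomy are taken as
  given from the catalog file; building them is out of scope.
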