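# Methods

## Scientific setting

Obstructive sleep apnea (OSA) severity varies night to night, and high
ambient temperature raises the probability that a given night crosses the
clinical thresholds (AHI >= 15 for moderate-to-severe, >= 30 for severe).
`heatosa` implements the full chain from a nightly panel of OSA indicators
to the health and economic burden attributable to warming:

1. a distributed-lag non-linear **case-time-series model** estimating the
   cumulative temperature/OSA association;
2. **attribution** of each day's excess risk relative to a 1950–1990
   climatology;
3. **burden accounting**: years of life lost (YLL) through the
   OSA/motor-vehicle-accident mortality pathway, years lived with
   disability (YLD), DALYs, a wellbeing cost, presenteeism/absenteeism
   days and labor loss, with scenario projection to 2100.

## The case-time-series model

Nights are grouped into participant x calendar-year x calendar-month
strata. Each stratum receives its own intercept, absorbing individual
baseline risk and shared long-term trends; identification of the
temperature effect comes from within-stratum variation only. With a log
link, the Poisson likelihood profiles the stratum intercepts analytically,
leaving

    l(beta) = sum_i y_i x_i'beta - sum_s Y_s log( sum_{i in s} exp(x_i'beta) ),

the multinomial (conditional) form. Strata with zero outcome total carry no
information and are dropped. The binary nightly outcome enters the Poisson
likelihood directly — the standard absorbing choice for this design at low
nightly probability — so coefficients are log *risk* ratios under a
log-linear model for the outcome probability. A separate odds-ratio to
risk-ratio converter (RR = OR / (1 - p0 + p0 OR)) is provided for
summarising odds-scale fits against the same baseline risk.

The temperature term is a cross-basis: a natural cubic spline in
temperature (default 4 df; internal knots at the 25th/50th/75th exposure
percentiles, boundary knots at the observed min/max) crossed with one
indicator per lag day over lags 0–4. Exposure on calendar day *d* predicts
the night beginning on day *d*; lag *l* uses day *d − l*. The indicator lag
basis makes the cumulative association an exact column-group sum:
logRR(t) = sum_l sum_j beta_{jl} (b_j(t) − b_j(ref)). The reference
temperature defaults to the 25th percentile of the fitting data. Adjustment
terms: a 4-df day-of-year spline, day-of-week indicators (Monday
reference), and a 4-df natural spline per continuous covariate (cloud
cover, relative humidity, surface pressure, precipitation, wind speed,
PM2.5, and within-user deviation of total sleep time). Tie-heavy
covariates (zero-inflated precipitation) degrade gracefully to fewer df.

Numerics: Newton–Raphson on the profiled likelihood with step-halving;
convergence when the maximum absolute score falls below 1e-8 or the
relative log-likelihood change below 1e-10; 100 iterations maximum, with
non-convergence reported, never silent. Coefficients exceeding 50 in
absolute value trigger a separation warning. Collinear adjustment columns
are removed by pivoted-Cholesky rank detection on the column Gram matrix
(numerically equivalent to pivoted-QR rank on the design, at k x k cost);
removal of a cross-basis column is an error, not a repair. The covariance
is the inverse observed information of the profiled likelihood.

### Known conservatism of the confidence intervals

For a binary outcome the Poisson variance exceeds the Bernoulli variance
by the factor 1/(1 − p), so model-based standard errors are inflated by
about 1/sqrt(1 − p0) (~15% at p0 = 0.25) and 95% CIs over-cover (empirical
null coverage is roughly 97–99% rather than 95%). This matches the
published modelling choice this package mirrors; the conservatism is in
the safe direction and is asserted (no undercoverage, spread of
truth-centred z-statistics within ~25% of standard normal) rather than
"corrected" with a robust variance.

## Natural cubic splines

The spline basis is the classical natural construction: a cubic B-spline
basis on the given knots, constrained to zero second derivative at the
boundary knots (via a QR projection of the curvature constraints), with
the constant removed from the span — intercepts live in the strata — and
linear extension beyond the boundaries. A basis with k internal knots has
k + 1 columns, so "4 df" means three internal knots. The construction is
validated against a textbook tridiagonal natural-spline interpolation
solve (agreement to 1e-8) and against a double-loop cross-basis oracle
(1e-12).

## Attribution and burden

For a target year, the fitted curve is evaluated (interpolating on the RR
scale) at each day's temperature and at the 1950–1990 day-of-year mean;
the difference RR(T_d) − RR(Thist_d) is the daily excess risk. Feb 29 is
dropped everywhere, so every year contributes exactly 365 values.
Temperatures outside the curve's grid are clipped to the grid ends (flat
extrapolation), with the clipped-day count logged — scenario temperatures
can exceed anything observed during fitting, and the flat tail is the
conservative choice.

The burden formulas are implemented exactly in their published
annual-mean form (see `heatosa.burden`), including the (1/365)-sum with a
per-day motor-vehicle-accident death rate in the YLL equation. Read
literally, that combination yields a daily-scale death flow multiplied by
residual life expectancy; we implement the formula as printed and do not
"correct" the dimensional reading — users supplying their own country
table control the rate's scale. Bounds: YLL varies RR_MVA over
(0.5, 1.0, 1.5); YLD varies the disability weight over (0.05, 0.08, 0.11)
with a 1-day impairment duration; the wellbeing cost values a DALY at
(1, 2, 3) x GDP per capita applied to the mean DALY; presenteeism (6.8%)
and absenteeism (2.1%) days use 235 working days per year and a labor
force down-weighted by half the part-time share. Because every output is
linear in the varied parameter, bounds are exact ratios of the mean —
which is also how the published worked numbers (e.g. a YLL lower bound of
exactly half the mean) arise. Productivity outputs propagate the curve's
uncertainty instead, by evaluating the pipeline at the curve's 95% CI
envelope; the published mechanism for those bounds is unstated, and this
is the package's choice.

Scenario projection chains attribution and the formulas per year. The
primary mode fixes prevalence and population at base-year values; the
sensitivity mode applies a population forecast and ramps prevalence
linearly to 1.3x between 2023 and 2050 (constant after).

## The synthetic-data generator

Real inputs (a proprietary under-mattress sensor panel, reanalysis
weather, climate-scenario ensembles) are emulated at desk scale:

* **Weather** — daily mean temperature as annual mean + seasonal sinusoid
  (peak mid-July) + stationary AR(1) noise + linear trend; min/max are
  mean -/+ a fixed 4 degC diurnal half-range; simple covariate series
  (cloud, humidity, pressure, precipitation, wind, PM2.5). The validation
  climate (mean 13.2 degC, amplitude 10.3, noise sd 2.8) was calibrated
  once so the generated 25th/99th temperature percentiles sit near the
  6.4/27.3 degC contrast the analyses quote.
* **Cohort** — nightly indicators drawn with a multiplicative (log-link)
  model: baseline nightly probability 0.254 (0.089 severe, matching the
  observed severity distribution), log-normal user heterogeneity
  (sd 0.25), small seasonal and day-of-week terms, and a cumulative
  4-day-lag temperature effect. The exposure transform lives in the same
  natural-spline space the fitter uses (a smooth softplus heat-response
  shape projected onto the basis), so the model class contains the truth
  and recovery is exact in expectation; a piecewise-linear truth outside
  the model space is available for misspecification checks. The lag-effect
  vector is calibrated in closed form so the generative cumulative
  RR(27.3 vs 6.4) equals any requested value exactly. Severe and
  moderate indicators are drawn from one uniform per night, so severe
  nights are a subset of OSA nights. Per-user random streams mean
  enlarging the cohort never perturbs existing users.
* **Missingness** — total sleep time is Normal(7.4, 0.8) h; nights under
  5 h lose their AHI-based indicators. An optional temperature-dependent
  mode shifts sleep down on hot days first (slope 0.05 h/degC above
  25 degC — a free parameter of the emulation, not an estimate), to
  exercise missingness-bias sensitivity analyses.
* **Leap days** are generated; climatology and attribution drop Feb 29.

What the generator does *not* emulate: real geography and station
weather, device measurement error, behavioural confounding (e.g. alcohol,
air conditioning), country heterogeneity in effect sizes. Passing
recovery tests therefore demonstrates correctness of the estimator under
the stated generative model, not robustness to everything real panels
contain.

## Validation study sizes

Estimator recovery uses 20 replicates of 2,000 users x 365 nights
(~730k nights per replicate) per outcome, with truths 1.45 (AHI >= 15)
and 1.49 (AHI >= 30); the median estimate must fall within 0.05 of the
truth and the CI must cover it in >= 18/20 replicates. Null coverage uses
100 replicates of 50 users x 365 nights. These sizes give Monte Carlo
error well inside the asserted tolerances while keeping the whole suite
runnable on a single CPU.

## Limitations

* Curves exported to CSV carry pointwise variances only; contrasts between
  two non-reference temperatures need the in-session covariance (or an
  external covariance supply) and are refused otherwise.
* The conditional-Poisson CIs are conservative for binary outcomes (above).
* The burden formulas inherit the published dimensional conventions; the
  YLL magnitude depends directly on the scale convention of the supplied
  motor-vehicle-accident death rate.
* No DALY discounting or age-weighting; no currency or inflation
  adjustment; climate-model ensembling is upstream of this package.
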