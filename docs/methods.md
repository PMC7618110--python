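# Methods

`tempmort` implements a two-stage time-series analysis of the
short-term association between daily mean temperature and all-cause
mortality, and converts the pooled associations into minimum mortality
temperatures (MMT) and cold/heat attributable burdens. The design
follows the standard multi-location workflow of environmental
epidemiology: distributed-lag non-linear models (DLNM) per location,
multivariate random-effects meta-regression across locations, best
linear unbiased predictions (BLUP), and backward attribution with
Monte-Carlo empirical confidence intervals.

## Stage 1: per-location quasi-Poisson DLNM

For location *i* with daily deaths `y_t` and daily mean temperature
`x_t`, the model is

    y_t ~ quasiPoisson(mu_t),
    log mu_t = alpha + cb(x_t, ..., x_{t-L}) + ns(t; df/yr x years)
               + DOW_t + gamma * RH_t [+ delta * PM2.5_t]

* **Cross-basis** `cb`: tensor product of an exposure basis (cubic
  B-spline, interior knots at the location's own 10th/75th/90th
  temperature percentiles, boundary knots at the observed range, first
  column dropped against the model intercept) and a lag basis (natural
  cubic spline over integer lags 0..L with an intercept column; 2
  interior knots for L = 7, 3 for L >= 14, placed equally spaced on
  the log-lag scale). Columns are var-major. The first L days are
  dropped from the likelihood rather than padded.
* **Seasonality**: natural cubic spline of the day index with
  `round(df_per_year x years)` total df (default 6/yr; 4 and 8
  available for sensitivity analyses), knots at equally spaced
  quantiles of the day index.
* **Day of week**: six indicators, Monday reference (the choice is
  immaterial to the curves; fixed for reproducibility).
* **Humidity**: same-day linear term (a moving average would also be
  defensible; the linear same-day term is the simplest reading of
  "linear control" and is what we fix). PM2.5 enters the same way
  when enabled.

Estimation is IRLS to the Poisson likelihood (coefficients equal the
Poisson MLE), convergence when the largest coefficient update falls
below 1e-9 or 50 iterations. The quasi-Poisson dispersion
`phi = Pearson X^2 / (n - p)` scales the covariance. Missing days are
dropped from the likelihood while lags remain on the calendar grid, so
histories never silently skip days.

The fitted cross-basis coefficients are reduced to the **overall
cumulative exposure-response** by the linear map that sums the lag
basis over integer lags: `coef_red = M coef`, `V_red = M V M'` with
`M = I (kron) (1' C)`. Curves are fit uncentred; all reported log-RRs
are differences `b(x) - b(ref)`, which are invariant to any internal
centering, so re-centering at the MMT happens at prediction time.

## Stage 2: multivariate meta-regression

Reduced coefficient vectors `theta_i` (dimension q = 6 by default)
with covariances `S_i` are pooled under

    theta_i ~ N(X_i beta, S_i + Psi),  X_i = z_i' (kron) I_q,

where `z_i` holds seven location-level meta-predictors (average
temperature, temperature range, population-weighted latitude and
elevation, population density, average relative humidity, and a
multidimensional poverty index) plus an intercept. `Psi` is estimated
by REML (default; ML and a one-step moment estimator are available)
over a Cholesky parameterization, quasi-Newton (L-BFGS-B) from the
documented start `Psi0 = 0.1 x mean(S_i)`, gradient tolerance 1e-8.
Meta-predictors are standardized internally and effects
back-transformed. Per-predictor Wald chi-square statistics use that
predictor's q x q block of the GLS covariance; heterogeneity is the
multivariate Cochran Q at the fixed-effects-only fit with
`df = (k - p) q` and `I2 = max(0, (Q - df)/Q) x 100`.

Coefficients estimated on location-specific percentile knots are
pooled as-is: each location's curve lives on its own temperature
scale, and the meta-model pools the *shape* relative to that scale.
This mirrors the standard two-stage practice and is the reason pooled
curves are always re-expressed per location before interpretation.

BLUPs shrink each location toward its meta-regression prediction:
`blup_i = pred_i + Psi (Psi + S_i)^{-1} (theta_i - pred_i)`, with the
conditional covariance plus propagated fixed-effect uncertainty.

## MMT and attributable burden

The MMT is the arg-min of the (un-centered) BLUP curve over the
location's empirical temperature percentiles 1..99 (ties broken toward
the median percentile; minima at percentile 1 or 99 are flagged as
boundary solutions — monotone curves are a real phenomenon, observed
MMPs in comparable studies span the whole 1..99 range). No
sub-percentile refinement is applied.

Backward attribution converts each day's exposure history into
attributable deaths:

    AN_t = y_t (1 - exp(-eta_t)),
    eta_t = (1/(L+1)) sum_{l=0..L} f(x_{t-l}),

with `f` the BLUP overall cumulative log-RR re-centered at the MMT.
A reduced curve does not identify lag-specific contributions, so the
cumulative effect is apportioned equally across the L+1 lags (the
convention of backward-attribution software in this field); for
constant exposure over the window the formula is exact. Days with
incomplete history contribute zero and are counted; days exactly at
the MMT are assigned to neither cold nor heat and are zeroed, which
makes `AN_total = AN_cold + AN_heat` an exact identity. Attributable
fractions divide by the location's total observed deaths. Percentile
bands (1/5/10 below, 90/95/99 above) sum days beyond those
temperature percentiles.

**Confidence intervals** are empirical 2.5th/97.5th percentiles over
coefficient redraws re-run through the attribution. Two design points
deserve emphasis:

1. *Joint sampling across locations.* The pipeline draws one
   fixed-effect vector per replicate, shared by all locations, and
   adds independent location disturbances through the shrinkage map
   (`curve_{i,s} = A_i (theta_i + eps_{i,s}) + (I - A_i) X_i' beta_s`).
   When between-location heterogeneity is small, every BLUP collapses
   onto the pooled curve and their errors are almost perfectly
   correlated; sampling locations independently would understate the
   width of any aggregate (country-level) interval by up to sqrt(k).
   In calibration experiments on synthetic data the joint ensemble
   restores near-nominal coverage of country-level attributable
   fractions where independent draws covered far below nominal.
2. *Fixed reference per redraw.* Redraws are centered at the
   point-estimate MMT. Re-locating each redraw's own minimum
   (`mmt_per_draw=True`) is available but not the default: the minimum
   of a noisier redraw is more downward-biased than the point
   estimate's, which shifts the whole percentile interval upward.
   Relatedly, the point estimate itself carries a small upward bias
   because the curve value at the *estimated* minimum undershoots the
   value at the true minimum; the bias shrinks with per-location
   information (series length x death counts) and is negligible at
   the default study scale, but grows if series are shortened.

`n_sim` defaults to 1000; a seed is mandatory.

## Preprocessing

Relative humidity derives from 2 m temperature and dewpoint via the
August-Roche-Magnus approximation `e_s(x) ∝ exp(a x / (b + x))` with
a = 17.625, b = 243.04 degC (one of several published constant sets;
configurable). RH is computed hourly and then averaged to the local
day (UTC-5 by default) — the formula is nonlinear, so mean-of-RH and
RH-of-mean differ, and the former is fixed as the definition. Days
observing fewer than 75% of expected hours are marked missing.
Spatial averaging of gridded reanalysis fields over administrative
polygons is out of scope; the loader documents the pre-extracted
long-format file it consumes.

## Synthetic data generator

The generator emulates the structure of a national vital-statistics /
reanalysis study: 32 locations, 10 years of daily data, location mean
temperatures spanning 12.4-28.2 degC with weak seasonality (amplitude
1.5 degC, near-equator) and AR(1) day-to-day noise (rho = 0.7, sd
1.5 degC); baseline daily death rates log-uniform between 3 and 70
(integrating to ~2.5 million deaths, the scale of the study period);
mild day-of-week effects and a slow trend; negative-binomial counts
parameterized day-by-day so the realized variance is exactly
`phi x mu` (default phi = 1.3; quasi-Poisson has no generative form,
so the gamma-Poisson mixture is the standard stand-in).

The true risk surface is piecewise quadratic in temperature with its
minimum at a chosen percentile of the location's own distribution
(default 25th), anchored by the cumulative log-RR at the 99th (heat,
default 0.12) and 1st (cold, default 0.04) percentiles. The default
cold anchor is ~0.3x the heat anchor so the two limbs have matched
curvature at the minimum: an unmatched kink makes the arg-min of the
*best possible* smooth approximant sit several percentiles away from
the true minimum, i.e. the MMP would be unrecoverable by any
spline-based fit — a property of the target, not of an estimator.
Heat and cold limbs carry separate normalized lag profiles (acute
exponential decay for heat, a gamma-shaped slowly-emerging profile
over 0..28 days for cold, uniform for calibration experiments), which
reproduces the qualitative finding that longer lag windows reveal
cold burden while heat stays stable. Between-location heterogeneity
acts log-normally on the limb heights, optionally tied to the
elevation covariate.

Truth (curves, MMT, attributable numbers) is computed by direct
arithmetic on the generated exposure histories — never through the
fitting code — with a burn-in long enough that every emitted day has a
complete truth history. The generator does **not** emulate spatially
correlated climate across locations, demographic structure,
cause-specific mortality, reporting artifacts, or data gaps; passing
tests therefore demonstrate statistical correctness of the machinery
under the stated model, not robustness to those real-data features.

## Problem sizes in the test suite

The test suite runs recovery experiments at sizes chosen to keep the
full suite in the tens of minutes on one CPU: MMP recovery uses 25
replicates of the full 32 x 10-year preset; interval coverage uses 100
replicates at 16 locations x 10 years (the 10-year span is retained
because shortening series, not dropping locations, is what inflates
the minimum-centering bias); Wald calibration uses 500 scalar-outcome
replicates. The acceptance script runs one full-scale end-to-end
replicate.

## Known limitations

* The MMP estimate is intrinsically noisy when the pooled curve is
  nearly flat on one side of its minimum (the typical J-shape):
  even at full study scale its sampling scatter spans several
  percentiles with a slight drift toward the flat side, and because
  the pooled coefficients are shared, taking the median across
  locations does not average it away. Curves should be read together
  with their uncertainty, not through the MMT point alone.
* Attributable-fraction point estimates inherit the upward
  minimum-centering bias described above when per-location information
  is scarce.
* The reduced-curve backward attribution assumes the equal-lag
  apportionment; under strongly peaked lag structures and rapidly
  varying exposure it is an approximation.
* `I2 = 0` is only guaranteed in the exact homogeneity limit; sampled
  homogeneous data give small positive values about half the time, by
  construction of the truncated estimator.
* The `mm` meta-estimation method is a crude moment start, not a
  substitute for REML.
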