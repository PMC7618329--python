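# Methods

`aqhimix` builds a mortality-anchored multi-pollutant air quality health
index (AQHI) from city-level daily time series and evaluates it against
threshold-based comparator indices. This note describes the statistical
models, the numerical choices behind them, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Exposure metric

All risk models use the lag 0–2 day moving average of each pollutant's
daily concentration (the mean of the same and the two preceding days) as
the operational short-term exposure, reflecting the empirical finding that
acute mortality effects concentrate in the first three days after
exposure. Moving averages propagate missingness: a day whose window
contains any missing measurement is excluded from model rows rather than
renormalised, mirroring the exclude-missing-days rule used with monitored
data.

## First-stage city models

### Single-pollutant DLNM

Per city and pollutant, daily deaths are modelled by quasi-Poisson
regression (log link; Poisson point estimates, covariance inflated by the
Pearson dispersion χ²/(n−p)) on a distributed-lag non-linear cross-basis:
the tensor product of

* an exposure-dimension natural cubic spline with two internal knots at
  the city's 25th/75th concentration percentiles, and
* a lag-dimension natural cubic spline over lags 0–7 on the log(lag+1)
  scale, two internal knots equally spaced, plus an intercept
  (3 × 4 = 12 columns by default).

The log(lag+1) convention handles lag 0 on the log scale; the +1 offset is
a documented choice. Confounders in every model: a natural cubic spline of
time with 7 df per year (prorated by series length, minimum 3), day-of-week
indicators (six dummies against a Monday baseline), and natural cubic
splines of the 8-day moving averages of temperature (6 df) and relative
humidity (3 df). Natural bases are evaluated on boundary-normalised
coordinates (an affine reparameterisation) so that long day indexes do not
produce ill-conditioned cubic columns.

The scalar per-µg/m³ log relative risk β_k feeding the single-pollutant
death risk function comes from a companion model in which the cross-basis
is replaced by one linear term on the lag 0–2 moving average: the
exponential death-risk formula presumes a constant per-unit coefficient,
which the non-linear DLNM does not supply directly. The DLNM is retained
for exposure-response and lag-response summaries.

### Multi-pollutant model (CGAIM)

The constrained groupwise additive index model estimates, per city,

    log mu_t = confounders_t + g(z_t),    z_t = Σ_k w_k x_kt,

with w on the simplex (w_k ≥ 0, Σ w_k = 1) and g nondecreasing. Fitting
alternates:

1. **Ridge function.** With w fixed, g is expanded in a degree-3 I-spline
   basis (five interior knots at index quantiles) with nonnegative
   coefficients — every such combination is nondecreasing — and fitted
   jointly with the unconstrained confounders by IRLS; each iteration
   solves a partially nonnegative weighted least squares (confounders
   projected out via QR, then NNLS on the residualised working response).
2. **Weights.** With g fixed, the linearised working model depends on w
   through g′(z)·x_k; the simplex-constrained weighted least-squares
   update is a small quadratic program (solved with SLSQP), followed by
   backtracking on the *profile* quasi-deviance (refitting g for each
   candidate) so the objective never increases across alternations.

The alternation starts at the constrained-linear estimate — an IRLS/NNLS
fit of log mu = confounders + Σ_k θ_k x_kt with θ ≥ 0, normalised to the
simplex — which is a consistent weight estimator when g is increasing.
Starting at an uninformative uniform point instead lets the alternation
drift to arbitrary simplex corners whenever the profile deviance is flat,
which is the typical regime for single-city daily mortality data.
Convergence is declared when the largest weight change falls below 1e-5 or
the profile deviance improves by less than 1e-7 (relative); the alternation
caps at 50 cycles.

Weights are estimated directly on the raw µg/m³ scale, because the
multi-pollutant death risk function applies them to raw concentrations.
For conditioning, all four exposures are divided by one *common* factor
(the mean of their within-city standard deviations); common scaling leaves
simplex weights exactly invariant. Per-pollutant standardisation with a
post-hoc remap (w_k ∝ w̃_k/sd_k) was rejected: with weak per-city signal
the remap inflates the estimation noise of low-variance pollutants, and
after nonnegativity clipping this biases their pooled weights upward.

The index slope β_c for the death risk function is a quasi-Poisson refit
with a single linear term on the fixed fitted index — the death-risk
formula is linear in the index, so a scalar slope is the natural reading
even when the fitted g is curved. Weight uncertainty comes from a
moving-block bootstrap (blocks of 30 days over complete-case rows,
preserving short-range serial dependence). Each replicate is refitted from
its own constrained-linear initialisation rather than warm-started at the
point estimate: on flat profile deviances warm-started replicates stay
near the start and the covariance badly understates the weight
uncertainty. Identical pollutant columns make weights non-identifiable, in
which case the QP's solution is reported and flagged by the bootstrap's
spread.

## Second-stage pooling

City estimates are pooled by random-effects meta-analysis. Scalars use the
DerSimonian–Laird moment estimator of the between-city variance τ²
(floored at 0; REML available by scalar optimisation of the restricted
likelihood). Coefficient vectors (spline blocks) are pooled with full
within-city covariances and a diagonal between-city covariance estimated
component-wise. Compositional weight vectors are pooled component-wise and
projected back onto the simplex (clip at 0, renormalise); no log-ratio
transform is applied because weights may be exactly 0. Countries with one
city pass their estimates through with a logged notice.

## Index construction

Death risk functions at concentrations x (µg/m³):

* single-pollutant: DRF = 100 · Σ_k (exp(β_k x_k) − 1)  (percent scale),
* multi-pollutant:  DRF = β_c · Σ_k W_k x_k.

Either DRF is rescaled to the 1–10+ AQHI so that the index is exactly 3
where the WHO 2021 short-term guidelines are met (PM2.5 24-h 15, O3 8-h
100, NO2 24-h 25, SO2 24-h 40 µg/m³, overridable):

    AQHI = max(1, round_half_up(3 · DRF / DRF_WHO)).

Round-half-up and the floor at 1 are explicit choices; the published
description fixes only the anchor and the 1–10+ range. Categories: low
(1–3), moderate (4–6), high (7–10), very high (>10). The multi-pollutant
DRF is unit-dependent before scaling, so unscaled DRF values are not
comparable across countries; the anchor removes this for the index itself.

Comparator AQIs use versioned breakpoint tables shipped as CSV resources:
EPA (pre-2024 and 2024 PM2.5 dialects; gas breakpoints in ppm/ppb are
applied after converting µg/m³ inputs at 25 °C/1 atm, with the tables'
truncation rules), the EEA European index bands 1–6, and the HJ 633-2012
IAQI with its round-up rule. The overall index is the worst per-pollutant
sub-index; concentrations beyond a table's top interval extend the last
segment's slope (the "500+"/"300+" reading).

## Utility validation

Each city's series is split by time (default early 70% train / late 30%
test; train strictly precedes test, enforced inside the pipeline). Index
parameters are estimated on the training part only; indices are computed
on the test part; each index's utility is the pooled percent change in
mortality per IQR increase, from city-level quasi-Poisson regressions with
the standard confounders. IQRs are computed on test-set index values
(utility is evaluated where it is measured), either pooled overall or per
country. Non-linear index-response curves replace the linear term with a
natural cubic spline whose knots sit at the 25th/75th index percentiles
averaged across cities (boundaries likewise averaged so that city bases
coincide and can be pooled multivariately); curves are reported relative
to the low end of the common range. Cities whose test segment is shorter
than 365 days are excluded from pooling with a warning.

## Synthetic data

The generator emulates the structure of a multi-city daily panel:

* **Exposures:** lognormal daily concentrations (the canonical model for
  ambient pollutants) with an annual cycle on the log scale (PM2.5/NO2/SO2
  peaking mid-January, O3 mid-July), correlated AR(1) innovations
  (autocorrelation 0.6; latent correlations 0.1–0.4), log-scale sds
  0.55/0.30/0.45/0.65 for PM2.5/O3/NO2/SO2, and per-city mean levels drawn
  log-uniformly from the cross-country ranges seen in multi-country
  monitoring data (PM2.5 15–90, O3 60–120, NO2 10–60, SO2 3–50 µg/m³).
* **Weather:** sinusoidal temperature (peak July) and humidity with AR
  noise, humidity clipped to [0, 100].
* **Deaths:** negative-binomial (gamma-Poisson) counts calibrated to a
  Pearson dispersion of ≈1.3 around baseline 60/day, with a slow log-linear
  trend, day-of-week effects, a U-shaped same-day temperature term, and the
  pollutant effect: either a linear effect (default 6×10⁻⁴ per µg/m³) of
  the weighted lag 0–2 index with true weights (0.35, 0.35, 0.20, 0.10),
  or per-pollutant lag-distributed effects. Non-intercept terms are
  centred so the realised mean matches the baseline.
* **Heterogeneity and missingness:** city slopes jittered with sd 5×10⁻⁵,
  weights with logistic-normal sd 0.05; missing-completely-at-random
  pollutant gaps at 4.0/2.1/1.9/5.3% (PM2.5/O3/NO2/SO2).

One master seed drives everything; city streams derive deterministically
from the city index. The generator does **not** emulate spatial
correlation between cities, chemical coupling between pollutants,
measurement error, mortality displacement, or non-stationary pollution
policy shifts — so passing recovery tests demonstrate correctness of the
estimation machinery under the stated data-generating process, not
robustness to everything real data can do.

### What parameter recovery can and cannot show

Under these study conditions the per-city Fisher information on the
individual pollutant coefficients θ_k = β_c·W_k is small: the unconstrained
Poisson-GLM oracle yields per-city t-ratios of roughly 0.3–2 for a 5-year
city at baseline 60 deaths/day and slope 6×10⁻⁴. Pooling eight such cities
leaves component-wise weight uncertainties of about ±0.1–0.3 (worst for
SO2, whose true per-µg/m³ contribution is far below its measurement
noise). Tight recovery of all four weights therefore requires panels of
hundreds of city-years × cities; the package's recovery tests assert the
bounds that the information budget supports (slope within sampling error,
weight constraints, dominant-pollutant identification under strong
signal), and the full-panel weight-recovery check documents the attainable
accuracy honestly rather than loosening itself.

## Problem sizes used in the test suite

Property checks run at deliberately modest sizes chosen to exercise the
statistics, not the hardware: 200 three-year cities for bias/coverage of
the linear coefficient, 200 replicates for the null type-I-error
calibration of the utility CI, an 8-city × 5-year panel for the two-stage
recovery check (bootstrap 50 replicates per city), and 3–10-year single
cities elsewhere.

## Numerical choices

* Natural cubic bases use the truncated-power construction with natural
  constraints, evaluated on boundary-normalised coordinates; regression of
  any function in the span reproduces it to ~1e-10.
* Rank checks via QR with relative tolerance 1e-8 on |diag(R)|.
* IRLS linear predictors are clipped at ±30 to guard exp overflow.
* Weights below 1e-6 are reported as exactly 0 and the simplex
  renormalised.
* Spline imputation of pollutant gaps fits a natural spline of time to the
  observed days (7 df/year, minimum 3) and floors predictions at 0.
* DL τ² is floored at 0; Q ≤ df implies τ² = 0 exactly.

## Limitations

* A scalar β_c summarises a possibly curved monotone dose-response; when g
  is strongly curved the linear refit is an approximation (the same
  approximation the death-risk formula itself makes).
* Weight pooling by clip-and-renormalise is simple and transparent but not
  a compositional-data method; with many exact-zero city weights it can
  shrink small components.
* The EPA table applies 1-h gas breakpoints to the daily metrics carried
  in the data schema, as index calculators routinely do when only daily
  summaries exist; absolute AQI-USA levels for NO2/SO2 are therefore
  conservative.
* Single-city "countries" pass through unpooled; their uncertainties are
  city-level, not country-level.
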