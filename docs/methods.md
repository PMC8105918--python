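# Methods

## Data model

A study is a dense grid of (areal unit × calendar day) exposure and
meteorology records with outcome counts on weekdays only (primary-care
systems record on working days; public holidays are treated as ordinary
weekdays). Counts missing on weekends are encoded as empty cells, never 0:
zero is a legitimate observation under a zero-inflated count law. Each
unit carries two time-invariant covariates, the percentage of residents
aged ≥65 and a deprivation score.

## Exposure decomposition and lags

For pollutant concentration `X_it` the long-term exposure of unit *i* is
its mean `X̄_i` over **all calendar days** of the study and the short-term
exposure is the deviation `D_it = X_it − X̄_i`. The decomposition is an
exact additive identity; per-unit deviation means vanish to float
precision. Means use all calendar days because lagged deviations need
weekend exposure values even though outcomes are weekday-only: lags act on
calendar days (a Monday's lag 1 is Sunday), and the week average spans the
index day plus the six preceding calendar days. A weekday-only shifting
variant (`LagSpec(..., calendar_days=False)`) is provided for sensitivity;
calendar-day is the default because pollution exists on weekends. Rows
whose lag history is incomplete are dropped from model fitting.

Lagging is applied to the deviations with the unit mean untouched:
lagging a constant reproduces the constant, so this equals lagging raw
exposure and then decomposing, and keeps the two terms orthogonal in
expectation.

## Design matrices

The count-part design has labelled columns: intercept; the pollutant's
short-term (lagged deviation) and long-term (unit mean) terms; natural
cubic splines of same-day temperature (3 df) and relative humidity (3 df);
a natural spline of the sequential day index with `round(6 × study years)`
df (30 over five years), knots at equally spaced quantiles; day-of-week
dummies with Monday as the (arbitrary, documented) reference — the column
set follows the days actually observed, so a weekday-only panel yields 4
dummies and a full week 6; and the two unit covariates. Two-pollutant
models add the co-pollutant's short-term term at the same lag plus its
long-term mean (adjusting both axes of variation; whether the long-term
term belongs is genuinely open, so a flag can drop it). Meteorology enters
at lag 0 only.

Natural splines are built from a cubic B-spline basis projected onto the
null space of the boundary second-derivative constraints (the classical
construction); evaluation outside the boundary knots extrapolates
linearly. A rank check (SVD condition < 1e8 after column scaling) rejects
degenerate designs and names the dependent columns via pivoted QR. Note
that a panel needs more units than unit-level columns (intercept,
long-term mean, two covariates) for the design to be identifiable.

## The mixed ZINB model

Observation model, with `π = logistic(γ₀)` shared across unit-days and an
intercept-only zero part (no random effect in the zero component — the
default of standard mixed-ZINB fitters, and nothing in the design argues
for zero-part covariates here; a mirror switch exists for exports):

    y_it ~ π δ₀ + (1 − π) NB(μ_it e^{b_i}, θ),   b_i ~ N(0, σ_b²)

NB is mean/dispersion parameterized, variance `μ + μ²/θ`, one scalar θ per
model. The marginal likelihood integrates each unit's `b_i` by **adaptive
Gauss–Hermite quadrature** (15 nodes by default, odd so one node sits at
the mode): nodes are recentred at the per-unit conditional mode (found by
a damped, vectorised Newton iteration) and rescaled by the curvature
there. Adaptivity matters because hundreds of observations per unit make
the integrand sharply peaked; non-adaptive rules would need far more
nodes. `σ_b ≤ ~1.5e-6` is integrated analytically (degenerate at zero).
Log-gamma differences `lgamma(y+θ) − lgamma(θ)` are computed by the exact
log recurrence for the small counts that dominate these panels, which
stays accurate even at θ = 1e8 where direct `gammaln` differences cancel
catastrophically.

Fitting maximizes the marginal likelihood by L-BFGS-B over
(β, γ₀, log θ, log σ_b), with log σ_b box-bounded below at log(1e-6).
Covariates are internally standardized (exactly invertible, including the
covariance). Gradients are analytic with quadrature nodes held fixed at
the current modes; the dropped node-motion terms are at quadrature-error
level (a unit test confirms agreement with central differences to 1e-6),
and a numeric-gradient polish runs whenever L-BFGS-B reports
non-convergence. Initialisation: β from a Poisson GLM, γ₀ from the
observed zero excess (floored at 0.01), θ from method-of-moments on
Poisson residuals, σ_b from the between-unit spread of residual log
rates. Standard errors come from the inverse observed information
(central differences of the gradient, step `eps^(1/3)` × parameter scale,
symmetrized, eigenvalues floored at 1e-8). A fitted σ_b below 1e-3 is
reported as boundary-degenerate: the likelihood is flat there and its
curvature-based SE is not interpretable. Non-convergence never raises —
the fit returns with `converged=False`.

## Effect reporting

A log-rate coefficient β with standard error s becomes
`100·(exp(β·IQR) − 1)` with 95% limits `100·(exp((β ± 1.96 s)·IQR) − 1)`.
Short-term terms are scaled by the **temporal IQR** — Q3 − Q1 of the daily
area-average (unweighted over units) concentration series; long-term terms
by the **spatial IQR** of the per-unit study-period means. The quantile
convention is linear interpolation between order statistics, pinned in one
function and used everywhere. The analysis grid (pollutant × lag ×
outcome × age band × adjustment) degrades gracefully: a failing cell is
recorded, not fatal. Intervals are nominal; no multiple-testing
adjustment is applied (stated in the report footer).

The Poisson time-series sensitivity model sums counts over units per
weekday, averages exposure over units per day, and fits a log-linear
Poisson regression (IRLS) with the same temporal confounders; the Pearson
χ²/df overdispersion factor is reported and can optionally inflate the SE
(quasi-Poisson).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes —
not any real pollution surface.

* **Exposures**: `X_itp = m_p + S_ip + T_tp + ε_itp` with unit effects
  `S_i` drawn once from a correlated multivariate normal (spatial SDs and
  correlations from the study area's printed summaries), an area-wide
  daily signal `T_t` = annual sinusoid + AR(1) (coefficient 0.7) with
  correlated innovations scaled so the total temporal SD matches its
  target, and independent unit-day noise (default 10% of the temporal SD —
  within-unit temporal heterogeneity is not identified by area-wide
  summaries, so this is a declared modelling choice). Negative values are
  clipped at zero and the clip rate is logged; under the default PM₂.₅
  marginals (mean 15.6, total SD ≈ 8.3) a Gaussian field necessarily
  clips ~3% of unit-days — the real distribution is right-skewed — so the
  generator asserts a <5% ceiling rather than a cosmetic <1%.
* **Meteorology**: sinusoid + AR(1), temperature mean 11.0 °C / SD 5.7
  (seasonal amplitude 7 °C), humidity mean 77.2% / SD 10.1 clipped to
  [0, 100]; shared across units.
* **Counts**: drawn from the mixed ZINB model itself. Confounder effects
  use the same natural-spline bases as the design builder, so generating
  coefficients live exactly in the fitted parameterization and recovery
  tests are sharp. Structural zeros are independent across unit-days.
  A linear predictor above 30 aborts with advice to rescale.

Preset calibration: per-unit-day mean counts are the study area's printed
all-area outcome means divided by its 177 units (e.g. preventer inhalers,
all ages: 61.01/177 ≈ 0.345); intercepts were solved analytically from
`target ≈ (1−π)·exp(β₀ + σ_b²/2)·E[exp(covariate terms)]` with the
expectation evaluated once on a seed-0 covariate draw, and frozen in the
preset YAML. Default nuisance values θ = 1.5, π = 0.08, σ_b = 0.25 are
realistic for sparse daily small-area counts. The true short-term effect,
ln(1.02)/9.1 per μg/m³, is +2% per the printed 9.1 μg/m³ PM₁₀ temporal
IQR; a generated Gaussian panel's own temporal IQR is larger
(1.349 × 8.8 ≈ 11.9 μg/m³), so on its own scale the truth is ≈ +2.7%.
What passing recovery tests show is that the estimator is correct for
data generated by its own model; they cannot show robustness to exposure
measurement error, spatial confounding, or outcome misclassification in
real data.

## Problem sizes and validation choices

The simulation studies run at a "desk" scale chosen to make replicated
fitting routine: 50 units × 260 weekdays (one calendar year), 25
replicates for parameter recovery and 50 for CI calibration; one fit takes
a few seconds. Quadrature accuracy is verified against dense brute-force
trapezoid integration (1e5 points over ±10σ) on a 3-unit × 5-day
instance, where the two agree to ~1e-14; node counts 7→15→31 change the
log-likelihood below 1e-6/1e-8. Nested-model reductions are checked
against statsmodels: the Poisson log-likelihood at (π≈0, θ=1e8, σ_b≈0) and
a flat (no random effect) zero-inflated NB fit, whose own BFGS optimizer
is reliable on a reduced design (exposure + weekday + unit covariates) —
the comparison runs there, at 1e-3 coefficient agreement.

## Known limitations

* ML variance components are biased downward in few-unit panels: with 50
  units and four unit-level regressors, E[log σ̂_b] − log σ_b ≈
  ½·log((m−q)/m) ≈ −0.04, which replication at 150 units confirms
  vanishes. Recovery tests that resolve bias below this size will flag
  σ_b; the fixed effects, θ and γ₀ are unbiased at this scale.
* The zero part is intercept-only; zero-inflation covariates would need a
  different fitter surface.
* No spatially correlated random effects, no distributed-lag-nonlinear
  models, no exposure measurement-error correction; lag profiles are
  estimated by separate fits per lag, not jointly.
* Wald intervals rely on the observed information; near-boundary σ_b
  makes its row of the covariance non-interpretable (flagged).
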