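# Methods

This note records the modelling choices, numerical conventions and known
limitations of `stcar`, in the spirit of a statistical package's model
documentation.

## Observation model and families

All four families share the Gaussian observation model
`y_dt ~ N(x_dt' beta + psi_dt, nu2)` on a complete D-area × T-year panel.
The nugget variance `nu2` is homoscedastic: a single observation-level
variance per model, which is the parameterisation under which the model
scalars are reported.  Heteroscedastic noise is out of scope.

The families differ only in `psi`:

* **independent_glm** — `psi = 0`; the baseline against which the value of
  spatial/temporal structure is measured.
* **st_anova** — additive main effects `phi_d + delta_t`, optionally plus
  an iid interaction `gamma_dt ~ N(0, tau2_i)`.  The interaction is **off
  by default**: with one observation per cell and a free nugget, `gamma`
  and the noise compete for the same variance, so the default model keeps
  the identifiable main-effects decomposition; a flag enables it.
* **st_linear** — area-specific linear trends
  `phi_d + (alpha + delta_d)(t − t̄)/T` with `t = 1..T`, `t̄ = (T+1)/2`.
  The scaling by `1/T` keeps the slope scale comparable across panel
  lengths; `alpha` is the overall slope.
* **st_ar** — a first-order chain of spatial fields:
  `phi_1 ~ N(0, tau2_T Q(rho_S)^{-1})`,
  `phi_t | phi_{t−1} ~ N(rho_T phi_{t−1}, tau2_T Q(rho_S)^{-1})`.
  No separate additive temporal main effect is included: the chain itself
  carries the temporal structure, and the reported parameter set for this
  family (`tau2_T, rho_S, rho_T, nu2`) stays minimal and identifiable.

## CAR priors

All structured spatial blocks use the proper Leroux parameterisation
`Q(rho) = rho (D_w − W) + (1 − rho) I`, which interpolates between
independence (`rho = 0`) and the intrinsic CAR (`rho = 1`) and has a
well-defined normalising constant for `rho < 1`; the temporal main effect
uses the same form on the path graph.  `rho = 1` is accepted only for
structure inspection, never for density evaluation or sampling — intrinsic
CAR inference is a non-goal.  At the problem sizes the package targets
(tens of areas) all linear algebra is dense; one Cholesky factorisation per
density evaluation or exact draw.

## Priors and defaults

| parameter | prior | default rationale |
|---|---|---|
| beta | N(0, 100000) each | effectively flat at the data scales involved |
| nu2, every tau2 | IG(shape 1, scale 0.01) | weakly informative on variances |
| every rho | Uniform(0, 1) | no prior preference over dependence strength |

The IG(1, 0.01) default has no finite mean or variance; where a test needs
finite prior moments (the joint-distribution check below) a proper test
prior IG(3, 2) is used instead, without changing the production default.

## MCMC

One sweep updates `beta` → all random-effect blocks → all variances → all
`rho`s.  Every Gaussian block and every variance is an exact draw from its
full conditional (conjugate normal and inverse-gamma steps); the `rho`
parameters use a reflected Gaussian random-walk Metropolis step whose
acceptance ratio includes the CAR log-determinant.  Proposal scales adapt
by ±20% per 50-sweep window toward a 40–50% acceptance rate during burn-in
only, so the post-burn-in chain is time-homogeneous.

Identifiability of the intercept against the random effects is maintained
by sum-to-zero re-centring: immediately after each block draw the block
mean is transferred to the intercept (or to `alpha` for the st_linear slope
field), an operation that leaves the linear predictor bitwise unchanged.
For the st_ar family the whole D·T field is centred once per sweep.

The reference protocol is 20,000 burn-in sweeps, 100,000 kept sweeps,
thinning 10 (10,000 stored draws), single chain.  The simulation studies in
the test suite and acceptance script use scaled protocols with the same
shape — 2,000/8,000/4 for the study-scale recovery runs, 500/1,500/3 for
the small discrimination runs, 1,000/4,000/4 for the four-family
comparison — chosen as the smallest runs at which the conjugate-oracle and
recovery checks are stable.

Starting values are deterministic (intercept at the data mean, `nu2` at the
data variance, effects at zero, variances at a tenth of the data variance,
`rho`s at 0.5); burn-in handles the rest.  Runs are bitwise reproducible
given the seed.

## Model comparison and validation conventions

* **DIC** = D̄ + p_D, p_D = D̄ − D(θ̂).  The plug-in point θ̂ is the
  posterior mean of the linear predictor and of `nu2`; p_D is
  parameterisation-dependent, so this convention is fixed and stated.
* **WAIC** = −2(lppd − p_W), with p_W the sum of pointwise sample variances
  (denominator S−1) of the log-densities.
* **LMPL** = Σ log CPO with the harmonic-mean CPO estimator; per-draw
  densities are floored at the smallest positive normal float, and an
  observation hitting that floor indicates severe misfit.
* **loglikelihood** is the plug-in log-likelihood at the same θ̂ as DIC.
* **Validation statistics are in-sample** on the full panel (a hold-out
  split is not part of the default workflow).  The per-observation
  predictive is `N(m_i, s_i)` with `m_i` the posterior-mean linear
  predictor and `s_i² = Var_draws(mu_i) + E[nu2]`; CRPS uses the closed
  Gaussian form and coverage (`cvg`, reported in percent) the central 95%
  interval of that same normal.
* Credible intervals are equal-tailed with linearly interpolated sample
  quantiles; a coefficient is flagged influential iff its interval
  excludes zero.
* In the comparison table the best model is the minimum for
  DIC/WAIC/rmse/mae/crps, the maximum for LMPL/log-likelihood, and the
  closest to the nominal 95 for coverage.

## Synthetic data

The generator emulates the structure the analysis assumes, not any
particular real dataset:

* **Lattice** — a rook-adjacency grid stands in for an administrative
  contiguity graph (the reference scenario uses 8×8 = 64 areas over
  17 years, 1088 records); any edge-list lattice can be substituted.
* **Covariates** — five named climate variables, each a spatially smooth
  CAR base field plus a common yearly shift plus record noise, clipped to
  plausible physical ranges (temperature 20–35 °C, humidity 60–90%, wind
  speed 0.5–3 m/s, sunshine 4–9 h); rainfall is generated on the log scale
  and exponentiated, so it is strictly positive and log-transform-safe.
* **Response** — built on the transformed covariate scale (square-root
  temperature, natural-log rainfall, the default transform set) so that
  the generating coefficients live on the scale the model is fitted on.
  Random effects are drawn from their priors and immediately sum-to-zero
  centred, matching the fitted model's identifiability constraint, which
  makes "truth" directly comparable with posteriors in recovery studies.
* **Reference truth** — coefficients of realistic sign and size for a
  yield-rate-vs-climate problem, with the wind-speed coefficient exactly
  zero (so significance logic is testable); variance and dependence
  parameters `tau2_S = 0.2, tau2_T = 0.4, nu2 = 3.4, rho_S = 0.45,
  rho_T = 0.25`.

What passing tests on these panels do **not** show: robustness to missing
cells (a hard error by design), to non-Gaussian responses, to real climate
covariates' marginal distributions and cross-correlations, or to irregular
contiguity graphs far from grid-like degree distributions.

A consequence of the reference truth worth knowing: with `tau2_S = 0.2`
against a nugget of 3.4 and 17 replicates per area, the spatial field's
signal (marginal SD ≈ 0.3) sits below the per-area noise floor
(≈ 3.4/17 ≈ 0.45 SD), so `tau2_S` itself is only weakly identified at this
design size — its posterior shrinks while `nu2` absorbs the residual
spatial variance.  Regression coefficients and predictive performance are
unaffected; recovery claims in the tests are therefore about the
coefficients, predictive calibration and model ordering, not about pinning
down every variance component.

## Validation strategy of the implementation itself

* Every Gaussian full conditional is checked against textbook dense
  joint-normal conditioning on instances with D·T ≤ 12 (tolerance 1e-8).
* The CAR log-density is checked against a generic multivariate-normal
  log-density (tolerance 1e-10).
* The Gibbs/Metropolis kernel as a whole passes a Geweke-style
  joint-distribution check on a 4-area × 3-year model: alternating
  data-redraw and parameter sweeps reproduce prior moments within
  Monte-Carlo error.
* The independent-error GLM posterior is checked against an exact
  oracle (conditional conjugacy with the one-dimensional `nu2` marginal
  integrated numerically).
* DIC/WAIC/LMPL are re-derived by naive loops from persisted draws
  (tolerance 1e-8), and the closed-form Gaussian CRPS against a
  million-point stratified sampling estimate (tolerance 1e-3).

## Degenerate inputs and numerical guards

Zero or negative harvested area is an invalid exposure; negative
production an invalid value.  Log/sqrt transform domain violations abort
naming the offending record.  Panels with missing cells fail validation
before any fitting — no imputation.  Zero effect variances in the
generator produce exactly-zero blocks; `nu2 = 0` produces a noiseless
response.  Metropolis proposals landing exactly on an interval boundary
are rejected (measure-zero event of the reflection map).

## Limitations

Single-chain inference by default (a multi-chain convergence dashboard is
not included); AR order fixed at 1; binomial/Poisson families, spatially
varying coefficients, multivariate CAR and shapefile/choropleth handling
are out of scope.  The optional hold-out validation (area- or year-blocked)
is deliberately left to the user's own splitting, since the default
workflow reports in-sample statistics.
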