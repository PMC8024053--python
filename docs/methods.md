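# Methods

`melsjm` implements a joint mixed-effects location-scale model for a
repeatedly measured exposure (the motivating case is systolic blood
pressure across childhood) linked to a single later outcome (log left
ventricular mass index) through shared individual random effects.

## The model

Readings are indexed by within-clinic occasion *h*, clinic visit *i* and
individual *j*:

```
y1[hij] = x_mean[ij]' beta + u0[j] + u1[j] z[ij] + e[ij] + eps[hij]

e[ij]   ~ N(0, s2_e[ij]),   log s2_e[ij] = x_scale[ij]' alpha + u2[j]
eps[hij]~ N(0, sigma_eps^2)

y2[j]   = x_out[j]' gamma + g1 u0[j] + g2 u1[j] + g3 u2[j] + u3[j]

(u0, u1, u2) ~ MVN(0, Sigma_u),   u3 ~ N(0, sigma_u3^2), independent
```

* `z[ij]` is age centered at the sample mean, so `u0` is the individual's
  level at the average age.  The fixed mean uses a linear age spline with
  a knot at 12 years (`s1 = min(age, knot)`, `s2 = max(age - knot, 0)`),
  so the two spline coefficients read directly as mm Hg per year below
  and above the knot.  Allowing the spline coefficients themselves to
  vary randomly tends to be fragile in cohorts of this size, so the
  random slope is a single linear-age effect.
* The log link on the visit-level variance keeps it positive and makes
  covariate effects multiplicative: a coefficient `a` on a covariate
  means the within-individual variance changes by `(exp(a)-1)*100` % per
  unit.  `u2` gives every individual their own variability level.
* `eps` is within-clinic (same-visit) disagreement between readings —
  measurement error in the broad sense — and is separated from the
  visit-to-visit variability `e`, which is the quantity of scientific
  interest.  `u3` is the outcome residual and never enters `Sigma_u`:
  the structural zeros are built into the parameterization (there is no
  coordinate that could correlate `u3` with the other effects).
* The two-level form (`levels=2`) drops the `eps` layer for designs with
  a single reading per visit.

Covariate handling follows common epidemiological practice: continuous
covariates are grand-mean centered on the analysis sample, weight-type
covariates and the outcome are log-transformed first, sex is coded
female = 1, and sex-by-spline interactions are products of the female
indicator with the centered spline columns.  Analysis samples are
complete-case per model specification, with drop counts recorded.

## Likelihood

All computations go through the exact marginal likelihood, with no
sampled latent variables:

1. **Within-visit collapse.** Given the visit mean, the readings of one
   visit are exchangeable normals; they enter the likelihood only through
   their precision-weighted mean (weights `n_pooled`, for stored means of
   several readings, whose error variance is `sigma_eps^2/n_pooled`), the
   within-visit sum of squares, and counts.  The compound-symmetry
   covariance `s2_e J + sigma_eps^2 diag(1/n_pooled)` is marginalized
   analytically — `e` is never a latent variable.
2. **Analytic (u0, u1).** Conditional on `u2`, the model is linear and
   Gaussian in `(u0, u1)`, which are integrated in closed form using a
   2x2 Woodbury identity per individual.
3. **Outcome by conditioning.** The outcome enters as the conditional
   Gaussian `y2 | clinic data, u2`, whose variance
   `sigma_u3^2 + g' V_c g` grows with the loadings.  This factorization
   is algebraically identical to the joint Gaussian but numerically
   stable for arbitrarily small `sigma_u3` or large loadings (a joint
   2x2 information-matrix formulation suffers catastrophic cancellation
   there, which an MCMC sampler will find and exploit).
4. **Adaptive Gauss–Hermite over u2.** The remaining one-dimensional
   integral uses Gauss–Hermite nodes centered and scaled per individual
   to a Gaussian approximation of the integrand built from the linear
   channel (exact in `u2` when the variance channel is frozen) plus a
   half-point-per-visit variance-information term.  Order 9 is accurate
   to ~1e-5 log-likelihood units even when the outcome loading makes the
   integrand far narrower than the random-effect prior; order 21 is the
   library default.  Non-adaptive prior-centered rules lose several
   log-likelihood units in exactly the parameter regions an MCMC chain
   visits, which manifests as spurious posterior structure.

Two independent oracles guard this path in the test suite: full
three-dimensional tensor Gauss–Hermite quadrature after a Cholesky
rotation of `Sigma_u`, and plain Monte-Carlo integration over
`u ~ MVN(0, Sigma_u)`.  They share no integration machinery with the
production path.

A numba-compiled kernel computes the same quantity for speed (about
0.5 ms per evaluation at J = 300); it is cross-checked against the
reference numpy implementation, which is used automatically when numba
is unavailable.

## Estimation

Because the random effects are integrated out exactly, the posterior has
a few dozen dimensions regardless of cohort size.  Fitting proceeds as:

1. **MAP** by L-BFGS on an unconstrained parameterization, started from
   method-of-moments values (per-individual least squares).
2. **Laplace covariance** from a finite-difference Hessian at the mode.
3. **Adaptive preconditioned random-walk Metropolis**: the global step
   size targets a 0.25 acceptance rate and the proposal covariance is
   refreshed from the chain's own history during warmup (blended 50/50
   with the Laplace covariance); every 15th iteration all coordinates
   also receive single-coordinate Metropolis updates, which traverse the
   skewed variance-parameter marginals faster than joint moves.  All
   adaptation freezes at the end of warmup, so the sampling phase is a
   valid fixed-kernel chain.  Chains get deterministically derived
   per-chain seeds from one master seed.

The parameterization was chosen for geometry, and matters more than the
kernel:

* **SDs on the direct scale through |.|** (reflection at zero) rather
  than logs: posteriors of weakly identified SDs (e.g. the log-scale
  effect SD at J = 300) put real mass near zero, which a log transform
  stretches into an arbitrarily long tail.
* **Correlations via partial correlations** (`atanh`-transformed), with
  the uniform-over-correlation-matrices (LKJ shape 1) prior expressed
  exactly through per-partial Beta densities.
* **Loadings as the regression on whitened active effects**:
  `kappa = L_A' lambda_A` with `L_A` the Cholesky factor of the active
  block of `Sigma_u`.  The data inform `kappa` directly, which removes
  both the loading-versus-SD funnel and a strong curved ridge between
  loadings and the location/log-scale correlation that otherwise stalls
  any random-walk sampler.

Priors are weakly informative and data-scaled: zero-centered normals on
regression coefficients with scales `10 * sd(response) / sd(column)`,
half-normals on all SDs with scales of five response-SDs, normals of
scale ten outcome-SDs on the whitened loadings, and LKJ(1) on the
correlation matrix.  All scales are configurable through
`FitConfig.prior_scale_multiplier`.

Convergence reporting uses arviz split R-hat and ESS with a 1.05
threshold; a non-converged run completes and is flagged, never silently
accepted.  A random-walk kernel has no divergent transitions, so the
report carries acceptance rates instead.

Point estimation (`fit_map`) exposes the posterior mode for uses where a
full posterior is unnecessary, e.g. the replicated bias experiments.

## Two-stage comparator

`two_stage_baseline` implements the textbook shortcut the joint model
replaces: per-individual OLS of the clinic means on centered age
(intercept, slope, and the log of the unbiased residual variance, floored
at 1e-8 for exact-fit individuals; individuals need at least three
visits), followed by OLS of the outcome on the centered summaries plus
outcome covariates.  Stage-one noise is ignored by stage two, which
attenuates the loadings — most severely the log-variance loading, whose
stage-one estimate has only a few degrees of freedom per individual.
`bias_experiment` measures this on replicate synthetic cohorts, using
the joint posterior mode as the joint point estimate; with six visits
and two readings the two-stage log-variance loading collapses toward
zero while the joint estimate is approximately unbiased.  In the
no-measurement-error, 50-visit limit the two estimators agree for the
location and slope loadings; that limit experiment uses an uncorrelated
log-scale effect, because with correlated effects the noisy stage-one
variance summary leaks bias into the other loadings even without
measurement error (a distinct, real deficiency of the two-stage method,
but not the one that experiment isolates).

## Synthetic cohorts

The generator draws from exactly the model above, with a design that
emulates a six-clinic childhood cohort:

* clinic mean ages (7.5, 9.5, 10.5, 11.5, 13, 15.5) with 0.25-year
  jitter; two readings per visit except the 10.5-year clinic, which
  contributes a single stored value (optionally marked as a pooled mean
  of `k` readings via `n_pooled`, with error variance `sigma_eps^2/k`;
  the default treats it as one raw reading);
* attendance thinned by an individual logit-normal propensity (SD 1.5)
  plus per-clinic offsets, calibrated once so per-clinic attendance is
  85–91% and most individuals attend all six clinics while a small tail
  attends few — at the default 2,000 individuals this yields roughly
  10,500 visits and 19,400 readings.  Thinning never removes the
  individual-level outcome row; outcome missingness is a separate rate;
* covariate stand-ins: sex Bernoulli(0.549); log-weight and height grow
  linearly in age around individual anchors; maternal age, parity and a
  five-level education factor with realistic moments; outcome-visit age
  near 17.7 years and an outcome-visit weight on the same growth curve.

Default generating parameters (`default_true_params`) describe a cohort
whose exposure rises slowly before the knot and steeply after, whose
within-individual variance grows ~11%/year, is ~20% higher in girls and
~5% per 10% of body weight, with random-effect SDs (5.39, 0.65, 0.42), a
0.50 correlation between level and log-variability, within-clinic SD
5.61, and small opposite-signed outcome loadings.  Percentage-change
values are stored back-transformed to the coefficient scale
(`ln(1+p/100)` per unit; `ln(1+p/100)/ln(1.10)` per 10%).

What the generator does **not** emulate: real covariate joint
distributions and their attendance dependence, cohort selection bias,
autocorrelated within-individual errors, and non-Gaussian exposure
tails.  Passing calibration on these cohorts shows the estimator is
correct for the model it claims to fit, not that the model is adequate
for any particular real cohort.

## Reporting

Percentage-change transforms are applied draw-wise and then summarized;
both are monotone, so credible-interval endpoints commute with the
transform (tested).  The results table mirrors the conventional layout:
mean-function effects in raw units, random-effect SDs/correlations,
variance-function effects on percent scales (per 10% for log-scale
covariates, per unit otherwise), outcome effects likewise.

Outlier screening standardizes residuals at three levels from a
preliminary parameter estimate: within-clinic contrasts (exactly standard
normal under the model), visit means around shrunken individual
trajectories, and shrunken individual intercepts, with a default |z| > 4
threshold as a reproducible proxy for visual QQ inspection.  Flagged
measurements are removed, flagged visits lose all readings, flagged
individuals lose all rows.

## Numerical choices and limitations

* Log within-individual variances are clipped to ±30 inside density
  evaluations (with a warning) to prevent overflow during sampling.
* Stage-one residual variances are floored at 1e-8 before logs.
* The quadrature order, chain lengths and replicate counts used in the
  test suite (order 9; 2,500 warmup + 4,500 kept draws per chain; 20
  calibration replicates at J = 300; 30 bias replicates at J = 600) are
  the package's scaled study sizes for routine verification; they
  reproduce pooled 95% coverage within [85, 100]% and pass rank-
  uniformity checks.  Cohorts of the motivating study's size (~2,000)
  fit in a few minutes.
* At J = 300 the outcome loadings are weakly identified: the posterior
  for the log-scale loading is heavy-tailed (its magnitude trades off
  against the log-scale SD), and R-hat for such derived quantities can
  sit above 1.05 at the default chain lengths even when coverage is
  correct.  Longer chains, or the better-identified whitened loadings
  (`kappa`), are the remedy.
* No autocorrelated within-individual errors; no random coefficients in
  the variance function beyond its intercept; no WAIC/LOO model
  comparison; no imputation of missing covariates.
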