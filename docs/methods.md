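# Methods

This note documents the statistical model behind `athleref`, the numerical
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the package's known limitations.

## Observation model and prior

Within one (sport, sex) cell an outcome is modelled as i.i.d. Gaussian
with mean `mu` and precision `tau`; across cells `(mu, tau)` follows the
conjugate normal–gamma prior NG(mu0, kappa0, alpha0, beta0):
`tau ~ Gamma(alpha0, rate beta0)` and `mu | tau ~ N(mu0, 1/(kappa0·tau))`.
Units: `mu0` in outcome units, `beta0` in outcome units², `kappa0` and
`alpha0` dimensionless; `kappa0` is interpretable as the prior's effective
sample size *in persons* for the mean, and `2·alpha0` plays the same role
for the variance.

Outcomes that are strongly right-skewed in practice — bone mineral
density, absolute and percent fat mass in every region, and the FMI, FFMI
and ALSTI indices — are transformed with the natural log before fitting
and every percentile point and interval endpoint is exponentiated
afterwards. Quantiles are equivariant under monotone transforms, so this
is exact, and the base of the logarithm is irrelevant; natural logs are
used for simplicity. Non-positive values in a log-scale outcome are a
validation error, never silently dropped.

## Empirical-Bayes hyperparameter estimation

The hyperparameters are estimated per outcome and sex by maximising the
sum over cells of the closed-form log marginal likelihood (Gaussian
likelihood with `(mu, tau)` integrated out against the prior); a cell with
a single athlete still contributes (its marginal is a Student-t with
`2·alpha0` degrees of freedom), and empty cells contribute nothing.
The closed form is verified in the test suite against two-dimensional
Gauss–Legendre quadrature to |Δ| < 1e-6.

Optimisation is Nelder–Mead over `(mu0, log kappa0, log alpha0,
log beta0)` — a smooth 4-parameter objective where robustness matters more
than speed. Details that matter:

* **Start point** by method of moments: `mu0` the n-weighted grand mean of
  cell means; `alpha0`, `beta0` from the mean and spread of cell sample
  variances; `kappa0` from the between-cell variance of means in excess of
  the sampling contribution. All clipped to sane ranges; this only seeds
  the optimiser.
* **Initial simplex with absolute steps.** The `mu0` step scales with the
  pooled within-cell SD (a shift-invariant quantity) and the log-parameter
  steps are fixed at 0.35, so shifting every observation by a constant `c`
  shifts the fitted `mu0` by exactly `c` and leaves the other estimates
  untouched. (A relative initial simplex would break this exact
  equivariance.)
* **Bounding box with smooth penalty.** With few cells the marginal
  likelihood can increase monotonically in `alpha0` toward the degenerate
  equal-variance limit `alpha0 → ∞` — a boundary MLE, the same phenomenon
  that leads variance-moderation software to cap its prior
  degrees-of-freedom estimate. Parameters are therefore kept in a wide box
  (`alpha0 ≤ 500`, `kappa0 ∈ [1e-6, 1e6]`) by a quadratic penalty outside
  it; `alpha0 = 500` means "variance effectively constant across sports"
  and is reported as such.
* **Termination** at 1e-8 on the objective with an iteration cap;
  non-convergence raises with the optimiser diagnostics, and degenerate
  data (all values identical) fail fast with a named error.

Cells enter the likelihood with n ≥ 1, posteriors are produced under the
sharing rule n ≥ 2, and tables display estimates under the reporting rule
n ≥ 8 (rows with 2 ≤ n < 8 are kept, flagged `reported=False`, and
rendered with the sample size visible but estimates blanked).

## Percentile points, joint region, simultaneous intervals

The conjugate posterior per cell is again normal–gamma with the standard
update; batch and one-observation-at-a-time updates agree to machine
precision (tested). Percentile points use the plug-in Gaussian quantile
`mu_n + z_p·sigma_hat` with `sigma_hat² = beta_n/(alpha_n−1)`, the
posterior mean of the variance — a single defensible plug-in requiring
`alpha_n > 1`. The alternative `beta_n/alpha_n` (inverse of the mean
precision, always defined) is exposed as
`variance_estimator="inverse_mean_precision"`.

The joint 95% region is a **highest-posterior-density set** computed on a
uniform grid over `(mu, log tau)` spanning ±6 marginal posterior SDs per
axis (Student-t marginal for `mu`, log-gamma for `log tau`), default
200×200 (100×100 in the simulation studies). Cells are sorted by density
and accumulated until the requested mass is enclosed (midpoint rule); the
enclosed mass is reported and must sit within 0.5 percentage points of the
level, else a resolution error is raised. HPD regions nest across levels
by construction. Membership tests for arbitrary points use the analytic
density against the grid-derived threshold. The enclosed mass is verified
in the tests by an independent Monte-Carlo route (sampling from the
posterior and counting density exceedances).

Simultaneous CIs for all ranks come from extremising `mu + z_p/sqrt(tau)`
over the region's grid cells. Because every rank uses the same joint
region, the five intervals hold *simultaneously* at the region's level;
containment of the true `(mu, tau)` implies containment of all five true
quantiles, so CI coverage is bounded below by region coverage.

`locate_in_reference` classifies a measurement against a monotone row of
percentile points: below the 5th-percentile point it reports `<5`, above
the 95th `>95`, otherwise the bracketing rank pair and the rank whose
point is nearest on the outcome scale (ties go to the lower rank).

## Reliability and comparisons

ICC(3,1) is computed from the two-way ANOVA mean squares,
`(MS_subjects − MS_error)/(MS_subjects + (k−1)·MS_error)`, consistency
form (occasion main effect excluded from error), cross-checked against
pingouin and a brute-force sums oracle. The laboratory CV is the
within-subject root-mean-square CV — 100 × √(mean per-subject variance) /
grand mean — the standard test–retest summary and the only CV computable
from repeated scans alone; for duplicates the per-subject variance
reduces to d²/2.

Sex comparisons gate on Shapiro–Wilk at 0.05 per group (both groups must
pass; constant or n < 3 samples fail the gate) and run Welch's t-test or
the Mann–Whitney U test accordingly; the pooled-variance t-test is
available via `equal_var=True`. Sport comparisons use the tie-corrected
Kruskal–Wallis omnibus (scipy) with Dunn's pairwise rank-mean z-tests
implemented directly (tie-corrected SE), since no installed package
provides them. All p-values are nominal by design; no multiplicity
adjustment is applied anywhere.

## Synthetic-data generator

`simulate_dataset` mirrors the analysis model: per cell and outcome it
draws `(mu, tau)` from the outcome's normal–gamma hyperprior and then
Gaussian values, exponentiating for the log-scale outcomes (so fat-mass
aggregates are sums of log-normals — positive and right-skewed). Default
cell sizes are the packaged 21-sport × 2-sex design table, which keeps
many cells under the n ≥ 8 gate and one-athlete cells in play, exactly
the regime the sharing rules exist for; the skinfold/circumference and
DXA blocks are assigned to subsets of each cell with overlap as close to
the design's crossover count as the sizes allow. Default hyperparameters
emulate the descriptive statistics of an adult athlete population (e.g.
male height 179.3 ± 6.5 cm within sport, ±6 cm between sports; female
whole-body %FM ≈ 23%, male ≈ 14%); they are fixed constants of the
package, chosen once for realism.

DXA values are generated part-wise (arms, legs, trunk, head per tissue)
and aggregated, so appendicular = arms + legs, subtotal = whole − head
and FFM = LST + BMC hold *exactly* — useful for testing the derived
measures. Gaussian physical magnitudes are redrawn in the rare event of a
draw at or below 5% of the prior mean, preserving the record types'
positivity invariants with negligible distributional effect.

What the generator does **not** emulate: inter-variable correlation
(weight–height allometry, fat–lean covariance) beyond the DXA additivity
constraints, age structure beyond a uniform 16–35 range, measurement
error, or real between-sport profiles. Passing tests therefore
demonstrate that the estimator recovers the model it assumes under the
study's sample-size design — not that real athlete data satisfy those
assumptions.

## Validation experiments and problem sizes

* **Hyperparameter recovery**: 20 replicates of 200 groups × 20
  observations (and 20 groups as a contrast), fixed seeds. Median relative
  error per hyperparameter is 6–9% at 200 groups, under the 15% bar, and
  strictly larger at 20 groups. `mu0`'s error is normalised by the prior
  SD of the group mean since its true value may be zero.
* **Joint coverage**: 500 replicates of 20 groups with sizes drawn from
  the packaged design (sharing floor 2), truth NG(0, 1, 3, 2), level
  0.95, 100×100 grids; hyperparameters are re-fitted from scratch each
  replicate. Across ~10,000 group-replicates the simultaneous-CI coverage
  is ≈ 94–95% and the region coverage ≈ 92.5–93%. With the *true*
  hyperparameters the region covers at the nominal 95.0% (verified), and
  with 200 groups the fitted pipeline reaches ≈ 94.5%/95.4%: the one- to
  two-point shortfall at 20 groups is the price of plugging in
  hyperparameters estimated from few groups, a known property of
  empirical-Bayes intervals that ignore hyperparameter uncertainty.

These sizes keep the full suite and the reproduction script fast on a
single CPU while leaving Monte-Carlo error well below the effects being
checked.

## Limitations

* Percentiles are parametric (Gaussian, possibly after log); no LMS /
  Box–Cox curves, no age-varying centiles — stratification is by sex and
  sport only.
* Empirical-Bayes plug-in intervals mildly undercover when the number of
  groups is small (quantified above); a fully Bayesian or bootstrap
  treatment of hyperparameter uncertainty is out of scope.
* The HPD region is grid-based; pathological posteriors needing mass far
  beyond ±6 marginal SDs raise a resolution error rather than silently
  truncating.
* Reference tables produced from synthetic data are structurally faithful
  but numerically meaningless for real athletes; the package ships no
  real measurements.
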