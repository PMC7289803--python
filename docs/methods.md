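# Methods

## Synthetic survey generator

The generator (`carnitrack.synth`) emulates a national wildlife-triangle
scheme on a planar km grid.  Defaults mirror the survey conditions the
package targets: 1805 transect units observed annually 1989–2017, four
species (bear, lynx, wolf, wolverine), and a protected fraction of 0.338.

**Units and covariates.**  Each unit carries the six matching covariates:
forest cover (%), terrain ruggedness, distance to the closest settlement
(km), human population density (persons/km²), and planar `x_km`/`y_km`
standing in for longitude/latitude.  Covariates have latitudinal gradients
(forest rises, human density falls toward the north) so that confounded
protection assignment produces spatially structured imbalance.  Regions are
the four `y_km` quartile bands (South, Central, North, Lapland), mimicking
pooled game-management clusters.  All model distances are Euclidean in km:
the spatial covariates only enter analyses as linear predictors, so
projection fidelity is irrelevant at this scale.

**Protection assignment.**  Protection is Bernoulli(expit(α + c·x_std));
the confounding vector `c` defaults to (0.3, 0.4, 0.5, −0.4, 0, 0.6) on the
standardized covariates — protection more likely in northern, forested,
remote units — and α is calibrated by root finding so the expected
protected fraction hits the target to 1e-6.  PA size (km²) is lognormal for
protected units, exactly 0 otherwise.  A geometric helper reproduces the
survey convention that a unit is protected when a 1-km buffer around its
centroid touches a PA polygon.

**Density series.**  The index is generated by an explicit hurdle process:
unit-level random intercepts b0 ~ N(0, σ_b0²) and b1 ~ N(0, σ_b1²); per
year a nonzero indicator Bernoulli(expit(γ'x + γ_PA·PA + b0)); positive
values exp(β'x + β_PA·PA + β_PAy·PA·(t−t0) + β_PAlon·PA·x_std + b1 + ε),
ε ~ N(0, σ²).  Zeros arise only from the Bernoulli part and positives are
exactly lognormal, matching the hurdle model fitted downstream and enabling
exact parameter recovery.  Species defaults stagger the zero-part intercept
(bear −0.8 … wolverine −2.2) to span roughly 65–90 % zeros, the plausible
range for rare-carnivore track counts; σ_b0 = 0.8, σ_b1 = 0.5, σ = 0.7.
The bear's late-summer (vs. winter) survey season is carried only as a
species label; seasons are analyzed identically.

**What the generator does not emulate:** spatial autocorrelation beyond the
linear gradients, temporal autocorrelation within units, observation error
in the track counts, missing survey years, and correlated random effects
across the two model parts.  Passing tests therefore demonstrate
correctness of the estimators under the stated DGP, not robustness to
these real-data features.

## Matching

The propensity model is a logistic GLM fitted by damped IRLS (converged
when the score gradient's max-norm < 1e-8; perfect separation raises an
error naming the separating covariates; statsmodels is used as an
independent cross-check in the tests, not as the implementation).
Matching is 1:1 nearest-neighbor with replacement on the Mahalanobis
distance with the pooled-sample covariance (the common default when the
choice is open).  The caliper is 0.2 SD of the raw propensity scores;
a logit-scale caliper is available via `MatchSpec(caliper_scale="logit")`.
Ties break to the lowest control id and treated units are processed in
ascending id order — with replacement this does not change the solution,
but it fixes reporting order.  Treated units with no in-caliper control are
reported unmatched, never force-matched.

Balance: SMD = (mean_t − mean_c)/SD with the pre-match pooled SD
sqrt((var_t + var_c)/2) as the common denominator before and after
matching (controls weighted by reuse count after), so the two columns are
comparable.  eQQ statistics are mean/median/max absolute differences of
same-quantile values, the larger group interpolated to the smaller group's
quantile grid.  A zero-variance covariate reports SMD 0 with a warning.

## Absolute PA effect

Pair differences are computed for every year in which both pair members
were observed; pairs with no common year are dropped and counted.  Because
pairs contribute unequal numbers of years, the pooled estimate resamples:
each of 1000 iterations draws one year's difference per pair and takes the
median across pairs; the estimate is the median of iteration medians and
the 95 % CI its 2.5/97.5 percentiles (the minimal faithful reading of a
resampling CI for this scheme).  Regional estimates apply the same
procedure within clusters, assigning cross-cluster pairs to the treated
member's cluster.  Annual tests use the *mean* difference (the t-test is a
mean-based test) with Bonferroni multiplier equal to the number of years
tested; years with n ≤ 10 are flagged, zero-variance years handled
degenerately (p = 1 at mean 0, p → 0 otherwise, flagged).

**Calibration of the resampling CI.**  The interval conditions on the set
of pairs and resamples years, so its coverage of a true zero effect depends
on the ratio of between-unit heterogeneity to within-unit year noise.  A
simulation study built into the acceptance tests shows three regimes:
under zero inflation the atom at Δ = 0 pins the median and the interval is
conservative (coverage ≈ 1.0); when unit heterogeneity dominates year noise
the interval is anticonservative (coverage ≈ 0.6 at σ_b1 = 1.0, σ = 0.2);
it is approximately calibrated (≈ 0.95) in the continuous regime with
σ_b1 ≈ σ.  The coverage acceptance experiment therefore uses the
continuous null (100 twin pairs × 20 years, σ_b1 = 0.6, σ = 0.45) where a
coverage statement is meaningful, and separately asserts the documented
conservativeness of the zero-inflated regime.

## Two-part mixed model

Both parts share one fixed-effect design (the zero part mirrors the
continuous part): intercept, six z-scored covariates, PA (0/1), and the
optional terms year (centered at the first study year, entered as a
continuous slope), PA×year, PA×y (latitude), PA×x (longitude); interaction
columns are products of the standardized mains.  Designs with condition
number > 1e10 are rejected naming the suspect columns.  The candidate set
is the 12 admissible combinations of the optional terms (PA×year only with
year), ranked by AIC with ΔAIC to the best; the set is overridable.

**Likelihood.**  With independent random intercepts the per-unit likelihood
factorizes into two 1-D integrals, each evaluated by adaptive Gauss–Hermite
quadrature: the integrand is recentered at the unit's conditional mode
(damped Newton for the logit part; closed form for the Gaussian part, for
which the adaptive rule is exact at any node count) and rescaled by the
curvature there.  15 nodes by default; the tests verify 25-node agreement
with dense trapezoid integration to 1e-6 relative error and < 1e-4 loglik
movement between 15 and 25 nodes on fitted models.

**Optimization.**  L-BFGS-B over (γ, log σ_b0) and (β, log σ, log σ_b1)
with *analytic* gradients obtained by differentiating under the integral at
the fixed adaptive nodes — legitimate because the AGQ value is stationary
in the recentering parameters up to quadrature error — followed by Newton
polishing (analytic gradient, differenced Hessian) until the gradient
max-norm is below 1e-6; fits typically reach 1e-8–1e-12.  Starting values
come from fixed-effects-only logistic/OLS fits; candidate fits warm-start
from the base model.  Variance parameters live on the log scale with a
floor; estimates below 1e-6 are reported as exactly 0 with a note, and a
boundary parameter is excluded from the gradient certificate.  The
covariance of the estimates is the inverse observed information, computed
by central-differencing the analytic gradient.

**Marginalization.**  Conditional fixed effects in nonlinear mixed models
are subject-specific; population-averaged coefficients are recovered by
integrating the conditional mean over the random-effect distribution.
Zero part: the marginal success probabilities are computed by 40-node
Gauss–Hermite quadrature and their logits projected back onto the fixed
design by least squares.  Continuous part: on the log scale only the
intercept changes, by σ_b1²/2 (closed form); slopes are unchanged.
Standard errors propagate the observed-information covariance through the
map by the delta method; p-values are two-sided normal, matching Wald
output conventions.  When both variances are 0 the marginal coefficients
equal the conditional ones exactly; for the logit part slopes attenuate by
≈ 1/sqrt(1 + 0.346 σ_b0²), which the tests verify.

**Sign conventions.**  γ models the probability of a *nonzero* observation,
so positive γ_PA means protection increases detection/occupancy; β is on
the log index scale.

**Diagnostics.**  Simulation-based scaled residuals: 250 unconditional
simulations from the fitted model (random effects redrawn), each
observation's residual its randomized empirical rank among simulations —
uniform on [0, 1] under a correct model — with a Kolmogorov–Smirnov
uniformity test and a dispersion ratio (observed vs. simulated response SD)
with an empirical two-sided p-value.

**PA-size models.**  Restricted to protected units (any unprotected unit is
an error), with standardized log PA size plus year replacing the PA terms;
identical machinery otherwise.

**Known limitations.**  The two random intercepts are independent;
correlated intercepts would need 2-D quadrature and are out of scope.  The
continuous part is lognormal (the canonical two-part choice, matching the
generator); a Gamma part is not implemented.  Maximum likelihood (not
REML) is used throughout, as in standard adaptive-quadrature mixed-model
software; consequently random-intercept SDs carry a small downward
finite-sample bias (~2–3 % at 300 units with 8 cluster-constant
covariates) — verified to match an independent linear-mixed-model ML fit
to 1e-5, with REML on the same data recovering the truth.  Coefficients
are reported on the standardized-covariate scale.

## Pipeline

A single global seed spawns per-stage seeds by hashing the stage name, so
stages are reproducible in isolation; reruns with the same config/seed are
byte-identical (timestamps excluded).  Tables are UTF-8 comma-separated CSV
with a mandatory header; schema validation checks types, ranges, the
pa_size⇔protected consistency, uniqueness of (unit, year, species), and
warns on series too short to enter the resampling.  The CLI (`carnitrack
simulate|match|effects|fit|validate|run-all`) is a thin wrapper over the
library.  Plot generation is intentionally omitted; all artifacts are
machine-readable CSV/JSON plus a markdown summary.

## Problem sizes used in the test suite

Simulation-backed tests use 100–300 units and 10–20 years per replicate
(50 replicates for recovery and model-selection consistency, 200 for CI
coverage), sizes at which every estimator's sampling error is small
relative to the assertion tolerances while the whole suite stays fast on a
single CPU.  The acceptance script runs the pipeline at the full default
scale (1805 units × 29 years × 4 species).
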