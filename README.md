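# carnitrack

Counterfactual evaluation of protected-area (PA) effects on large-carnivore
density indices from wildlife-triangle snow-track surveys.

## The problem

National track-count schemes monitor carnivore abundance on permanent
transects ("wildlife triangles") as a standardized index — crossings per
24 h per 10 km.  Asking whether the PA network supports higher carnivore
densities than unprotected land is a causal question: protected transects
differ systematically in forest cover, terrain, remoteness and human
density, so a naive protected-vs-unprotected comparison is confounded.

`carnitrack` implements the two complementary analyses used for this
question, plus a synthetic survey generator with known ground truth so that
every stage is testable end to end:

1. **Covariate matching.**  A logistic propensity model
   e(x) = P(protected | x) over six matching covariates, then one-to-one
   nearest-neighbor matching *with replacement* on the generalized
   Mahalanobis distance d(i,j) = sqrt((x_i−x_j)ᵀ S⁻¹ (x_i−x_j)), restricted
   by a caliper of 0.2 SD of the propensity scores.  Balance is reported as
   normalized mean differences (SMD) and eQQ statistics, before and after.

2. **Absolute PA effect.**  For each matched pair and year, the
   treated-minus-control difference in the index; the pooled (and regional)
   summary resamples one year per pair over 1000 iterations and reports the
   median of iteration medians with a 2.5/97.5-percentile 95 % CI.  Annual
   means are tested against zero by one-sample t-tests with Bonferroni
   correction.

3. **Two-part (hurdle) mixed model.**  The index is semicontinuous — a
   point mass at zero plus a right-skewed positive part.  The model couples
   a Bernoulli-logit part for P(index > 0) and a lognormal part for the
   positive values, each with an independent unit-level random intercept,
   fitted by maximum likelihood with adaptive Gauss–Hermite quadrature.
   Twelve candidate fixed-effect structures (optional year, PA×year,
   PA×latitude, PA×longitude terms) are ranked by AIC, and coefficients are
   reported both conditionally and marginalized (population-averaged), with
   delta-method standard errors.

## Worked example

```python
import carnitrack as ct

cfg = ct.SimulationConfig(n_units=300, year_start=1990, year_end=2009, seed=3)
units, obs = ct.simulate(cfg)

fit, result, balance = ct.match_units(units)
print(len(result.pairs), round(result.match_rate, 3))
print(balance.table[["smd_before", "smd_after"]].round(3).head(3))

diffs = ct.pair_differences(result.pairs, obs, "lynx")
est = ct.pooled_median_ci(diffs, seed=1)
print(round(est.median_effect, 3), (round(est.ci_low, 3), round(est.ci_high, 3)))
```

prints

```
93 0.979
                    smd_before  smd_after
forest_pct               0.919     -0.101
ruggedness               0.664      0.073
dist_settlement_km       0.690      0.159
0.0 (0.0, 0.0)
```

All but two protected units found an in-caliper control; matching removed
most of the simulated confounding (mean |SMD| drops severalfold); and with no
PA effect in the generator, heavy zero inflation pins the median paired
difference at exactly 0 — the typical picture for rare carnivores.

Fitting the hurdle model on the same data:

```python
frame = ct.build_model_frame(units, obs, "lynx")
best = ct.fit_two_part(frame)           # base structure: 6 covariates + PA
marg = ct.marginal_coefficients(best)
print(marg.part("continuous").loc["pa"].round(4))
```

gives the marginal protection coefficient on the log-density scale with its
z statistic and normal p-value.

The same stages are scriptable from a shell:

```bash
carnitrack simulate --seed 3 --out demo/
carnitrack match --units demo/units.csv --out demo/
carnitrack effects --pairs demo/pairs.csv --observations demo/observations.csv --species lynx --out demo/
carnitrack run-all --seed 3 --out demo_full/
```

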