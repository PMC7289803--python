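"""Two-part mixed model: quadrature oracles, closed-form limits, design
construction, marginalization, model selection and diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
import statsmodels.api as sm

from carnitrack import hurdle as hd
from carnitrack.hurdle import (
    HurdleParams,
    ModelError,
    ModelSpec,
    aic_rank,
    build_model_frame,
    candidate_model_set,
    cluster_loglik_agq,
    design_matrices,
    fit_two_part,
    marginal_coefficients,
    pa_size_model,
    residual_diagnostics,
)
from carnitrack.synth import COVARIATES, SimulationConfig, SpeciesParams, simulate


def _frame():
    """Tiny hand-checkable model frame (3 rows, 2 units)."""
    return pd.DataFrame(
        {
            "unit_id": [1, 1, 2],
            "year": [2000, 2001, 2000],
            "index": [0.0, 2.0, 1.0],
            "protected": [True, True, False],
            "pa_size_km2": [5.0, 5.0, 0.0],
            "forest_pct": [60.0, 60.0, 40.0],
            "ruggedness": [5.0, 5.0, 3.0],
            "dist_settlement_km": [2.0, 2.0, 6.0],
            "human_density": [10.0, 10.0, 30.0],
            "x_km": [100.0, 100.0, 200.0],
            "y_km": [500.0, 500.0, 300.0],
        }
    )


def _bigger_frame(n_units=12, n_years=3, seed=0, all_positive=False):
    """Full-rank model frame for specs with interaction columns."""
    rng = np.random.default_rng(seed)
    rows = []
    for u in range(1, n_units + 1):
        prot = u % 2 == 0
        cov = dict(
            forest_pct=rng.uniform(20, 90), ruggedness=rng.uniform(1, 10),
            dist_settlement_km=rng.uniform(0.5, 20), human_density=rng.uniform(1, 60),
            x_km=rng.uniform(0, 600), y_km=rng.uniform(0, 1100),
        )
        for t in range(n_years):
            val = float(np.exp(rng.normal(-0.5, 0.7)))
            if not all_positive and rng.random() < 0.4:
                val = 0.0
            rows.append(
                {"unit_id": u, "year": 2000 + t, "index": val, "protected": prot,
                 "pa_size_km2": 5.0 if prot else 0.0, **cov}
            )
    return pd.DataFrame(rows)


class TestDesignMatrices:
    def test_year_spec_has_eight_slopes_plus_intercept(self):
        d = design_matrices(_frame(), ModelSpec(name="year", year=True))
        assert len(d.columns) == 9  # intercept + 6 covariates + pa + year
        assert d.columns[0] == "intercept"
        assert "pa" in d.columns and "year" in d.columns

    def test_hand_computed_entries(self):
        d = design_matrices(_frame(), ModelSpec(name="year", year=True))
        f = np.array([60.0, 60.0, 40.0])
        expected_forest = (f - f.mean()) / f.std()
        np.testing.assert_allclose(
            d.X[:, d.columns.index("forest_pct")], expected_forest, atol=1e-12
        )
        np.testing.assert_allclose(d.X[:, d.columns.index("pa")], [1, 1, 0])
        np.testing.assert_allclose(d.X[:, d.columns.index("year")], [0, 1, 0])
        np.testing.assert_allclose(d.X[:, 0], 1.0)

    def test_interactions_are_products_of_standardized_mains(self):
        df = _bigger_frame()
        d = design_matrices(df, ModelSpec(name="m", pa_lon=True))
        pa = d.X[:, d.columns.index("pa")]
        xlon = d.X[:, d.columns.index("x_km")]
        np.testing.assert_allclose(
            d.X[:, d.columns.index("pa:x_km")], pa * xlon, atol=1e-12
        )

    def test_no_treated_units_error(self):
        df = _frame()
        df["protected"] = False
        df["pa_size_km2"] = 0.0
        with pytest.raises(ModelError, match="no treated"):
            design_matrices(df, ModelSpec())

    def test_collinear_covariates_error(self):
        df = _frame()
        df["ruggedness"] = df["forest_pct"] * 2.0
        with pytest.raises(ModelError, match="collinear"):
            design_matrices(df, ModelSpec())

    def test_pa_year_without_year_rejected(self):
        with pytest.raises(ModelError):
            ModelSpec(name="bad", pa_year=True)


class TestClusterLoglikAGQ:
    def _cluster(self, rng, n=12):
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = np.where(rng.random(n) < 0.6, np.exp(rng.normal(-0.5, 0.7, n)), 0.0)
        return y, X

    def test_no_random_effect_limit_equals_independent_glm_densities(self):
        rng = np.random.default_rng(0)
        y, X = self._cluster(rng)
        params = HurdleParams(
            gamma=np.array([0.2, -0.4]), beta=np.array([-0.5, 0.3]),
            sigma=0.7, sigma_b0=0.0, sigma_b1=0.0,
        )
        got = cluster_loglik_agq(y, X, params)
        z = (y > 0).astype(float)
        eta = X @ params.gamma
        expected = np.sum(z * eta - np.logaddexp(0, eta))
        pos = y > 0
        expected += np.sum(
            stats.norm.logpdf(np.log(y[pos]), loc=(X @ params.beta)[pos], scale=0.7)
        )
        assert got == pytest.approx(expected, abs=1e-10)

    def test_matches_fine_trapezoid_integration(self):
        # independent 1-D integrals for each part, both integrated by brute
        # force on a dense grid over +/- 8 random-effect SDs
        rng = np.random.default_rng(1)
        y, X = self._cluster(rng)
        params = HurdleParams(
            gamma=np.array([0.3, -0.2]), beta=np.array([-0.4, 0.25]),
            sigma=0.6, sigma_b0=1.2, sigma_b1=0.8,
        )
        got = cluster_loglik_agq(y, X, params, nodes=25)

        z = (y > 0).astype(float)
        b = np.linspace(-8 * 1.2, 8 * 1.2, 200001)
        eta = X @ params.gamma
        ll_b = (z[:, None] * (eta[:, None] + b) - np.logaddexp(0, eta[:, None] + b)).sum(0)
        f = np.exp(ll_b + stats.norm.logpdf(b, 0, 1.2))
        expected = np.log(np.trapezoid(f, b))
        pos = y > 0
        b1 = np.linspace(-8 * 0.8, 8 * 0.8, 200001)
        r = np.log(y[pos]) - (X @ params.beta)[pos]
        ll_b1 = stats.norm.logpdf(r[:, None], loc=b1, scale=0.6).sum(0)
        f1 = np.exp(ll_b1 + stats.norm.logpdf(b1, 0, 0.8))
        expected += np.log(np.trapezoid(f1, b1))
        assert got == pytest.approx(expected, rel=1e-6)

    def test_gaussian_subcase_matches_closed_form_marginal(self):
        # the positive part with a random intercept is marginally MVN with
        # compound-symmetry covariance sigma^2 I + sigma_b^2 J
        rng = np.random.default_rng(2)
        n = 8
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = np.exp(rng.normal(0.0, 1.0, n))  # all positive
        params = HurdleParams(
            gamma=np.array([5.0, 0.0]),  # z part: nearly always nonzero
            beta=np.array([0.1, -0.2]), sigma=0.5, sigma_b0=0.0, sigma_b1=0.9,
        )
        got = cluster_loglik_agq(y, X, params, nodes=15)
        z_ll = np.sum(5.0 - np.logaddexp(0, np.full(n, 5.0)))
        cov = 0.5**2 * np.eye(n) + 0.9**2 * np.ones((n, n))
        mvn = stats.multivariate_normal(mean=X @ params.beta, cov=cov)
        assert got - z_ll == pytest.approx(mvn.logpdf(np.log(y)), abs=1e-8)

    def test_permutation_invariance_within_cluster(self):
        rng = np.random.default_rng(3)
        y, X = self._cluster(rng)
        params = HurdleParams(
            gamma=np.array([0.1, 0.2]), beta=np.array([0.0, 0.1]),
            sigma=0.8, sigma_b0=0.7, sigma_b1=0.5,
        )
        base = cluster_loglik_agq(y, X, params)
        perm = rng.permutation(len(y))
        assert cluster_loglik_agq(y[perm], X[perm], params) == pytest.approx(
            base, abs=1e-10
        )


@pytest.fixture(scope="module")
def fitted(small_survey_module):
    cfg, units, obs = small_survey_module
    frame = build_model_frame(units, obs, "lynx")
    return frame, fit_two_part(frame, se=True)


@pytest.fixture(scope="module")
def small_survey_module():
    cfg = SimulationConfig(
        n_units=150, year_start=1998, year_end=2012,
        species_params={
            "lynx": SpeciesParams(gamma0=-0.3, gamma_pa=0.5, beta_pa=0.3,
                                  sigma_b0=0.7, sigma_b1=0.4, sigma=0.7)
        },
        seed=42,
    )
    units, obs = simulate(cfg)
    return cfg, units, obs


class TestFitTwoPart:
    def test_fixed_effects_limit_matches_glm_fits(self, small_survey_module):
        # with random effects pinned at zero the two parts collapse to a
        # logistic regression and an OLS log-linear model
        _, units, obs = small_survey_module
        frame = build_model_frame(units, obs, "lynx")
        fit = fit_two_part(frame, se=False, random_effects=False)
        d = fit.design
        ref_logit = sm.Logit(d.z, d.X).fit(disp=0)
        np.testing.assert_allclose(
            fit.gamma.to_numpy(), ref_logit.params, atol=1e-3
        )
        pos = d.z > 0
        ref_ols = sm.OLS(d.logy[pos], d.X[pos]).fit()
        np.testing.assert_allclose(fit.beta.to_numpy(), ref_ols.params, atol=1e-3)
        assert fit.sigma_b0 == 0.0 and fit.sigma_b1 == 0.0

    def test_recovers_generating_parameters(self, fitted):
        _, fit = fitted
        assert fit.converged
        se_pa_c = np.sqrt(fit.vcov_cont.loc["beta_pa", "beta_pa"])
        se_pa_z = np.sqrt(fit.vcov_zero.loc["gamma_pa", "gamma_pa"])
        assert abs(fit.beta["pa"] - 0.3) < 4 * se_pa_c
        assert abs(fit.gamma["pa"] - 0.5) < 4 * se_pa_z
        assert abs(fit.sigma - 0.7) < 0.1
        assert abs(fit.sigma_b0 - 0.7) < 0.35
        assert abs(fit.sigma_b1 - 0.4) < 0.25

    def test_aic_identity(self, fitted):
        _, fit = fitted
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.k, abs=1e-10)
        assert fit.k == 2 * len(fit.beta) + 3

    def test_quadrature_stability_nodes_15_vs_25(self, fitted):
        frame, fit = fitted
        params = HurdleParams(
            gamma=fit.gamma.to_numpy(), beta=fit.beta.to_numpy(),
            sigma=fit.sigma, sigma_b0=fit.sigma_b0, sigma_b1=fit.sigma_b1,
        )
        d = fit.design
        total = {n: 0.0 for n in (15, 25)}
        for n_nodes in total:
            for start, stop in zip(d.starts, np.append(d.starts[1:], len(d.y))):
                total[n_nodes] += cluster_loglik_agq(
                    d.y[start:stop], d.X[start:stop], params, nodes=n_nodes
                )
        assert total[25] == pytest.approx(total[15], abs=1e-4)
        assert total[15] == pytest.approx(fit.loglik, abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        df = _bigger_frame(all_positive=True)
        with pytest.raises(ModelError, match="zero and nonzero"):
            fit_two_part(df)


class TestCandidateSet:
    def test_twelve_distinct_specs(self):
        specs = candidate_model_set()
        assert len(specs) == 12
        assert len({s.name for s in specs}) == 12
        assert len({(s.year, s.pa_year, s.pa_lat, s.pa_lon) for s in specs}) == 12

    def test_base_terms_in_every_spec(self, small_survey_module):
        _, units, obs = small_survey_module
        frame = build_model_frame(units, obs, "lynx")
        for spec in candidate_model_set():
            cols = design_matrices(frame, spec).columns
            assert cols[:8] == ["intercept", *COVARIATES, "pa"]

    def test_marginality_no_pa_year_without_year(self):
        for spec in candidate_model_set():
            assert not (spec.pa_year and not spec.year)


class TestAicRank:
    def _dummy(self, name, loglik, k):
        f = hd.HurdleFit(
            spec=ModelSpec(name=name), design=None, gamma=pd.Series(dtype=float),
            beta=pd.Series(dtype=float), sigma=1.0, sigma_b0=0.0, sigma_b1=0.0,
            loglik=loglik, k=k, aic=-2 * loglik + 2 * k, converged=True,
            n_quadrature_nodes=15,
        )
        return f

    def test_aic_formula(self):
        t = aic_rank([self._dummy("m", -100.0, 10)])
        assert t.loc[0, "aic"] == pytest.approx(220.0)

    def test_parsimony_breaks_loglik_ties(self):
        t = aic_rank([self._dummy("big", -50.0, 10), self._dummy("small", -50.0, 9)])
        assert t.iloc[0]["model"] == "small"

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            aic_rank([])

    def test_nonconverged_listed_after_converged(self):
        bad = self._dummy("bad", -10.0, 5)
        bad.converged = False
        t = aic_rank([bad, self._dummy("good", -100.0, 5)])
        assert t.iloc[0]["model"] == "good"
        assert not t.iloc[1]["converged"]


class TestMarginalization:
    def test_zero_variance_gives_conditional_exactly(self, small_survey_module):
        _, units, obs = small_survey_module
        frame = build_model_frame(units, obs, "lynx")
        fit = fit_two_part(frame, se=True, random_effects=False)
        marg = marginal_coefficients(fit)
        np.testing.assert_array_equal(
            marg.part("zero")["estimate"].to_numpy(), fit.gamma.to_numpy()
        )
        np.testing.assert_array_equal(
            marg.part("continuous")["estimate"].to_numpy(), fit.beta.to_numpy()
        )

    def test_logit_attenuation_ratio(self):
        # population-averaged logistic slopes shrink by approximately
        # 1/sqrt(1 + 0.346 sigma_b0^2); checked on a clean one-covariate
        # design at sigma_b0 = 1
        rng = np.random.default_rng(13)
        X = np.column_stack([np.ones(4000), rng.normal(size=4000)])
        theta = np.array([0.3, 0.8, np.log(1.0)])
        gm = hd._marginal_gamma(theta, X)
        expected_ratio = 1 / np.sqrt(1 + 0.346 * 1.0**2)
        assert gm[1] / 0.8 == pytest.approx(expected_ratio, rel=0.05)
        assert abs(gm[1]) < 0.8  # attenuation, never amplification

    def test_attenuation_never_amplifies(self, fitted):
        _, fit = fitted
        assert fit.sigma_b0 > 0
        marg = marginal_coefficients(fit)
        gm = marg.part("zero")["estimate"].to_numpy()
        cond = fit.gamma.to_numpy()
        slopes = slice(1, None)
        assert np.all(np.abs(gm[slopes]) <= np.abs(cond[slopes]) + 1e-8)

    def test_continuous_slopes_unchanged_intercept_inflated(self, fitted):
        _, fit = fitted
        marg = marginal_coefficients(fit)
        bm = marg.part("continuous")["estimate"]
        np.testing.assert_allclose(
            bm.to_numpy()[1:], fit.beta.to_numpy()[1:], atol=1e-12
        )
        assert bm["intercept"] == pytest.approx(
            fit.beta["intercept"] + fit.sigma_b1**2 / 2
        )

    def test_se_and_p_present(self, fitted):
        _, fit = fitted
        t = marginal_coefficients(fit).table
        assert (t["se"] > 0).all()
        assert t["p"].between(0, 1).all()


class TestResidualDiagnostics:
    def test_residuals_bounded_and_calibrated(self, fitted):
        _, fit = fitted
        diag = residual_diagnostics(fit, n_sim=200, seed=0)
        assert np.all((diag.residuals >= 0) & (diag.residuals <= 1))
        # the model fits its own data: uniformity should not be rejected
        assert diag.ks_pvalue > 0.01
        assert 0.7 < diag.dispersion_ratio < 1.3

    def test_detects_contaminated_data(self, small_survey_module):
        # inject gross outliers -> dispersion should flag the misfit
        _, units, obs = small_survey_module
        obs2 = obs.copy()
        pos = obs2["index"] > 0
        idx = obs2.index[pos][::7]
        obs2.loc[idx, "index"] *= 40.0
        frame = build_model_frame(units, obs2, "lynx")
        fit = fit_two_part(frame, se=False)
        diag = residual_diagnostics(fit, n_sim=200, seed=1)
        assert diag.dispersion_pvalue < 0.05 or diag.ks_pvalue < 0.05


class TestPaSizeModel:
    def test_mixed_protection_rejected(self, small_survey_module):
        _, units, obs = small_survey_module
        frame = build_model_frame(units, obs, "lynx")
        with pytest.raises(ModelError, match="protected"):
            pa_size_model(frame)

    def test_null_size_effect_z_moderate(self, small_survey_module):
        # PA size does not enter the generator, so its marginal z should be
        # an ordinary null statistic
        _, units, obs = small_survey_module
        prot = units[units["protected"]]
        frame = build_model_frame(prot, obs, "lynx")
        fit, marg = pa_size_model(frame)
        z = marg.part("continuous").loc["log_pa_size", "z"]
        assert abs(z) < 3.5
        assert "log_pa_size" in fit.design.columns
        assert "pa" not in fit.design.columns
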