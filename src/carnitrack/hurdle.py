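"""Two-part (hurdle) mixed-effects model for semicontinuous track indices.

The track index has a point mass at zero and a right-skewed positive part.
The model therefore has two components sharing one fixed-effect design:

* a Bernoulli-logit part for the probability of a *nonzero* index
  (so a positive protection coefficient means protection increases
  detection/occupancy), with a unit-level random intercept b0 ~ N(0, s_b0^2);
* a lognormal part for the positive values, log y ~ N(x'beta + b1, sigma^2),
  with an independent unit-level random intercept b1 ~ N(0, s_b1^2).

Because the two random intercepts are independent, the per-unit likelihood
factorizes into two one-dimensional integrals, each evaluated by adaptive
Gauss-Hermite quadrature (AGQ): the integrand is recentered at the unit's
conditional mode and rescaled by the curvature there, so a modest number of
nodes (15 by default) is accurate even for large random-effect variances.
Model selection runs over a 12-model candidate set (optional year,
protection x year, protection x latitude, protection x longitude terms)
ranked by AIC, and fixed effects are reported both conditionally on the
random effects and marginalized (population-averaged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit, logsumexp

from .synth import COVARIATES

logger = logging.getLogger(__name__)

_SB_FLOOR = 1e-8  # below this a random-intercept SD is treated as exactly 0
_SB_BOUNDARY = 1e-6  # fits at/below this are reported as boundary (SD = 0)


class ModelError(ValueError):
    """Degenerate model frame or design (collinearity, no treated units...)."""


@dataclass(frozen=True)
class ModelSpec:
    """One candidate fixed-effect structure.

    All candidates contain the six matching covariates plus protection
    status (replaced by log PA size in the ``pa_size`` variant); the
    optional terms are year (centered at the first study year) and the
    protection interactions with year, latitude (``y_km``) and longitude
    (``x_km``).  The zero part mirrors the continuous-part design.
    """

    name: str = "base"
    year: bool = False
    pa_year: bool = False
    pa_lat: bool = False
    pa_lon: bool = False
    pa_size: bool = False

    def __post_init__(self):
        if self.pa_year and not self.year:
            raise ModelError("PA x year requires the year main effect")
        if self.pa_size and (self.pa_year or self.pa_lat or self.pa_lon):
            raise ModelError("PA-size models carry no protection interactions")


def candidate_model_set() -> list:
    """The 12 candidate structures: all admissible combinations of
    {year; PA x year (only with year); PA x lat; PA x lon}."""
    combos = [
        ("base", 0, 0, 0, 0),
        ("year", 1, 0, 0, 0),
        ("year+pa_year", 1, 1, 0, 0),
        ("pa_lat", 0, 0, 1, 0),
        ("pa_lon", 0, 0, 0, 1),
        ("pa_lat+pa_lon", 0, 0, 1, 1),
        ("year+pa_lat", 1, 0, 1, 0),
        ("year+pa_lon", 1, 0, 0, 1),
        ("year+pa_lat+pa_lon", 1, 0, 1, 1),
        ("year+pa_year+pa_lat", 1, 1, 1, 0),
        ("year+pa_year+pa_lon", 1, 1, 0, 1),
        ("year+pa_year+pa_lat+pa_lon", 1, 1, 1, 1),
    ]
    return [
        ModelSpec(name=n, year=bool(y), pa_year=bool(py), pa_lat=bool(pla), pa_lon=bool(plo))
        for n, y, py, pla, plo in combos
    ]


@dataclass
class DesignInfo:
    """Shared fixed-effect design plus clustering for both model parts."""

    X: np.ndarray  # (n, p), rows sorted by (cluster, year)
    columns: list
    y: np.ndarray  # index values
    z: np.ndarray  # 1 if index > 0
    logy: np.ndarray  # log index where positive, nan elsewhere
    cluster_codes: np.ndarray  # 0..m-1 per row
    cluster_ids: np.ndarray  # m unit ids
    starts: np.ndarray  # reduceat starts per cluster
    spec: ModelSpec
    year0: int
    standardization: dict  # covariate -> (mean, sd)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)


def build_model_frame(
    units: pd.DataFrame, observations: pd.DataFrame, species: str
) -> pd.DataFrame:
    """Merge unit covariates onto one species' observation series."""
    obs = observations.loc[observations["species"] == species]
    if obs.empty:
        raise ModelError(f"no observations for species {species!r}")
    cols = ["unit_id", "protected", "pa_size_km2", *COVARIATES]
    return obs.merge(units[cols], on="unit_id", validate="many_to_one")


def design_matrices(data: pd.DataFrame, spec: ModelSpec) -> DesignInfo:
    """Build the shared fixed/zero design matrix and grouping index.

    Covariates are z-scored on the analysis sample; year is centered at the
    first study year; protection is coded 0/1; interaction columns are
    elementwise products of the standardized mains.  In the PA-size variant
    the protection main effect is replaced by standardized log PA size.
    """
    data = data.sort_values(["unit_id", "year"], kind="stable")
    y = data["index"].to_numpy(float)
    if np.any(y < 0):
        raise ModelError("negative index values in model frame")
    z = (y > 0).astype(float)

    std = {}
    cols, names = [np.ones(len(data))], ["intercept"]
    for c in COVARIATES:
        v = data[c].to_numpy(float)
        mu, sd = v.mean(), v.std(ddof=0)
        if sd == 0:
            raise ModelError(f"covariate {c!r} has zero variance")
        std[c] = (mu, sd)
        cols.append((v - mu) / sd)
        names.append(c)
    xs = dict(zip(names[1:], cols[1:]))

    year0 = int(data["year"].min())
    year_c = data["year"].to_numpy(float) - year0
    if spec.pa_size:
        size = data["pa_size_km2"].to_numpy(float)
        if np.any(size <= 0):
            raise ModelError("PA-size model requires pa_size_km2 > 0 for all rows")
        ls = np.log(size)
        mu, sd = ls.mean(), ls.std(ddof=0)
        if sd == 0:
            raise ModelError("log PA size has zero variance")
        std["log_pa_size"] = (mu, sd)
        cols.append((ls - mu) / sd)
        names.append("log_pa_size")
    else:
        pa = data["protected"].to_numpy(bool).astype(float)
        if pa.sum() == 0:
            raise ModelError("protection column is all zeros: no treated units")
        cols.append(pa)
        names.append("pa")
        if spec.year:
            cols.append(year_c)
            names.append("year")
        if spec.pa_year:
            cols.append(pa * year_c)
            names.append("pa:year")
        if spec.pa_lat:
            cols.append(pa * xs["y_km"])
            names.append("pa:y_km")
        if spec.pa_lon:
            cols.append(pa * xs["x_km"])
            names.append("pa:x_km")
    if spec.pa_size and spec.year:
        cols.append(year_c)
        names.append("year")

    X = np.column_stack(cols)
    cond = np.linalg.cond(X)
    if cond > 1e10:
        corr = np.corrcoef(X[:, 1:], rowvar=False)
        bad = [
            (names[i + 1], names[j + 1])
            for i in range(corr.shape[0])
            for j in range(i + 1, corr.shape[0])
            if abs(corr[i, j]) > 0.999
        ]
        raise ModelError(
            f"collinear design (condition number {cond:.3g}); "
            f"suspect column pairs: {bad or names[1:]}"
        )

    codes, uniq = pd.factorize(data["unit_id"].to_numpy(), sort=True)
    starts = np.flatnonzero(np.diff(codes, prepend=-1))
    logy = np.where(z > 0, np.log(np.where(y > 0, y, 1.0)), np.nan)
    return DesignInfo(
        X=X,
        columns=names,
        y=y,
        z=z,
        logy=logy,
        cluster_codes=codes,
        cluster_ids=np.asarray(uniq),
        starts=starts,
        spec=spec,
        year0=year0,
        standardization=std,
    )


# ---------------------------------------------------------------------------
# adaptive Gauss-Hermite quadrature machinery


@lru_cache(maxsize=None)
def _gh(nodes: int):
    x, w = np.polynomial.hermite.hermgauss(nodes)
    return x, np.log(w)


@dataclass
class _Part:
    """Rows of one model part, cluster-sorted with reduceat bookkeeping."""

    X: np.ndarray
    resp: np.ndarray  # z for the zero part, log y for the continuous part
    codes: np.ndarray  # 0..m-1 local cluster codes per row
    starts: np.ndarray
    sizes: np.ndarray


def _make_parts(d: DesignInfo):
    zero = _Part(
        X=d.X,
        resp=d.z,
        codes=d.cluster_codes,
        starts=d.starts,
        sizes=np.diff(np.append(d.starts, len(d.z))),
    )
    pos = d.z > 0
    codes_pos, _ = pd.factorize(d.cluster_codes[pos], sort=True)
    starts_pos = np.flatnonzero(np.diff(codes_pos, prepend=-1))
    cont = _Part(
        X=d.X[pos],
        resp=d.logy[pos],
        codes=codes_pos,
        starts=starts_pos,
        sizes=np.diff(np.append(starts_pos, pos.sum())),
    )
    return zero, cont


def _logphi(b, sd):
    return -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * (b / sd) ** 2


def _softmax_rows(logv):
    mx = logv.max(axis=1, keepdims=True)
    e = np.exp(logv - mx)
    return e / e.sum(axis=1, keepdims=True)


def _bern_core(gamma, sigma_b, part: _Part, nodes: int, want_grad: bool = False):
    """AGQ log-likelihood (and optional gradient) of the Bernoulli part.

    The gradient differentiates under the integral at the fixed adaptive
    nodes; because the AGQ value is stationary in the recentering parameters
    up to quadrature error, this equals the exact gradient to the same
    accuracy as the likelihood itself.  Gradient order: (gamma, log sigma_b).
    """
    eta = part.X @ gamma
    z = part.resp
    p_dim = part.X.shape[1]
    if sigma_b < _SB_FLOOR:
        p = expit(eta)
        ll = z * eta - np.logaddexp(0.0, eta)
        ll_i = np.add.reduceat(ll, part.starts)
        if not want_grad:
            return ll_i, None
        grad = np.append(part.X.T @ (z - p), 0.0)
        return ll_i, grad
    inv_v = 1.0 / sigma_b**2
    m = len(part.starts)
    b = np.zeros(m)
    for _ in range(60):
        p = expit(eta + b[part.codes])
        g = np.add.reduceat(z - p, part.starts) - b * inv_v
        h = np.add.reduceat(p * (1 - p), part.starts) + inv_v
        step = g / h
        np.clip(step, -8.0, 8.0, out=step)
        b += step
        if np.max(np.abs(g)) < 1e-10 * max(1.0, np.max(np.abs(b))):
            break
    if not np.all(np.isfinite(b)):
        bad = int(np.flatnonzero(~np.isfinite(b))[0])
        raise FloatingPointError(f"non-finite mode during AGQ for cluster index {bad}")
    p = expit(eta + b[part.codes])
    h = np.add.reduceat(p * (1 - p), part.starts) + inv_v
    tau = 1.0 / np.sqrt(h)
    xk, logw = _gh(nodes)
    bk = b[:, None] + np.sqrt(2.0) * tau[:, None] * xk[None, :]  # (m, K)
    etak = eta[:, None] + bk[part.codes]  # (n, K)
    ll_obs = z[:, None] * etak - np.logaddexp(0.0, etak)
    per_cl = np.add.reduceat(ll_obs, part.starts, axis=0)  # (m, K)
    logint = per_cl + _logphi(bk, sigma_b) + xk[None, :] ** 2 + logw[None, :]
    ll_i = 0.5 * np.log(2.0) + np.log(tau) + logsumexp(logint, axis=1)
    if not want_grad:
        return ll_i, None
    pi = _softmax_rows(logint)  # (m, K) node posteriors
    w_obs = pi[part.codes]  # (n, K)
    resid = z[:, None] - expit(etak)
    grad_gamma = part.X.T @ (w_obs * resid).sum(axis=1)
    grad_logsb = float((pi * ((bk / sigma_b) ** 2 - 1.0)).sum())
    grad = np.empty(p_dim + 1)
    grad[:p_dim] = grad_gamma
    grad[p_dim] = grad_logsb
    return ll_i, grad


def _logn_core(beta, sigma, sigma_b, part: _Part, nodes: int, want_grad: bool = False):
    """AGQ log-likelihood (and optional gradient) of the lognormal part.

    The integrand is Gaussian in the random intercept, so the adaptive rule
    is exact at any node count; the closed-form conditional mode makes the
    evaluation one-shot.  Gradient order: (beta, log sigma, log sigma_b).
    """
    r = part.resp - part.X @ beta
    const = -0.5 * np.log(2 * np.pi) - np.log(sigma)
    s2 = sigma**2
    p_dim = part.X.shape[1]
    if sigma_b < _SB_FLOOR:
        ll = const - 0.5 * (r / sigma) ** 2
        ll_i = np.add.reduceat(ll, part.starts)
        if not want_grad:
            return ll_i, None
        grad = np.concatenate(
            [part.X.T @ (r / s2), [float(np.sum(r**2 / s2 - 1.0))], [0.0]]
        )
        return ll_i, grad
    inv_v = 1.0 / sigma_b**2
    S = np.add.reduceat(r, part.starts)
    h = part.sizes / s2 + inv_v
    b = (S / s2) / h
    tau = 1.0 / np.sqrt(h)
    xk, logw = _gh(nodes)
    bk = b[:, None] + np.sqrt(2.0) * tau[:, None] * xk[None, :]
    resid = r[:, None] - bk[part.codes]
    ll_obs = const - 0.5 * (resid / sigma) ** 2
    per_cl = np.add.reduceat(ll_obs, part.starts, axis=0)
    logint = per_cl + _logphi(bk, sigma_b) + xk[None, :] ** 2 + logw[None, :]
    ll_i = 0.5 * np.log(2.0) + np.log(tau) + logsumexp(logint, axis=1)
    if not want_grad:
        return ll_i, None
    pi = _softmax_rows(logint)
    w_obs = pi[part.codes]
    grad_beta = part.X.T @ (w_obs * resid).sum(axis=1) / s2
    grad_logs = float((w_obs * (resid**2 / s2 - 1.0)).sum())
    grad_logsb = float((pi * ((bk / sigma_b) ** 2 - 1.0)).sum())
    grad = np.empty(p_dim + 2)
    grad[:p_dim] = grad_beta
    grad[p_dim] = grad_logs
    grad[p_dim + 1] = grad_logsb
    return ll_i, grad


def _bern_cluster_logliks(gamma, sigma_b, part: _Part, nodes: int) -> np.ndarray:
    return _bern_core(gamma, sigma_b, part, nodes)[0]


def _logn_cluster_logliks(beta, sigma, sigma_b, part: _Part, nodes: int) -> np.ndarray:
    return _logn_core(beta, sigma, sigma_b, part, nodes)[0]


@dataclass(frozen=True)
class HurdleParams:
    """Raw parameter bundle for likelihood evaluation."""

    gamma: np.ndarray
    beta: np.ndarray
    sigma: float
    sigma_b0: float
    sigma_b1: float


def cluster_loglik_agq(y_cluster, X_cluster, params: HurdleParams, nodes: int = 15) -> float:
    """AGQ log-likelihood contribution of a single unit (both parts).

    ``y_cluster`` holds that unit's index series (zeros included) and
    ``X_cluster`` the matching design rows.  Because the two random
    intercepts are independent the likelihood factorizes; each factor is a
    one-dimensional integral handled by adaptive Gauss-Hermite quadrature.
    """
    y = np.asarray(y_cluster, float)
    X = np.atleast_2d(np.asarray(X_cluster, float))
    z = (y > 0).astype(float)
    n = len(y)
    zero = _Part(X=X, resp=z, codes=np.zeros(n, int), starts=np.array([0]),
                 sizes=np.array([n]))
    ll = float(_bern_cluster_logliks(params.gamma, params.sigma_b0, zero, nodes)[0])
    pos = z > 0
    if pos.any():
        npos = int(pos.sum())
        cont = _Part(
            X=X[pos],
            resp=np.log(y[pos]),
            codes=np.zeros(npos, int),
            starts=np.array([0]),
            sizes=np.array([npos]),
        )
        ll += float(
            _logn_cluster_logliks(params.beta, params.sigma, params.sigma_b1, cont, nodes)[0]
        )
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite cluster log-likelihood")
    return ll


# ---------------------------------------------------------------------------
# fitting


@dataclass
class HurdleFit:
    """Fitted two-part mixed model."""

    spec: ModelSpec
    design: DesignInfo
    gamma: pd.Series  # zero part, logit scale (P(nonzero))
    beta: pd.Series  # continuous part, log scale
    sigma: float
    sigma_b0: float
    sigma_b1: float
    loglik: float
    k: int
    aic: float
    converged: bool
    n_quadrature_nodes: int
    vcov_zero: pd.DataFrame | None = None  # over (gamma..., log sigma_b0)
    vcov_cont: pd.DataFrame | None = None  # over (beta..., log sigma, log sigma_b1)
    notes: list = field(default_factory=list)
    grad_norm: float = float("nan")

    @property
    def n_obs(self) -> int:
        return len(self.design.y)

    @property
    def n_clusters(self) -> int:
        return self.design.n_clusters


def _quick_logistic(X, z):
    beta = np.zeros(X.shape[1])
    for _ in range(25):
        p = expit(X @ beta)
        g = X.T @ (z - p)
        w = np.clip(p * (1 - p), 1e-6, None)
        try:
            step = np.linalg.solve(X.T @ (X * w[:, None]), g)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(step)) > 5:
            step *= 5 / np.max(np.abs(step))
        beta += step
        if np.max(np.abs(g)) < 1e-6:
            break
    return np.clip(beta, -15, 15)


def _numeric_hessian(grad_f, x, h=1e-5):
    """Observed information by central differencing of the analytic gradient."""
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        hi = h * max(1.0, abs(x[i]))
        xp = x.copy(); xp[i] += hi
        xm = x.copy(); xm[i] -= hi
        H[:, i] = (grad_f(xp) - grad_f(xm)) / (2 * hi)
    return (H + H.T) / 2.0


_LOG_SB_LO, _LOG_SB_HI = np.log(_SB_FLOOR / 2), np.log(50.0)


def _newton_polish(val_grad, theta, lower, max_steps=8, gtol=1e-7):
    """Drive the gradient max-norm to ~machine level near the optimum.

    L-BFGS-B stops on relative function decrease; a few Newton steps with
    the analytic gradient and a differenced Hessian sharpen the solution.
    Coordinates pinned at their lower bound are left alone.
    """
    theta = theta.copy()
    free = np.flatnonzero(
        [lo is None or theta[i] > lo + 1e-8 for i, lo in enumerate(lower)]
    )
    f0, g = val_grad(theta)
    for _ in range(max_steps):
        if np.max(np.abs(g[free])) < gtol:
            break
        H = _numeric_hessian(lambda t: val_grad(t)[1], theta)[np.ix_(free, free)]
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(len(free)), g[free])
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        improved = False
        for _ in range(6):
            trial = theta.copy()
            trial[free] -= scale * step
            for i, lo in enumerate(lower):
                if lo is not None:
                    trial[i] = max(trial[i], lo)
            f1, g1 = val_grad(trial)
            if f1 <= f0 + 1e-10:
                theta, f0, g = trial, f1, g1
                improved = True
                break
            scale /= 4.0
        if not improved:
            break
    return theta, f0, g


def fit_two_part(
    data: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    nodes: int = 15,
    max_iter: int = 500,
    se: bool = True,
    start: HurdleParams | None = None,
    random_effects: bool = True,
) -> HurdleFit:
    """Maximum-likelihood fit of the two-part mixed model by AGQ.

    The total log-likelihood is maximized by quasi-Newton (L-BFGS-B) ascent
    over (gamma, log sigma_b0) and (beta, log sigma, log sigma_b1) — the two
    blocks are independent because the random intercepts are.  Starting
    values come from fixed-effects-only logistic and log-linear fits.  The
    covariance of the estimates is the inverse observed information
    (numeric Hessian) on those parameterizations.  Random-intercept SDs
    estimated at the boundary (< 1e-6) are reported as 0 with a note.
    ``random_effects=False`` pins both SDs at exactly 0, collapsing the fit
    to independent fixed-effects logistic and log-linear models.
    """
    d = design_matrices(data, spec)
    if d.n_clusters < 2:
        raise ModelError("need at least 2 clusters (units)")
    if d.z.sum() == 0 or d.z.sum() == len(d.z):
        raise ModelError("need both zero and nonzero observations")
    zero, cont = _make_parts(d)
    p = d.X.shape[1]
    notes: list = []

    if start is not None:
        g0 = np.append(start.gamma, np.log(max(start.sigma_b0, _SB_FLOOR)))
        ols = np.append(
            start.beta, [np.log(start.sigma), np.log(max(start.sigma_b1, _SB_FLOOR))]
        )
    else:
        g0 = np.append(_quick_logistic(zero.X, zero.resp), np.log(0.5))
        bhat, *_ = np.linalg.lstsq(cont.X, cont.resp, rcond=None)
        resid = cont.resp - cont.X @ bhat
        s0 = max(resid.std(ddof=0), 1e-3)
        ols = np.concatenate([bhat, [np.log(s0), np.log(0.3)]])

    def nll_zero(theta):
        ll, g = _bern_core(theta[:p], np.exp(theta[p]), zero, nodes, want_grad=True)
        return -float(ll.sum()), -g

    def nll_cont(theta):
        ll, g = _logn_core(
            theta[:p], np.exp(theta[p]), np.exp(theta[p + 1]), cont, nodes,
            want_grad=True,
        )
        return -float(ll.sum()), -g

    sb_bounds = (_LOG_SB_LO, _LOG_SB_HI) if random_effects else (_LOG_SB_LO, _LOG_SB_LO)
    if not random_effects:
        g0[p] = _LOG_SB_LO
        ols[p + 1] = _LOG_SB_LO
    bounds_z = [(None, None)] * p + [sb_bounds]
    bounds_c = [(None, None)] * p + [(np.log(1e-6), np.log(50.0)), sb_bounds]
    opts = {"maxiter": max_iter, "maxfun": 20 * max_iter, "ftol": 1e-14, "gtol": 1e-8}
    opt_z = optimize.minimize(
        nll_zero, g0, jac=True, method="L-BFGS-B", bounds=bounds_z, options=opts
    )
    opt_c = optimize.minimize(
        nll_cont, ols, jac=True, method="L-BFGS-B", bounds=bounds_c, options=opts
    )
    lower_z = [None] * p + [_LOG_SB_LO]
    lower_c = [None] * p + [np.log(1e-6), _LOG_SB_LO]
    theta_z, fz, gz = _newton_polish(nll_zero, opt_z.x, lower_z)
    theta_c, fc, gc = _newton_polish(nll_cont, opt_c.x, lower_c)
    gamma, sigma_b0 = theta_z[:p], float(np.exp(theta_z[p]))
    beta = theta_c[:p]
    sigma, sigma_b1 = float(np.exp(theta_c[p])), float(np.exp(theta_c[p + 1]))
    loglik = -(fz + fc)

    # gradient check on interior parameters (a variance parameter at its
    # boundary is excluded: the gradient need not vanish there)
    if sigma_b0 <= _SB_BOUNDARY:
        gz = gz[:p]
    if sigma_b1 <= _SB_BOUNDARY:
        gc = gc[: p + 1]
    grad_norm = float(max(np.max(np.abs(gz)), np.max(np.abs(gc))))
    converged = bool(opt_z.success and opt_c.success and grad_norm < 1e-6)
    if not converged:
        notes.append(
            f"convergence not certified (grad max-norm {grad_norm:.2e}; "
            f"optimizer success: zero={opt_z.success}, cont={opt_c.success})"
        )
        logger.warning("fit_two_part: %s", notes[-1])
    if sigma_b0 <= _SB_BOUNDARY:
        notes.append(f"sigma_b0 at boundary ({sigma_b0:.2e}); reported as 0")
        sigma_b0 = 0.0
    if sigma_b1 <= _SB_BOUNDARY:
        notes.append(f"sigma_b1 at boundary ({sigma_b1:.2e}); reported as 0")
        sigma_b1 = 0.0

    k = 2 * p + 3
    fit = HurdleFit(
        spec=spec,
        design=d,
        gamma=pd.Series(gamma, index=d.columns),
        beta=pd.Series(beta, index=d.columns),
        sigma=sigma,
        sigma_b0=sigma_b0,
        sigma_b1=sigma_b1,
        loglik=float(loglik),
        k=k,
        aic=float(-2 * loglik + 2 * k),
        converged=converged,
        n_quadrature_nodes=nodes,
        notes=notes,
        grad_norm=grad_norm,
    )
    if se:
        zn = [f"gamma_{c}" for c in d.columns] + ["log_sigma_b0"]
        cn = [f"beta_{c}" for c in d.columns] + ["log_sigma", "log_sigma_b1"]
        fit.vcov_zero = pd.DataFrame(
            _safe_inv(_numeric_hessian(lambda t: nll_zero(t)[1], theta_z)),
            index=zn, columns=zn,
        )
        fit.vcov_cont = pd.DataFrame(
            _safe_inv(_numeric_hessian(lambda t: nll_cont(t)[1], theta_c)),
            index=cn, columns=cn,
        )
    return fit


def _safe_inv(H):
    try:
        V = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        logger.warning("observed information singular; using pseudo-inverse")
        V = np.linalg.pinv(H)
    # numerical Hessians can have tiny negative eigenvalue leakage
    d = np.diag(V).copy()
    if np.any(d < 0):
        logger.warning("negative variance estimates clipped to 0")
    return V


def fit_candidates(
    data: pd.DataFrame,
    specs=None,
    nodes: int = 15,
    se: bool = False,
) -> list:
    """Fit every candidate structure, warm-starting from the base model."""
    specs = list(specs) if specs is not None else candidate_model_set()
    base_spec = next((s for s in specs if s.name == "base"), specs[0])
    base = fit_two_part(data, base_spec, nodes=nodes, se=se)
    fits = []
    for s in specs:
        if s.name == base_spec.name:
            fits.append(base)
            continue
        d = design_matrices(data, s)
        gamma0 = np.array([base.gamma.get(c, 0.0) for c in d.columns])
        beta0 = np.array([base.beta.get(c, 0.0) for c in d.columns])
        warm = HurdleParams(
            gamma=gamma0, beta=beta0, sigma=base.sigma,
            sigma_b0=max(base.sigma_b0, 0.05), sigma_b1=max(base.sigma_b1, 0.05),
        )
        fits.append(fit_two_part(data, s, nodes=nodes, se=se, start=warm))
    return fits


def aic_rank(fits) -> pd.DataFrame:
    """AIC ranking table (ascending), non-converged fits listed last."""
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to rank")
    rows = [
        {
            "model": f.spec.name,
            "loglik": f.loglik,
            "k": f.k,
            "aic": f.aic,
            "converged": f.converged,
        }
        for f in fits
    ]
    t = pd.DataFrame(rows).sort_values(
        ["converged", "aic"], ascending=[False, True], ignore_index=True
    )
    best = t.loc[t["converged"], "aic"].min() if t["converged"].any() else t["aic"].min()
    t["delta_aic"] = t["aic"] - best
    return t


# ---------------------------------------------------------------------------
# marginalization, diagnostics, PA-size variant


@dataclass
class MarginalCoefs:
    """Population-averaged fixed effects with delta-method SEs."""

    table: pd.DataFrame  # part, term, estimate, se, z, p

    def part(self, which: str) -> pd.DataFrame:
        return self.table[self.table["part"] == which].set_index("term")


def _marginal_gamma(theta, X, n_nodes=40):
    """Map (gamma, log sigma_b0) -> marginalized logit coefficients."""
    p = X.shape[1]
    gamma, sb = theta[:p], np.exp(theta[p])
    if sb < _SB_FLOOR:
        return gamma.copy()
    xk, logw = _gh(n_nodes)
    w = np.exp(logw) / np.sqrt(np.pi)
    eta = X @ gamma
    pm = expit(eta[:, None] + np.sqrt(2.0) * sb * xk[None, :]) @ w
    pm = np.clip(pm, 1e-12, 1 - 1e-12)
    sol, *_ = np.linalg.lstsq(X, logit(pm), rcond=None)
    return sol


def marginal_coefficients(fit: HurdleFit, n_nodes: int = 40) -> MarginalCoefs:
    """Marginalized (population-averaged) coefficients of both parts.

    Zero part: the conditional success probability is integrated over the
    random-intercept distribution by Gauss-Hermite quadrature, and the
    marginal logits are projected back onto the fixed design by least
    squares.  Continuous part: on the log scale, marginalizing the lognormal
    random intercept only shifts the intercept by sigma_b1^2 / 2 (closed
    form); slopes are unchanged.  Standard errors propagate the fit's
    observed-information covariance through the map by the delta method;
    p-values are two-sided normal.
    """
    if fit.vcov_zero is None or fit.vcov_cont is None:
        raise ValueError("fit was run with se=False; refit with se=True")
    d = fit.design
    X = d.X
    pdim = X.shape[1]
    theta_z = np.append(fit.gamma.to_numpy(), np.log(max(fit.sigma_b0, _SB_FLOOR)))

    gamma_marg = _marginal_gamma(theta_z, X, n_nodes)
    if fit.sigma_b0 == 0.0:
        J_z = np.hstack([np.eye(pdim), np.zeros((pdim, 1))])
    else:
        J_z = np.empty((pdim, pdim + 1))
        for i in range(pdim + 1):
            h = 1e-5 * max(1.0, abs(theta_z[i]))
            tp = theta_z.copy(); tp[i] += h
            tm = theta_z.copy(); tm[i] -= h
            J_z[:, i] = (_marginal_gamma(tp, X, n_nodes) - _marginal_gamma(tm, X, n_nodes)) / (2 * h)
    V_z = J_z @ fit.vcov_zero.to_numpy() @ J_z.T
    se_z = np.sqrt(np.clip(np.diag(V_z), 0.0, None))

    beta_marg = fit.beta.to_numpy().copy()
    beta_marg[0] += fit.sigma_b1**2 / 2.0
    J_c = np.hstack([np.eye(pdim), np.zeros((pdim, 2))])
    J_c[0, pdim + 1] = fit.sigma_b1**2  # d(sb1^2/2)/d log sb1
    V_c = J_c @ fit.vcov_cont.to_numpy() @ J_c.T
    se_c = np.sqrt(np.clip(np.diag(V_c), 0.0, None))

    rows = []
    for part, est, se in (("zero", gamma_marg, se_z), ("continuous", beta_marg, se_c)):
        for term, e, s in zip(d.columns, est, se):
            zv = e / s if s > 0 else np.nan
            rows.append(
                {
                    "part": part,
                    "term": term,
                    "estimate": float(e),
                    "se": float(s),
                    "z": float(zv) if np.isfinite(zv) else np.nan,
                    "p": float(2 * stats.norm.sf(abs(zv))) if np.isfinite(zv) else np.nan,
                }
            )
    return MarginalCoefs(table=pd.DataFrame(rows))


def simulate_from_fit(fit: HurdleFit, n_sim: int, rng) -> np.ndarray:
    """Simulate ``n_sim`` response vectors from the fitted model.

    Random intercepts are redrawn per simulation (unconditional simulation,
    as in simulation-based residual diagnostics).
    """
    d = fit.design
    n, m = len(d.y), d.n_clusters
    eta = d.X @ fit.gamma.to_numpy()
    mu = d.X @ fit.beta.to_numpy()
    b0 = rng.normal(0.0, fit.sigma_b0, (n_sim, m)) if fit.sigma_b0 > 0 else np.zeros((n_sim, m))
    b1 = rng.normal(0.0, fit.sigma_b1, (n_sim, m)) if fit.sigma_b1 > 0 else np.zeros((n_sim, m))
    pz = expit(eta[None, :] + b0[:, d.cluster_codes])
    nonzero = rng.random((n_sim, n)) < pz
    eps = rng.normal(0.0, fit.sigma, (n_sim, n))
    vals = np.exp(mu[None, :] + b1[:, d.cluster_codes] + eps)
    return np.where(nonzero, vals, 0.0)


@dataclass
class ResidualDiagnostics:
    """Simulation-based scaled-residual report (DHARMa-style)."""

    residuals: np.ndarray  # in [0, 1]
    ks_statistic: float
    ks_pvalue: float
    dispersion_ratio: float
    dispersion_pvalue: float
    n_sim: int


def residual_diagnostics(fit: HurdleFit, n_sim: int = 250, seed: int = 0) -> ResidualDiagnostics:
    """Scaled simulation residuals, uniformity and dispersion checks.

    Each observation's scaled residual is its randomized empirical rank
    among ``n_sim`` simulations from the fitted model; under a correct model
    these are uniform on [0, 1] (Kolmogorov-Smirnov test).  The dispersion
    ratio compares the observed response SD with the simulated ones, with an
    empirical two-sided p-value.
    """
    rng = np.random.default_rng(seed)
    sims = simulate_from_fit(fit, n_sim, rng)  # (n_sim, n)
    y = fit.design.y
    below = (sims < y[None, :]).sum(axis=0)
    ties = (sims == y[None, :]).sum(axis=0)
    u = rng.random(len(y))
    res = (below + u * (ties + 1)) / (n_sim + 1)
    ks = stats.kstest(res, "uniform")
    sd_obs = y.std(ddof=1)
    sd_sim = sims.std(axis=1, ddof=1)
    ratio = sd_obs / sd_sim.mean()
    p_hi = (np.sum(sd_sim >= sd_obs) + 1) / (n_sim + 1)
    p_lo = (np.sum(sd_sim <= sd_obs) + 1) / (n_sim + 1)
    return ResidualDiagnostics(
        residuals=res,
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        dispersion_ratio=float(ratio),
        dispersion_pvalue=float(min(1.0, 2 * min(p_hi, p_lo))),
        n_sim=n_sim,
    )


def pa_size_model(
    data: pd.DataFrame, nodes: int = 15, se: bool = True
) -> tuple:
    """Protection-area-size model on protected units only.

    Same two-part machinery with standardized log PA size (plus year)
    replacing the protection terms.  Any unprotected unit in the input is an
    error: size effects are only defined within the protected network.

    Returns ``(HurdleFit, MarginalCoefs)``.
    """
    if not data["protected"].all():
        raise ModelError("PA-size model requires all units to be protected")
    if (data["pa_size_km2"] <= 0).any():
        raise ModelError("PA-size model requires pa_size_km2 > 0")
    spec = ModelSpec(name="pa_size", year=True, pa_size=True)
    fit = fit_two_part(data, spec, nodes=nodes, se=se)
    marg = marginal_coefficients(fit) if se else None
    return fit, marg
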