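"""Covariate matching of protected (treated) to unprotected (control) units.

Implements the counterfactual design used for protected-area impact
evaluation: a logistic propensity model for the protection assignment,
one-to-one nearest-neighbor matching *with replacement* on the generalized
Mahalanobis distance, a caliper of 0.2 standard deviations of the propensity
score as the minimum matching criterion, and balance diagnostics
(normalized mean differences and eQQ statistics) before and after matching.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.special import expit

from .synth import COVARIATES

logger = logging.getLogger(__name__)


class SeparationError(RuntimeError):
    """Perfect separation in the propensity model."""


class DesignError(ValueError):
    """Degenerate design (rank deficiency, no treated/control units...)."""


@dataclass(frozen=True)
class MatchSpec:
    """Matching configuration (1:1 nearest neighbor, Mahalanobis metric).

    ``caliper_scale`` selects whether the caliper width is 0.2 SD of the raw
    propensity scores (default) or of their logits.
    """

    with_replacement: bool = True
    caliper_sd_multiplier: float = 0.2
    caliper_scale: str = "probability"  # or "logit"
    covariate_names: tuple = COVARIATES

    def __post_init__(self):
        if self.caliper_sd_multiplier <= 0:
            raise ValueError("caliper_sd_multiplier must be > 0")
        if self.caliper_scale not in ("probability", "logit"):
            raise ValueError("caliper_scale must be 'probability' or 'logit'")


@dataclass
class PropensityFit:
    """Logistic propensity model e(x) = P(protected | x)."""

    coefficients: pd.Series  # intercept + covariates, logit scale
    scores: np.ndarray  # in (0, 1)
    converged: bool
    n_iterations: int


@dataclass
class MatchResult:
    """Treated-to-control pairing with caliper bookkeeping."""

    pairs: pd.DataFrame  # treated_id, control_id, distance, propensity_gap
    unmatched: list
    caliper: float
    spec: MatchSpec

    @property
    def match_rate(self) -> float:
        n_treated = len(self.pairs) + len(self.unmatched)
        return len(self.pairs) / n_treated if n_treated else float("nan")

    @property
    def control_use_counts(self) -> pd.Series:
        return self.pairs["control_id"].value_counts()


@dataclass
class BalanceReport:
    """Normalized mean differences and eQQ statistics, pre and post match."""

    table: pd.DataFrame  # index: covariate; columns: smd_before, smd_after,
    # eqq_mean/median/max_before, eqq_mean/median/max_after
    warnings: list = field(default_factory=list)


def fit_propensity(X: pd.DataFrame, treated, max_iter: int = 100) -> PropensityFit:
    """Fit the logistic propensity model by IRLS (Newton-Raphson).

    Convergence is declared when the score gradient's max-norm drops below
    1e-8.  Perfect or quasi-perfect separation and rank-deficient designs
    raise instead of returning useless scores.
    """
    treated = np.asarray(treated, dtype=bool)
    if treated.all():
        raise DesignError("all units are treated; propensity model undefined")
    if not treated.any():
        raise DesignError("no treated units; propensity model undefined")
    cols = list(X.columns)
    Xm = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
    names = ["intercept"] + cols
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise DesignError("rank-deficient propensity design matrix")

    y = treated.astype(float)
    beta = np.zeros(Xm.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xm @ beta
        p = expit(eta)
        grad = Xm.T @ (y - p)
        if np.max(np.abs(grad)) < 1e-8:
            converged = True
            break
        w = np.clip(p * (1 - p), 1e-10, None)
        H = Xm.T @ (Xm * w[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as e:  # pragma: no cover
            raise DesignError(f"singular information matrix: {e}") from e
        # damped Newton keeps quasi-separated fits from overshooting
        if np.max(np.abs(step)) > 10.0:
            step *= 10.0 / np.max(np.abs(step))
        beta = beta + step
        if np.max(np.abs(beta)) > 40.0:
            fitted = expit(Xm @ beta)
            if np.all(np.abs(y - fitted) < 1e-4):
                culprits = [
                    n for n, b in zip(names, beta) if abs(b) > 20.0 and n != "intercept"
                ]
                raise SeparationError(
                    "perfect separation in propensity model; separating "
                    f"covariate(s): {culprits or names[1:]}"
                )
    scores = expit(Xm @ beta)
    scores = np.clip(scores, 1e-12, 1 - 1e-12)
    return PropensityFit(
        coefficients=pd.Series(beta, index=names),
        scores=scores,
        converged=converged,
        n_iterations=it,
    )


def mahalanobis_distance_matrix(X: pd.DataFrame, treated) -> np.ndarray:
    """Treated x control Mahalanobis distances.

    The covariance ``S`` is computed on the pooled sample of all units.  A
    singular ``S`` falls back to the Moore-Penrose pseudo-inverse (logged).
    """
    treated = np.asarray(treated, dtype=bool)
    Xa = X.to_numpy(float)
    S = np.cov(Xa, rowvar=False)
    S = np.atleast_2d(S)
    try:
        VI = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        logger.warning("pooled covariance is singular; using pseudo-inverse")
        VI = np.linalg.pinv(S)
    # symmetrize for cdist's cholesky-free quadratic form
    VI = (VI + VI.T) / 2.0
    d2 = cdist(Xa[treated], Xa[~treated], metric="mahalanobis", VI=VI)
    return d2


def match(
    X: pd.DataFrame,
    treated,
    fit: PropensityFit,
    spec: MatchSpec = MatchSpec(),
    ids=None,
) -> MatchResult:
    """1:1 nearest-neighbor Mahalanobis matching under a propensity caliper.

    For each treated unit the control minimizing the Mahalanobis distance is
    chosen among controls whose propensity-score gap is at most
    ``caliper_sd_multiplier`` x SD of the scores.  Controls are reusable
    (matching with replacement).  Treated units with no in-caliper control
    are reported as unmatched — never silently force-matched.  Ties in
    distance break to the lowest control id; treated units are processed in
    ascending id order.
    """
    treated = np.asarray(treated, dtype=bool)
    ids = np.asarray(ids if ids is not None else np.arange(len(X)))
    scores = np.asarray(fit.scores, dtype=float)
    if spec.caliper_scale == "logit":
        scale_scores = np.log(scores / (1 - scores))
    else:
        scale_scores = scores
    caliper = spec.caliper_sd_multiplier * scale_scores.std(ddof=1)

    t_order = np.argsort(ids[treated], kind="stable")
    c_order = np.argsort(ids[~treated], kind="stable")
    D = mahalanobis_distance_matrix(X, treated)[np.ix_(t_order, c_order)]
    t_ids = ids[treated][t_order]
    c_ids = ids[~treated][c_order]
    e_t = scale_scores[treated][t_order]
    e_c = scale_scores[~treated][c_order]
    gap = np.abs(e_t[:, None] - e_c[None, :])
    in_caliper = gap <= caliper

    rows, unmatched = [], []
    used = np.zeros(len(c_ids), dtype=bool)
    for i, tid in enumerate(t_ids):
        ok = in_caliper[i].copy()
        if not spec.with_replacement:
            ok &= ~used
        if not ok.any():
            unmatched.append(tid)
            continue
        cand = np.flatnonzero(ok)
        d = D[i, cand]
        best = cand[d == d.min()]
        j = best[np.argmin(c_ids[best])]
        used[j] = True
        rows.append((tid, c_ids[j], D[i, j], abs(e_t[i] - e_c[j])))
    pairs = pd.DataFrame(
        rows, columns=["treated_id", "control_id", "distance", "propensity_gap"]
    )
    return MatchResult(pairs=pairs, unmatched=unmatched, caliper=caliper, spec=spec)


def _eqq_stats(t_vals: np.ndarray, c_vals: np.ndarray) -> tuple:
    """Mean/median/max absolute quantile difference between two samples.

    The larger sample is interpolated to the smaller sample's quantile grid.
    """
    t_vals, c_vals = np.sort(t_vals), np.sort(c_vals)
    n = min(len(t_vals), len(c_vals))
    probs = (np.arange(1, n + 1) - 0.5) / n
    qt = t_vals if len(t_vals) == n else np.quantile(t_vals, probs)
    qc = c_vals if len(c_vals) == n else np.quantile(c_vals, probs)
    diff = np.abs(qt - qc)
    return float(diff.mean()), float(np.median(diff)), float(diff.max())


def balance_table(
    X: pd.DataFrame, treated, result: MatchResult, ids=None
) -> BalanceReport:
    """Covariate balance before and after matching.

    The normalized difference is (mean_treated - mean_control) / SD, with
    the pooled pre-match SD sqrt((var_t + var_c)/2) as denominator for both
    the before and after columns so the two are comparable.  After matching,
    controls are weighted by their reuse count.  eQQ statistics are the
    mean/median/max absolute differences of same-quantile covariate values.
    """
    if len(result.pairs) == 0:
        raise DesignError("empty match result; no pairs to balance")
    treated = np.asarray(treated, dtype=bool)
    ids = np.asarray(ids if ids is not None else np.arange(len(X)))
    id_to_row = pd.Series(np.arange(len(X)), index=ids)
    t_rows = id_to_row[result.pairs["treated_id"]].to_numpy()
    c_rows = id_to_row[result.pairs["control_id"]].to_numpy()

    rows, warns = {}, []
    for cov in X.columns:
        v = X[cov].to_numpy(float)
        vt, vc = v[treated], v[~treated]
        sd = np.sqrt((vt.var(ddof=1) + vc.var(ddof=1)) / 2.0)
        if sd == 0:
            warns.append(f"covariate {cov!r} has zero variance; SMD set to 0")
            warnings.warn(warns[-1])
            smd_before = smd_after = 0.0
        else:
            smd_before = (vt.mean() - vc.mean()) / sd
            smd_after = (v[t_rows].mean() - v[c_rows].mean()) / sd
        eqq_b = _eqq_stats(vt, vc)
        eqq_a = _eqq_stats(v[t_rows], v[c_rows])
        rows[cov] = {
            "smd_before": smd_before,
            "smd_after": smd_after,
            "eqq_mean_before": eqq_b[0],
            "eqq_median_before": eqq_b[1],
            "eqq_max_before": eqq_b[2],
            "eqq_mean_after": eqq_a[0],
            "eqq_median_after": eqq_a[1],
            "eqq_max_after": eqq_a[2],
        }
    return BalanceReport(table=pd.DataFrame(rows).T, warnings=warns)


def match_units(
    units: pd.DataFrame, spec: MatchSpec = MatchSpec()
) -> tuple:
    """Convenience wrapper: propensity fit + matching + balance on a unit table.

    Returns ``(fit, result, balance)``.
    """
    X = units[list(spec.covariate_names)]
    treated = units["protected"].to_numpy(bool)
    ids = units["unit_id"].to_numpy()
    fit = fit_propensity(X, treated)
    result = match(X, treated, fit, spec, ids=ids)
    balance = balance_table(X, treated, result, ids=ids)
    return fit, result, balance
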