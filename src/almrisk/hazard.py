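"""Piecewise-constant hazard (person-period Poisson) regression.

The hazard is modelled as

    h(t) = exp(b0 + b1 * current_time + b2 * current_age + b3 * exposure + ...)

and fit by maximizing the Poisson log-likelihood of the person-period event
indicators with a log person-time offset:

    ll(b) = sum_rows [ y * (X b + log L) - L * exp(X b) ]

which is the exact likelihood of a piecewise-exponential survival model.
The exposure is standardized (mean 0, SD 1) over the whole analysis cohort
so that exp(b3) is the gradient of risk: the hazard ratio per SD.

The solver is a Newton-Raphson with analytic gradient/Hessian and
step-halving, started at b = 0 except the intercept at log(events /
person-time); the covariance is the inverse observed information, and all
inference is Wald.

`PoissonHazardRegressor` is the scikit-learn-compatible face of the solver
(fit/predict, get_params/set_params, trailing-underscore attributes);
`fit_model` builds a design from a person-period DataFrame according to a
`ModelSpec` (including the stacked competing-mortality layout) and delegates
to it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

__all__ = [
    "DegenerateInputError",
    "DesignError",
    "ZeroEventsError",
    "ModelSpec",
    "FitResult",
    "GrEstimate",
    "PoissonHazardRegressor",
    "standardize",
    "fit_model",
    "gradient_of_risk",
    "gr_at_age",
    "interaction_pvalue",
    "ci_to_se",
]

Z95 = 1.959964  # two-sided 95% normal quantile


class DegenerateInputError(ValueError):
    """Input with no usable variation."""


class DesignError(ValueError):
    """Rank-deficient or otherwise unusable design matrix."""


class ZeroEventsError(ValueError):
    """No events in the analysis dataset."""


def standardize(values) -> pd.Series:
    """Standardize to mean 0, SD 1 (denominator n-1); NaN propagates.

    The transformation is affine in the input, so hazard ratios per SD are
    invariant to any prior positive rescaling of the raw variable.
    """
    s = pd.Series(np.asarray(values, dtype=float))
    x = s.dropna()
    if len(x) < 2:
        raise DegenerateInputError("need >= 2 non-missing values to standardize")
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DegenerateInputError("zero spread: cannot standardize")
    out = (s - x.mean()) / sd
    if isinstance(values, pd.Series):
        out.index = values.index
    return out


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

def _poisson_loglik(beta, X, y, log_off):
    eta = X @ beta + log_off
    return float(y @ eta - np.exp(eta).sum())


def _newton_poisson(X, y, log_off, beta0, tol=1e-10, max_iter=100):
    """Newton-Raphson with step-halving for the offset Poisson likelihood."""
    beta = beta0.copy()
    ll = _poisson_loglik(beta, X, y, log_off)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = np.exp(X @ beta + log_off)
        grad = X.T @ (y - mu)
        hess = (X * mu[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise DesignError("singular information matrix during fit") from exc
        new_ll = _poisson_loglik(beta + step, X, y, log_off)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll) and halvings < 30:
            step *= 0.5
            halvings += 1
            new_ll = _poisson_loglik(beta + step, X, y, log_off)
        beta = beta + step
        if np.isfinite(new_ll) and abs(new_ll - ll) <= tol * (abs(ll) + 1.0):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    mu = np.exp(X @ beta + log_off)
    info = (X * mu[:, None]).T @ X
    cov = np.linalg.inv(info)
    return beta, cov, ll, it, converged


def _check_full_rank(X, names):
    g = X.T @ X
    scale = np.sqrt(np.diag(g))
    scale[scale == 0] = 1.0
    gn = g / np.outer(scale, scale)
    w, v = np.linalg.eigh(gn)
    bad = w < 1e-10
    if bad.any():
        involved = sorted(
            {names[i] for j in np.nonzero(bad)[0] for i in np.nonzero(np.abs(v[:, j]) > 0.1)[0]}
        )
        raise DesignError(f"design matrix is rank deficient; collinear terms: {involved}")


class PoissonHazardRegressor(BaseEstimator):
    """Scikit-learn-style piecewise-exponential Poisson regressor.

    Parameters
    ----------
    fit_intercept : bool
        Prepend an intercept column.
    tol : float
        Relative log-likelihood convergence tolerance.
    max_iter : int
        Newton-Raphson iteration cap.

    Attributes (after ``fit``)
    --------------------------
    coef_ : ndarray of slope coefficients (log hazard ratios)
    intercept_ : float (log baseline rate)
    cov_params_ : ndarray, inverse observed information (intercept first
        when fitted)
    loglik_ : float, maximized log-likelihood (up to the y! constant)
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, fit_intercept: bool = True, tol: float = 1e-10, max_iter: int = 100):
        self.fit_intercept = fit_intercept
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, exposure=None):
        """Fit on event counts ``y`` with person-time ``exposure`` (offset)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        y = np.asarray(y, dtype=float)
        if exposure is None:
            exposure = np.ones(len(y))
        exposure = np.asarray(exposure, dtype=float)
        if np.any(exposure <= 0):
            raise ValueError("exposure (person-time) must be positive")
        if y.sum() <= 0:
            raise ZeroEventsError("no events: the hazard is not identified")
        if self.fit_intercept:
            Xd = np.column_stack([np.ones(len(y)), X])
        else:
            Xd = X
        names = (
            (["(intercept)"] if self.fit_intercept else [])
            + [f"x{j}" for j in range(X.shape[1])]
        )
        _check_full_rank(Xd, names)
        log_off = np.log(exposure)
        beta0 = np.zeros(Xd.shape[1])
        if self.fit_intercept:
            beta0[0] = np.log(y.sum() / exposure.sum())
        beta, cov, ll, it, converged = _newton_poisson(
            Xd, y, log_off, beta0, tol=self.tol, max_iter=self.max_iter
        )
        if self.fit_intercept:
            self.intercept_ = beta[0]
            self.coef_ = beta[1:]
        else:
            self.intercept_ = 0.0
            self.coef_ = beta
        self.cov_params_ = cov
        self.loglik_ = ll
        self.n_iter_ = it
        self.converged_ = converged
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X, exposure=None):
        """Expected event counts (= rate if ``exposure`` is omitted)."""
        X = np.asarray(X, dtype=float)
        eta = self.intercept_ + X @ self.coef_
        mu = np.exp(eta)
        if exposure is not None:
            mu = mu * np.asarray(exposure, dtype=float)
        return mu


# ---------------------------------------------------------------------------
# model specification on person-period tables
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """One regression: outcome, exposure, adjustment set, interactions.

    ``adjustment`` lists covariate columns beyond ``current_time`` and
    ``current_age``, which are always included. ``interactions`` is a subset
    of {"current_age", "current_time"}: products of the exposure with those
    time-updated covariates. With ``competing_risk_duplication`` the model is
    fit on the stacked outcome+death table; terms are stratum-specific except
    those listed in ``stratum_shared``, and the reported exposure effect is
    the outcome stratum's.
    """

    outcome_cause: str
    exposure: str = "alm_ht2_z"
    adjustment: tuple = ()
    interactions: tuple = ()
    competing_risk_duplication: bool = False
    stratum_shared: tuple = ()

    def __post_init__(self):
        self.adjustment = tuple(self.adjustment)
        self.interactions = tuple(self.interactions)
        self.stratum_shared = tuple(self.stratum_shared)
        if self.exposure in self.adjustment:
            raise ValueError("exposure duplicated in adjustment")
        for term in self.interactions:
            if term not in ("current_age", "current_time"):
                raise ValueError(f"unknown interaction partner {term!r}")


@dataclass
class FitResult:
    """Fitted coefficients and Wald inference inputs for one ModelSpec."""

    coef: dict
    cov: pd.DataFrame
    loglik: float
    n_participants: int
    n_periods: int
    n_events: int
    converged: bool
    iterations: int
    spec: ModelSpec | None = None
    terms: tuple = ()

    def se(self, term: str) -> float:
        return float(np.sqrt(self.cov.loc[term, term]))


@dataclass
class GrEstimate:
    """Gradient of risk (hazard ratio per SD) with 95% CI and Wald p."""

    gr: float
    ci_low: float
    ci_high: float
    p: float
    at_age: float | None = None


def _interaction_name(exposure: str, partner: str) -> str:
    return f"{exposure}:{partner}"


def _build_design(pp: pd.DataFrame, spec: ModelSpec):
    base_terms = ["current_time", "current_age"] + list(spec.adjustment) + [spec.exposure]
    inter_terms = [_interaction_name(spec.exposure, p) for p in spec.interactions]

    cols = {}
    for name in base_terms:
        if name not in pp:
            raise DesignError(f"person-period table lacks column {name!r}")
        cols[name] = np.asarray(pp[name], dtype=float)
    for partner, name in zip(spec.interactions, inter_terms):
        cols[name] = cols[spec.exposure] * np.asarray(pp[partner], dtype=float)

    duplicated = spec.competing_risk_duplication and "cause_stratum" in pp
    names: list[str] = []
    mats: list[np.ndarray] = []
    if duplicated:
        d = (np.asarray(pp["cause_stratum"]) == "death").astype(float)
        names.append("(intercept)")
        mats.append(np.ones(len(pp)))
        if "(intercept)" not in spec.stratum_shared:
            names.append("stratum[death]")
            mats.append(d)
        for name in base_terms + inter_terms:
            names.append(name)
            mats.append(cols[name])
            if name not in spec.stratum_shared:
                names.append(f"{name}:stratum[death]")
                mats.append(cols[name] * d)
    else:
        names.append("(intercept)")
        mats.append(np.ones(len(pp)))
        for name in base_terms + inter_terms:
            names.append(name)
            mats.append(cols[name])
    X = np.column_stack(mats)
    return X, names


def fit_model(person_periods: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit the hazard model defined by ``spec`` on a person-period table.

    Rows with a missing value in any model column are dropped (complete-case
    per model); the realised participant/period/event counts are recorded on
    the result. The reported ``n_events`` counts outcome-stratum events.
    """
    pp = person_periods
    used_cols = ["current_time", "current_age", spec.exposure] + list(spec.adjustment)
    mask = np.ones(len(pp), dtype=bool)
    for name in used_cols:
        if name not in pp:
            raise DesignError(f"person-period table lacks column {name!r}")
        mask &= ~pd.isna(pp[name]).to_numpy()
    pp = pp.loc[mask]
    if len(pp) == 0:
        raise ZeroEventsError("no complete-case person-periods")

    X, names = _build_design(pp, spec)
    y = np.asarray(pp["event"], dtype=float)
    length = np.asarray(pp["length"], dtype=float)
    if y.sum() <= 0:
        raise ZeroEventsError(f"no {spec.outcome_cause} events after filtering")
    _check_full_rank(X, names)
    beta0 = np.zeros(X.shape[1])
    beta0[0] = np.log(y.sum() / length.sum())
    beta, cov, ll, it, converged = _newton_poisson(X, y, np.log(length), beta0)

    if spec.competing_risk_duplication and "cause_stratum" in pp:
        outcome_rows = np.asarray(pp["cause_stratum"]) != "death"
        n_events = int(y[outcome_rows].sum())
    else:
        n_events = int(y.sum())
    return FitResult(
        coef=dict(zip(names, beta)),
        cov=pd.DataFrame(cov, index=names, columns=names),
        loglik=ll,
        n_participants=int(pp["id"].nunique()),
        n_periods=int(len(pp)),
        n_events=n_events,
        converged=converged,
        iterations=it,
        spec=spec,
        terms=tuple(names),
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _wald(est: float, se: float, at_age: float | None = None) -> GrEstimate:
    gr = float(np.exp(est))
    if se == 0:
        return GrEstimate(gr, gr, gr, 1.0 if est == 0 else 0.0, at_age)
    z = est / se
    return GrEstimate(
        gr=gr,
        ci_low=float(np.exp(est - Z95 * se)),
        ci_high=float(np.exp(est + Z95 * se)),
        p=float(2.0 * norm.sf(abs(z))),
        at_age=at_age,
    )


def gradient_of_risk(fit: FitResult, exposure: str | None = None) -> GrEstimate:
    """GR = exp(b_exposure) with 95% Wald CI and two-sided p."""
    term = exposure or (fit.spec.exposure if fit.spec else None)
    if term is None or term not in fit.coef:
        raise KeyError(f"exposure term {term!r} not in fitted model")
    return _wald(fit.coef[term], fit.se(term))


def gr_at_age(fit: FitResult, age: float, exposure: str | None = None) -> GrEstimate:
    """Age-specific GR from an exposure x current_age interaction fit.

    log GR(age) = b3 + b4 * age, with delta-method variance
    V33 + age^2 V44 + 2 age V34.
    """
    term = exposure or (fit.spec.exposure if fit.spec else None)
    inter = _interaction_name(term, "current_age")
    if inter not in fit.coef:
        raise KeyError(f"interaction term {inter!r} not in fitted model")
    est = fit.coef[term] + age * fit.coef[inter]
    var = (
        fit.cov.loc[term, term]
        + age**2 * fit.cov.loc[inter, inter]
        + 2.0 * age * fit.cov.loc[term, inter]
    )
    return _wald(float(est), float(np.sqrt(var)), at_age=age)


def interaction_pvalue(fit: FitResult, term: str) -> float:
    """Two-sided Wald p-value for one fitted term."""
    if term not in fit.coef:
        raise KeyError(f"term {term!r} not in fitted model")
    se = fit.se(term)
    if se == 0:
        return 1.0 if fit.coef[term] == 0 else 0.0
    return float(2.0 * norm.sf(abs(fit.coef[term] / se)))


def ci_to_se(ci_low: float, ci_high: float) -> float:
    """SE of a log hazard ratio back-solved from a printed 95% CI."""
    if ci_low <= 0 or ci_high <= 0:
        raise ValueError("CI bounds must be positive")
    if ci_low > ci_high:
        raise ValueError("ci_low must be <= ci_high")
    return float((np.log(ci_high) - np.log(ci_low)) / (2.0 * Z95))
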