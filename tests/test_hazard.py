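"""Poisson hazard fitter: closed forms, oracles, Wald summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from sklearn.base import clone

import almrisk as ar
from almrisk.hazard import (
    DegenerateInputError,
    DesignError,
    FitResult,
    ModelSpec,
    PoissonHazardRegressor,
    Z95,
    ZeroEventsError,
    ci_to_se,
    gr_at_age,
    gradient_of_risk,
    interaction_pvalue,
    standardize,
)
from almrisk.persontime import ExpansionSpec, expand
from conftest import null_params


# ---------------------------------------------------------------------------
# standardize
# ---------------------------------------------------------------------------

def test_standardize_symmetric_triple():
    np.testing.assert_allclose(standardize([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])


def test_standardize_mean_zero_sd_one():
    rng = np.random.default_rng(0)
    x = rng.gamma(2.0, 3.0, size=500)
    z = standardize(x)
    assert z.mean() == pytest.approx(0.0, abs=1e-12)
    assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


def test_standardize_propagates_missing_and_rejects_degenerate():
    z = standardize(pd.Series([1.0, np.nan, 3.0]))
    assert np.isnan(z.iloc[1]) and not np.isnan(z.iloc[0])
    with pytest.raises(DegenerateInputError):
        standardize([5.0, 5.0, 5.0])
    with pytest.raises(DegenerateInputError):
        standardize([1.0])


@given(scale=st.floats(min_value=1e-3, max_value=1e3), shift=st.floats(-100, 100))
def test_standardize_affine_invariance(scale, shift):
    x = np.array([0.3, 1.7, 2.2, 5.0, 9.1])
    np.testing.assert_allclose(
        standardize(x), standardize(scale * x + shift), atol=1e-10
    )


# ---------------------------------------------------------------------------
# estimator closed forms
# ---------------------------------------------------------------------------

def test_intercept_only_mle_is_events_over_persontime():
    est = PoissonHazardRegressor().fit(
        np.empty((1, 0)), np.array([1.0]), exposure=np.array([10.0])
    )
    assert est.intercept_ == pytest.approx(np.log(0.1), abs=1e-10)
    # loglik at optimum: 1 * log(0.1 * 10) - 0.1 * 10 = -1
    assert est.loglik_ == pytest.approx(-1.0, abs=1e-10)


@given(
    events=st.lists(st.integers(0, 4), min_size=2, max_size=8).filter(
        lambda v: sum(v) > 0
    ),
    times=st.lists(st.floats(0.1, 20.0), min_size=8, max_size=8),
)
def test_intercept_only_rate_on_arbitrary_tables(events, times):
    y = np.asarray(events, dtype=float)
    t = np.asarray(times[: len(y)], dtype=float)
    est = PoissonHazardRegressor().fit(np.empty((len(y), 0)), y, exposure=t)
    assert est.intercept_ == pytest.approx(np.log(y.sum() / t.sum()), rel=1e-8)


def test_two_group_rate_ratio_exact():
    X = np.array([[1.0], [0.0]])
    y = np.array([20.0, 10.0])
    t = np.array([100.0, 100.0])
    est = PoissonHazardRegressor().fit(X, y, exposure=t)
    assert est.coef_[0] == pytest.approx(np.log(2.0), abs=1e-10)
    assert est.intercept_ == pytest.approx(np.log(0.1), abs=1e-10)


def test_estimator_sklearn_protocol():
    est = PoissonHazardRegressor(tol=1e-8, max_iter=50)
    assert est.get_params() == {"fit_intercept": True, "tol": 1e-8, "max_iter": 50}
    est2 = clone(est).set_params(max_iter=25)
    assert est2.max_iter == 25
    X = np.array([[0.0], [1.0], [0.0], [1.0]])
    est.fit(X, np.array([1.0, 2.0, 0.0, 3.0]), exposure=np.full(4, 5.0))
    mu = est.predict(X, exposure=np.full(4, 5.0))
    # fitted totals match observed totals within each exposure group (MLE score)
    assert mu[[0, 2]].sum() == pytest.approx(1.0, abs=1e-8)
    assert mu[[1, 3]].sum() == pytest.approx(5.0, abs=1e-8)


def test_zero_events_and_rank_deficiency_raise():
    with pytest.raises(ZeroEventsError):
        PoissonHazardRegressor().fit(np.zeros((3, 1)), np.zeros(3), np.ones(3))
    X = np.column_stack([np.arange(4.0), 2 * np.arange(4.0)])
    with pytest.raises(DesignError, match="collinear"):
        PoissonHazardRegressor().fit(X, np.array([1.0, 0, 1, 0]), np.ones(4))


# ---------------------------------------------------------------------------
# person-period model fits
# ---------------------------------------------------------------------------

def _simulated_fit(n=2000, seed=29, log_gr=np.log(0.85), rate=0.05, **spec_kw):
    p = null_params(n, seed, rates={"mof": rate}, log_grs={"mof": log_gr})
    b = ar.generate_baseline(p)
    fu, _ = ar.simulate_events(b, p)
    b["alm_ht2_z"] = standardize(b["alm_ht2"])
    pp = expand(b, fu, ExpansionSpec("mof"), covariates=["alm_ht2_z"])
    return b, fu, pp, ar.fit_model(pp, ModelSpec("mof", **spec_kw))


def test_fit_matches_statsmodels_glm():
    import statsmodels.api as sm

    _, _, pp, fit = _simulated_fit(n=800, seed=41)
    X = sm.add_constant(pp[["current_time", "current_age", "alm_ht2_z"]])
    oracle = sm.GLM(
        pp["event"], X, family=sm.families.Poisson(), offset=np.log(pp["length"])
    ).fit()
    assert fit.coef["alm_ht2_z"] == pytest.approx(oracle.params["alm_ht2_z"], abs=1e-7)
    assert fit.loglik == pytest.approx(oracle.llf, abs=1e-6)
    assert fit.se("alm_ht2_z") == pytest.approx(
        oracle.bse["alm_ht2_z"], rel=1e-5
    )


def test_fit_matches_cox_partial_likelihood():
    from lifelines import CoxPHFitter

    b, fu, _, fit = _simulated_fit(n=2000, seed=29)
    dat = pd.DataFrame(
        {
            "T": np.where(fu["mof_event"] == 1, fu["mof_time"], fu["followup_end"]),
            "E": fu["mof_event"],
            "z": b["alm_ht2_z"],
        }
    )
    cph = CoxPHFitter().fit(dat, duration_col="T", event_col="E")
    assert abs(fit.coef["alm_ht2_z"] - cph.params_["z"]) < 0.02


def test_fit_invariant_to_row_order_and_splitting():
    _, _, pp, fit = _simulated_fit(n=500, seed=53)
    shuffled = pp.sample(frac=1.0, random_state=1).reset_index(drop=True)
    fit_sh = ar.fit_model(shuffled, ModelSpec("mof"))
    for k, v in fit.coef.items():
        assert fit_sh.coef[k] == pytest.approx(v, abs=1e-8)
    # split every row in half, keeping covariates (event stays on 2nd half)
    a = pp.copy()
    b2 = pp.copy()
    a["length"] = pp["length"] / 2
    a["event"] = 0
    b2["length"] = pp["length"] / 2
    halved = pd.concat([a, b2], ignore_index=True)
    fit_half = ar.fit_model(halved, ModelSpec("mof"))
    for k, v in fit.coef.items():
        assert fit_half.coef[k] == pytest.approx(v, abs=1e-8)


def test_complete_case_filtering_counts():
    b, fu, pp, _ = _simulated_fit(n=500, seed=61)
    b["prior_falls"] = np.where(np.arange(len(b)) % 5 == 0, np.nan, b["prior_falls"])
    pp2 = expand(
        b, fu, ExpansionSpec("mof"), covariates=["alm_ht2_z", "prior_falls"]
    )
    fit = ar.fit_model(pp2, ModelSpec("mof", adjustment=("prior_falls",)))
    assert fit.n_participants == int(b["prior_falls"].notna().sum())


def test_missing_term_errors():
    _, _, _, fit = _simulated_fit(n=500, seed=61)
    with pytest.raises(KeyError):
        gradient_of_risk(fit, "not_a_term")
    with pytest.raises(KeyError):
        gr_at_age(fit, 60.0)  # no interaction in this fit
    with pytest.raises(KeyError):
        interaction_pvalue(fit, "alm_ht2_z:current_age")


# ---------------------------------------------------------------------------
# Wald summaries (closed forms)
# ---------------------------------------------------------------------------

def _manual_fit(coef: dict, cov: np.ndarray, exposure="z") -> FitResult:
    names = list(coef)
    return FitResult(
        coef=coef,
        cov=pd.DataFrame(cov, index=names, columns=names),
        loglik=0.0,
        n_participants=0,
        n_periods=0,
        n_events=0,
        converged=True,
        iterations=1,
        spec=ModelSpec("mof", exposure=exposure),
        terms=tuple(names),
    )


def test_gradient_of_risk_null_effect():
    fit = _manual_fit({"z": 0.0}, np.array([[0.04]]))
    gr = gradient_of_risk(fit)
    assert gr.gr == 1.0
    assert gr.ci_low < 1.0 < gr.ci_high
    assert gr.p == pytest.approx(1.0)


@pytest.mark.parametrize(
    "beta, se, lo, hi",
    [(np.log(0.88), 0.0317, 0.83, 0.94), (np.log(1.13), 0.0226, 1.08, 1.18)],
)
def test_gradient_of_risk_closed_form(beta, se, lo, hi):
    fit = _manual_fit({"z": beta}, np.array([[se**2]]))
    gr = gradient_of_risk(fit)
    assert gr.gr == pytest.approx(np.exp(beta))
    assert gr.ci_low == pytest.approx(lo, abs=0.005)
    assert gr.ci_high == pytest.approx(hi, abs=0.005)
    assert gr.ci_low <= gr.gr <= gr.ci_high and 0 <= gr.p <= 1


def test_gr_at_age_delta_method_hand_example():
    cov = np.array([[0.01, -1e-4], [-1e-4, 1e-6]])
    fit = _manual_fit({"z": 0.5, "z:current_age": -0.005}, cov)
    gr = gr_at_age(fit, 60.0)
    assert gr.gr == pytest.approx(np.exp(0.2))
    var = 0.01 + 60**2 * 1e-6 + 2 * 60 * (-1e-4)
    assert var == pytest.approx(0.0016)
    assert gr.ci_low == pytest.approx(np.exp(0.2 - Z95 * 0.04), rel=1e-6)
    assert gr.ci_high == pytest.approx(np.exp(0.2 + Z95 * 0.04), rel=1e-6)


def test_gr_at_age_no_interaction_is_constant():
    cov = np.array([[0.01, 0.0], [0.0, 1e-6]])
    fit = _manual_fit({"z": np.log(0.9), "z:current_age": 0.0}, cov)
    assert gr_at_age(fit, 50.0).gr == pytest.approx(gr_at_age(fit, 80.0).gr)
    assert gr_at_age(fit, 50.0).gr == pytest.approx(0.9)


def test_negative_interaction_gives_decreasing_gr():
    cov = np.diag([0.01, 1e-6])
    fit = _manual_fit({"z": 0.5, "z:current_age": -0.006}, cov)
    grs = [gr_at_age(fit, a).gr for a in (50, 60, 70, 80)]
    assert all(a > b for a, b in zip(grs, grs[1:]))


def test_interaction_pvalue_normal_quantiles():
    cov = np.diag([0.01, 0.0004])
    fit = _manual_fit({"z": 0.1, "z:current_age": 0.0}, cov)
    assert interaction_pvalue(fit, "z:current_age") == pytest.approx(1.0)
    fit2 = _manual_fit({"z": 0.1, "z:current_age": 1.96 * 0.02}, cov)
    assert interaction_pvalue(fit2, "z:current_age") == pytest.approx(0.05, abs=1e-3)


def test_ci_to_se():
    assert ci_to_se(1.0, 1.0) == 0.0
    assert ci_to_se(0.83, 0.94) == pytest.approx(0.0317, abs=3e-4)
    assert ci_to_se(1.08, 1.18) == pytest.approx(0.0226, abs=3e-4)
    with pytest.raises(ValueError):
        ci_to_se(-1.0, 2.0)
    with pytest.raises(ValueError):
        ci_to_se(1.2, 1.1)
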