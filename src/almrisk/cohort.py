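"""Synthetic cohort generator for an older-women DXA body-composition study.

Emulates the statistical structure of a large prospective postmenopausal
cohort: baseline covariates (age, anthropometry, appendicular lean mass,
femoral neck BMD, clinical risk factors, pseudo-FRAX probabilities,
trial-arm assignment), and competing-risk follow-up (four nested fracture
outcomes, questionnaire-ascertained falls, death, loss to follow-up,
administrative censoring).

The generator works on pandas DataFrames:

``baseline`` (one row per participant)
    id, age_baseline (y), height (cm), weight (kg), bmi (kg/m2), alm (g),
    alm_ht2 (g/cm2), fn_bmd (g/cm2), fn_tscore, total_fat_mass (kg),
    waist_hip_ratio, prior_fracture, parental_hip_fracture, smoking,
    corticosteroids, rheumatoid_arthritis, excess_alcohol, prior_falls
    (floats 0/1 with NaN for missing), frax_mof_nobmd (%), frax_mof_bmd (%),
    arm_dm / arm_ht / arm_cad ({active, placebo, not_enrolled}),
    os_participant (0/1).

``followup`` (one row per participant)
    id, followup_end (y), death_event, death_time, dropout_time,
    <cause>_event / <cause>_time for each simulated cause, has_fall_data.

``fall_reports`` (long format)
    id, contact_time (y), falls_count (0-3, 3 = "3 or more").

Event-time simulation uses monthly Bernoulli draws with per-interval
probability 1 - exp(-lambda * dt) under a log-linear hazard
lambda = baseline_rate * exp(age_log_slope * (age - ref_age)
+ exposure_log_gr * z + sum(extra_loghr * covariate)), so that survival over
k months composes exactly to the continuous-time exponential form.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit
from scipy.stats import truncnorm

__all__ = [
    "CauseHazard",
    "FraxCalibration",
    "GeneratorParams",
    "default_params",
    "generate_baseline",
    "compute_frax_like",
    "simulate_events",
    "true_gr",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "params_to_yaml",
    "params_from_yaml",
]

MONTH = 1.0 / 12.0  # month = 1/12 year exactly, package-wide

FRACTURE_CAUSES = ("any_fx", "osteoporotic_fx", "mof", "hip_fx")
ALL_CAUSES = FRACTURE_CAUSES + ("fall", "death")

BINARY_FACTORS = (
    "prior_fracture",
    "parental_hip_fracture",
    "smoking",
    "corticosteroids",
    "rheumatoid_arthritis",
    "excess_alcohol",
    "prior_falls",
)


class ParameterError(ValueError):
    """Invalid generator configuration."""


@dataclass
class CauseHazard:
    """Log-linear hazard for one cause of failure.

    ``baseline_rate`` is the rate (events / person-year) at the reference age
    with standardized exposure z = 0 and all ``extra_loghr`` covariates at 0.
    ``exposure_age_log_slope`` lets the per-SD exposure effect drift linearly
    with current age (an exposure x age interaction on the log-hazard scale).
    """

    cause: str
    baseline_rate: float
    age_log_slope: float = 0.0
    exposure_log_gr: float = 0.0
    extra_loghr: dict = field(default_factory=dict)
    exposure_age_log_slope: float = 0.0

    def validate(self) -> None:
        if self.baseline_rate < 0:
            raise ParameterError(f"baseline_rate < 0 for cause {self.cause!r}")


@dataclass
class FraxCalibration:
    """Coefficients of the pseudo-FRAX linear predictors.

    The 10-year major-osteoporotic-fracture probability is emulated as
    100 * logistic(lp); lp is linear in age, BMI, the binary clinical risk
    factors and (for the with-BMD variant) the femoral neck T-score. Only
    monotonicity and the calibrated cohort means are contractual.
    """

    intercept_nobmd: float = -2.4677
    intercept_bmd: float = -2.8816
    age_slope: float = 0.055  # per year
    bmi_slope: float = -0.02  # per kg/m2, protective
    tscore_slope: float = -0.35  # per T-score unit, with-BMD variant only
    risk_factor_weights: dict = field(
        default_factory=lambda: {
            "prior_fracture": 0.55,
            "parental_hip_fracture": 0.35,
            "smoking": 0.25,
            "corticosteroids": 0.45,
            "rheumatoid_arthritis": 0.30,
            "excess_alcohol": 0.25,
        }
    )
    ref_age: float = 63.3
    ref_bmi: float = 28.2


def _default_hazards() -> dict:
    # Baseline rates are calibrated (see docs/methods.md) so that, under the
    # default covariate distributions, cumulative first-event proportions over
    # follow-up match the emulated cohort: any fracture 15%, osteoporotic 11%,
    # MOF 9%, hip 3%, any reported fall 69%, death 20%.
    # Exposure log-HRs are the BMD-conditional values; combined with the
    # T-score effects and corr(ALM/ht2, BMD) = 0.41 they imply marginal per-SD
    # GRs of about 0.91 / 0.90 / 0.88 / 0.81 for the four fracture outcomes.
    return {
        "any_fx": CauseHazard(
            "any_fx",
            baseline_rate=0.005348,
            age_log_slope=0.035,
            exposure_log_gr=np.log(1.05),
            extra_loghr={"fn_tscore": -0.298, "prior_falls": np.log(1.2)},
        ),
        "osteoporotic_fx": CauseHazard(
            "osteoporotic_fx",
            baseline_rate=0.003125,
            age_log_slope=0.042,
            exposure_log_gr=np.log(1.07),
            extra_loghr={"fn_tscore": -0.361, "prior_falls": np.log(1.2)},
        ),
        "mof": CauseHazard(
            "mof",
            baseline_rate=0.002339,
            age_log_slope=0.045,
            exposure_log_gr=np.log(1.06),
            extra_loghr={"fn_tscore": -0.388, "prior_falls": np.log(1.2)},
        ),
        "hip_fx": CauseHazard(
            "hip_fx",
            baseline_rate=0.000312,
            age_log_slope=0.10,
            exposure_log_gr=0.0,
            extra_loghr={"fn_tscore": -0.439, "prior_falls": np.log(1.2)},
        ),
        "fall": CauseHazard(
            "fall",
            baseline_rate=0.082013,
            age_log_slope=0.025,
            exposure_log_gr=np.log(0.98),
            extra_loghr={"prior_falls": np.log(1.8)},
        ),
        "death": CauseHazard(
            "death",
            baseline_rate=0.004456,
            age_log_slope=0.09,
            exposure_log_gr=np.log(1.13),
            extra_loghr={"prior_falls": np.log(1.2)},
            exposure_age_log_slope=-0.0058,
        ),
    }


@dataclass
class GeneratorParams:
    """Full configuration of the synthetic cohort.

    Defaults are calibrated to the emulated cohort's printed summary
    statistics (moments, prevalences, the ALM-BMD correlation, follow-up and
    event frequencies); see docs/methods.md for the calibration procedure.
    """

    n: int = 11187
    seed: int = 0
    # baseline covariates
    age_range: tuple = (50.0, 79.0)
    age_mean: float = 63.3
    age_sd: float = 7.4
    height_mean: float = 161.6  # cm
    height_sd: float = 6.4
    bmi_mean: float = 28.2  # kg/m2
    bmi_sd: float = 5.9
    alm_ht2_mean: float = 0.56  # g/cm2
    alm_ht2_sd: float = 0.10
    fn_bmd_mean: float = 0.72  # g/cm2
    fn_bmd_sd: float = 0.13
    alm_bmd_corr: float = 0.41
    alm_bmi_corr: float = 0.70
    bmd_bmi_corr: float = 0.30
    tscore_ref: tuple = (0.849, 0.111)  # young-adult FN BMD mean, SD (g/cm2)
    covariate_prevalences: dict = field(
        default_factory=lambda: {
            "prior_fracture": 1325 / 7685,
            "parental_hip_fracture": 1326 / 10927,
            "smoking": 889 / 11029,
            "corticosteroids": 98 / 11187,
            "rheumatoid_arthritis": 607 / 10384,
            "excess_alcohol": 324 / 11151,
            "prior_falls": 3307 / 10067,
        }
    )
    missing_rates: dict = field(
        default_factory=lambda: {
            "prior_fracture": 1 - 7685 / 11187,
            "parental_hip_fracture": 1 - 10927 / 11187,
            "smoking": 1 - 11029 / 11187,
            "corticosteroids": 0.0,
            "rheumatoid_arthritis": 1 - 10384 / 11187,
            "excess_alcohol": 1 - 11151 / 11187,
            "prior_falls": 1 - 10067 / 11187,
        }
    )
    trial_enrollment: dict = field(
        default_factory=lambda: {"dm": 0.35, "ht": 0.30, "cad": 0.40}
    )
    frax_calibration: FraxCalibration = field(default_factory=FraxCalibration)
    # follow-up / events
    hazard_params: dict = field(default_factory=_default_hazards)
    ref_age: float = 63.3
    max_followup: float = 21.5  # years, administrative censoring
    dropout_rate: float = 0.03121  # per-year exponential loss to follow-up
    fall_contact_interval: float = 1.0  # years between fall questionnaires
    fall_data_missing_rate: float = 43 / 11187

    def validate(self) -> None:
        if self.n < 0:
            raise ParameterError("n must be >= 0")
        for name, p in self.covariate_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"prevalence of {name!r} outside [0, 1]")
        for name, p in self.missing_rates.items():
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"missing rate of {name!r} outside [0, 1]")
        if not abs(self.alm_bmd_corr) < 1:
            raise ParameterError("|alm_bmd_corr| must be < 1")
        if self.max_followup <= 0:
            raise ParameterError("max_followup must be > 0")
        if self.dropout_rate < 0:
            raise ParameterError("dropout_rate must be >= 0")
        if self.fall_contact_interval <= 0:
            raise ParameterError("fall_contact_interval must be > 0")
        causes = set()
        for cause, hz in self.hazard_params.items():
            hz.validate()
            if cause in causes:
                raise ParameterError(f"duplicate cause {cause!r}")
            causes.add(cause)


def default_params(**overrides) -> GeneratorParams:
    """Default :class:`GeneratorParams`, optionally overriding top-level fields."""
    params = GeneratorParams(**overrides)
    params.validate()
    return params


# ---------------------------------------------------------------------------
# baseline
# ---------------------------------------------------------------------------

def _latent_covariance(params: GeneratorParams) -> np.ndarray:
    c = np.array(
        [
            [1.0, params.alm_bmd_corr, params.alm_bmi_corr],
            [params.alm_bmd_corr, 1.0, params.bmd_bmi_corr],
            [params.alm_bmi_corr, params.bmd_bmi_corr, 1.0],
        ]
    )
    if np.linalg.eigvalsh(c).min() <= 0:
        raise ParameterError("latent correlation matrix is not positive definite")
    return c


def generate_baseline(params: GeneratorParams) -> pd.DataFrame:
    """Draw the baseline table; deterministic for a fixed ``params.seed``."""
    params.validate()
    rng = np.random.default_rng([params.seed, 0])
    n = params.n
    cols: dict = {"id": np.arange(n, dtype=np.int64)}

    lo, hi = params.age_range
    a = (lo - params.age_mean) / params.age_sd
    b = (hi - params.age_mean) / params.age_sd
    cols["age_baseline"] = truncnorm.rvs(
        a, b, loc=params.age_mean, scale=params.age_sd, size=n, random_state=rng
    )

    height = rng.normal(params.height_mean, params.height_sd, size=n)
    height = np.clip(height, 120.0, 215.0)
    cols["height"] = height

    z = rng.multivariate_normal(
        np.zeros(3), _latent_covariance(params), size=n, method="cholesky"
    ) if n else np.zeros((0, 3))
    z_alm, z_bmd, z_bmi = z.T
    alm_ht2 = np.clip(params.alm_ht2_mean + params.alm_ht2_sd * z_alm, 0.2, None)
    fn_bmd = np.clip(params.fn_bmd_mean + params.fn_bmd_sd * z_bmd, 0.25, None)
    bmi = np.clip(params.bmi_mean + params.bmi_sd * z_bmi, 14.5, 69.0)
    cols["bmi"] = bmi
    cols["weight"] = bmi * (height / 100.0) ** 2
    cols["alm_ht2"] = alm_ht2
    cols["alm"] = alm_ht2 * height**2  # g; alm/height^2 == alm_ht2 exactly
    cols["fn_bmd"] = fn_bmd
    ref_mean, ref_sd = params.tscore_ref
    cols["fn_tscore"] = (fn_bmd - ref_mean) / ref_sd

    fat_frac = np.clip(0.18 + 0.008 * bmi + 0.03 * rng.normal(size=n), 0.12, 0.60)
    cols["total_fat_mass"] = cols["weight"] * fat_frac
    cols["waist_hip_ratio"] = np.clip(
        0.84 + 0.03 * z_bmi + 0.045 * rng.normal(size=n), 0.60, 1.20
    )

    for name in BINARY_FACTORS:
        p = params.covariate_prevalences.get(name, 0.0)
        vals = (rng.random(n) < p).astype(float)
        miss = params.missing_rates.get(name, 0.0)
        if miss > 0:
            vals[rng.random(n) < miss] = np.nan
        cols[name] = vals

    for trial, p_enroll in params.trial_enrollment.items():
        enrolled = rng.random(n) < p_enroll
        active = rng.random(n) < 0.5
        arm = np.where(enrolled, np.where(active, "active", "placebo"), "not_enrolled")
        cols[f"arm_{trial}"] = arm
    enrolled_any = np.zeros(n, dtype=bool)
    for trial in params.trial_enrollment:
        enrolled_any |= np.asarray(cols[f"arm_{trial}"]) != "not_enrolled"
    cols["os_participant"] = (~enrolled_any).astype(float)

    df = pd.DataFrame(cols)
    frax_nobmd, frax_bmd = compute_frax_like(df, params.frax_calibration)
    df["frax_mof_nobmd"] = frax_nobmd
    df["frax_mof_bmd"] = frax_bmd
    return df


def compute_frax_like(records, calibration: FraxCalibration | None = None):
    """Pseudo-FRAX 10-year MOF probabilities (%, without and with BMD).

    Accepts a baseline DataFrame or a single record (Series / mapping).
    Missing risk factors score as absent. Monotone increasing in age and each
    risk factor; the with-BMD variant is monotone decreasing in the T-score.
    Outputs are strictly inside (0, 100).
    """
    cal = calibration or FraxCalibration()
    single = not isinstance(records, pd.DataFrame)
    df = pd.DataFrame([records]) if single else records
    lp = np.zeros(len(df))
    lp = lp + cal.age_slope * (np.asarray(df["age_baseline"], dtype=float) - cal.ref_age)
    lp = lp + cal.bmi_slope * (np.asarray(df["bmi"], dtype=float) - cal.ref_bmi)
    for name, w in cal.risk_factor_weights.items():
        if name in df:
            x = np.nan_to_num(np.asarray(df[name], dtype=float), nan=0.0)
            lp = lp + w * x
    frax_nobmd = 100.0 * expit(cal.intercept_nobmd + lp)
    tscore = np.asarray(df["fn_tscore"], dtype=float)
    frax_bmd = 100.0 * expit(cal.intercept_bmd + lp + cal.tscore_slope * tscore)
    if single:
        return float(frax_nobmd[0]), float(frax_bmd[0])
    return frax_nobmd, frax_bmd


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

def _exposure_z(baseline: pd.DataFrame, params: GeneratorParams) -> np.ndarray:
    # Population-standardized exposure: the generator's "per SD" scale.
    return (np.asarray(baseline["alm_ht2"], float) - params.alm_ht2_mean) / params.alm_ht2_sd


def _log_hazard(
    hz: CauseHazard,
    ages: np.ndarray,
    z: np.ndarray,
    baseline: pd.DataFrame,
    ref_age: float,
) -> np.ndarray:
    """Log hazard matrix (n x m) for one cause at per-interval current ages."""
    if hz.baseline_rate == 0:
        return np.full(ages.shape, -np.inf)
    eta = np.log(hz.baseline_rate) + hz.age_log_slope * (ages - ref_age)
    beta_z = hz.exposure_log_gr + hz.exposure_age_log_slope * (ages - ref_age)
    eta = eta + beta_z * z[:, None]
    for name, loghr in hz.extra_loghr.items():
        x = np.nan_to_num(np.asarray(baseline[name], dtype=float), nan=0.0)
        eta = eta + loghr * x[:, None]
    return eta


def _first_event_times(
    lam: np.ndarray, dt: np.ndarray, t_edges: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """First event time per row of a piecewise-constant hazard matrix.

    Monthly Bernoulli draws with p = 1 - exp(-lambda*dt); the event time is
    uniform within its interval. Rows without an event get +inf.
    """
    p = -np.expm1(-lam * dt[None, :])
    hit = rng.random(lam.shape) < p
    frac = rng.random(lam.shape[0])
    any_hit = hit.any(axis=1)
    k = np.argmax(hit, axis=1)
    times = t_edges[k] + frac * dt[k]
    return np.where(any_hit, times, np.inf)


def simulate_events(baseline: pd.DataFrame, params: GeneratorParams):
    """Simulate competing-risk follow-up for a baseline table.

    Returns ``(followup, fall_reports)`` DataFrames. Death truncates every
    other process; all processes are administratively censored at
    ``params.max_followup``; loss to follow-up is exponential with rate
    ``params.dropout_rate``. Deterministic for fixed ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng([params.seed, 1])
    n = len(baseline)
    hz = params.hazard_params
    requested = [c for c in ALL_CAUSES if c in hz]
    for cause in requested:
        if hz[cause].cause != cause:
            raise ParameterError(
                f"hazard_params[{cause!r}] has mismatched cause label {hz[cause].cause!r}"
            )

    m = int(np.ceil(params.max_followup / MONTH - 1e-9))
    t_edges = np.arange(m) * MONTH
    dt = np.minimum(t_edges + MONTH, params.max_followup) - t_edges
    age0 = np.asarray(baseline["age_baseline"], dtype=float)
    ages_mid = age0[:, None] + (t_edges + dt / 2.0)[None, :]
    z = _exposure_z(baseline, params)

    # --- death (drawn first; truncates everything else) ---
    if "death" in hz:
        lam_d = np.exp(_log_hazard(hz["death"], ages_mid, z, baseline, params.ref_age))
        t_death = _first_event_times(lam_d, dt, t_edges, rng)
    else:
        t_death = np.full(n, np.inf)

    # --- nested fracture outcomes via disjoint sub-cause processes ---
    frac_present = [c for c in FRACTURE_CAUSES if c in hz]
    # composite hazards, finest (hip) to broadest (any)
    order = [c for c in ("hip_fx", "mof", "osteoporotic_fx", "any_fx") if c in frac_present]
    lam_comp = {
        c: np.exp(_log_hazard(hz[c], ages_mid, z, baseline, params.ref_age))
        for c in order
    }
    comp_time: dict = {}
    inner_time = np.full(n, np.inf)
    inner_lam = 0.0
    for c in order:
        lam_sub = np.clip(lam_comp[c] - inner_lam, 0.0, None)
        t_sub = _first_event_times(lam_sub, dt, t_edges, rng)
        comp_time[c] = np.minimum(t_sub, inner_time)
        inner_time = comp_time[c]
        inner_lam = lam_comp[c]

    # --- dropout, administrative censoring, observation end ---
    if params.dropout_rate > 0:
        t_drop = rng.exponential(1.0 / params.dropout_rate, size=n)
    else:
        t_drop = np.full(n, np.inf)
    t_admin = params.max_followup
    t_end = np.minimum(np.minimum(t_death, t_drop), t_admin)
    death_event = t_death <= np.minimum(t_drop, t_admin)

    out: dict = {"id": np.asarray(baseline["id"])}
    out["followup_end"] = t_end
    out["death_event"] = death_event.astype(int)
    out["death_time"] = np.where(death_event, t_death, np.nan)
    out["dropout_time"] = np.where(
        (t_drop < t_admin) & ~death_event & (t_drop <= t_end), t_drop, np.nan
    )
    for c in frac_present:
        tt = comp_time[c]
        ev = tt < t_end
        out[f"{c}_event"] = ev.astype(int)
        out[f"{c}_time"] = np.where(ev, tt, np.nan)

    # --- fall questionnaires ---
    fall_rows = {"id": [], "contact_time": [], "falls_count": []}
    has_fall_data = np.ones(n, dtype=bool)
    t_fall = np.full(n, np.inf)
    fall_event = np.zeros(n, dtype=bool)
    if "fall" in hz and n:
        if params.fall_data_missing_rate > 0:
            has_fall_data = rng.random(n) >= params.fall_data_missing_rate
        gap = params.fall_contact_interval
        n_contacts = int(np.floor(params.max_followup / gap + 1e-9))
        contacts = (np.arange(1, n_contacts + 1) * gap)[None, :]
        ages_c = age0[:, None] + contacts - gap / 2.0
        lam_f = np.exp(
            _log_hazard(hz["fall"], ages_c, z, baseline, params.ref_age)
        )
        mu = lam_f * gap
        p_any = -np.expm1(-mu)
        observed = (contacts <= t_end[:, None] + 1e-12) & has_fall_data[:, None]
        u = rng.random(mu.shape)
        fell = (u < p_any) & observed
        # falls count | >= 1 fall: truncated Poisson(mu), top-coded at 3
        p1 = mu * np.exp(-mu) / np.where(p_any > 0, p_any, 1.0)
        p2 = mu**2 / 2.0 * np.exp(-mu) / np.where(p_any > 0, p_any, 1.0)
        u2 = rng.random(mu.shape)
        counts = np.where(u2 < p1, 1, np.where(u2 < p1 + p2, 2, 3))
        counts = np.where(fell, counts, 0)
        ii, jj = np.nonzero(observed)
        fall_rows["id"] = np.asarray(baseline["id"])[ii]
        fall_rows["contact_time"] = contacts[0, jj]
        fall_rows["falls_count"] = counts[ii, jj]
        first = np.where(fell.any(axis=1), np.argmax(fell, axis=1), -1)
        fall_event = first >= 0
        t_fall = np.where(fall_event, contacts[0, first], np.inf)
        out["fall_event"] = fall_event.astype(int)
        out["fall_time"] = np.where(fall_event, t_fall, np.nan)
    out["has_fall_data"] = has_fall_data.astype(int)

    followup = pd.DataFrame(out)
    fall_reports = pd.DataFrame(
        {
            "id": np.asarray(fall_rows["id"], dtype=np.int64),
            "contact_time": np.asarray(fall_rows["contact_time"], dtype=float),
            "falls_count": np.asarray(fall_rows["falls_count"], dtype=np.int64),
        }
    )
    return followup, fall_reports


def true_gr(params: GeneratorParams, cause: str) -> float:
    """Generator-truth gradient of risk (hazard ratio per SD) for ``cause``."""
    if cause not in params.hazard_params:
        raise ParameterError(f"unknown cause {cause!r}")
    return float(np.exp(params.hazard_params[cause].exposure_log_gr))


def generate_cohort(params: GeneratorParams):
    """Baseline + follow-up + fall reports in one seeded call."""
    baseline = generate_baseline(params)
    followup, fall_reports = simulate_events(baseline, params)
    return baseline, followup, fall_reports


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_cohort(baseline, followup, fall_reports, outdir) -> None:
    """Write baseline.csv / followup.csv / falls.csv under ``outdir``."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    baseline.to_csv(outdir / "baseline.csv", index=False)
    followup.to_csv(outdir / "followup.csv", index=False)
    fall_reports.to_csv(outdir / "falls.csv", index=False)


def read_cohort(indir):
    """Read the three cohort CSVs written by :func:`write_cohort`."""
    from pathlib import Path

    indir = Path(indir)
    baseline = pd.read_csv(indir / "baseline.csv")
    followup = pd.read_csv(indir / "followup.csv")
    falls_path = indir / "falls.csv"
    fall_reports = (
        pd.read_csv(falls_path)
        if falls_path.exists()
        else pd.DataFrame(columns=["id", "contact_time", "falls_count"])
    )
    return baseline, followup, fall_reports


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def params_to_yaml(params: GeneratorParams, path) -> None:
    """Serialize params to a plain-text config file (nested key: value)."""
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(params), fh, sort_keys=False)


def params_from_yaml(path) -> GeneratorParams:
    """Load :class:`GeneratorParams` from a config file written by
    :func:`params_to_yaml` (missing keys fall back to defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return params_from_dict(raw)


def params_from_dict(raw: dict) -> GeneratorParams:
    params = GeneratorParams()
    for key, value in raw.items():
        if key == "frax_calibration":
            params.frax_calibration = FraxCalibration(**value)
        elif key == "hazard_params":
            params.hazard_params = {
                cause: CauseHazard(**hz) for cause, hz in value.items()
            }
        elif key in ("age_range", "tscore_ref"):
            setattr(params, key, tuple(value))
        elif hasattr(params, key):
            setattr(params, key, value)
        else:
            raise ParameterError(f"unknown generator parameter {key!r}")
    params.validate()
    return params
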