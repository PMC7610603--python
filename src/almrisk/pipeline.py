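"""End-to-end study driver.

Runs the whole analysis on a cohort (synthetic or user-supplied CSVs):
baseline summary table, gradient-of-risk grids over sequential adjustment
sets for the four fracture outcomes and for falls / death, age-specific GRs
with exposure x age interaction tests, and the post hoc mortality models
with body-fat covariates.

All models share the hazard form exp(b0 + b1 current_time + b2 current_age
+ b3 exposure + adjustments); fracture and fall models account for competing
mortality through the stacked person-period duplication (disable with
``competing_risk_duplication=False``); death models treat death as the
outcome directly. The exposure is standardized once on the whole cohort
before any expansion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    FRACTURE_CAUSES,
    GeneratorParams,
    default_params,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from .hazard import (
    ModelSpec,
    ZeroEventsError,
    fit_model,
    gr_at_age,
    gradient_of_risk,
    interaction_pvalue,
    standardize,
)
from .persontime import MONTH, ExpansionSpec, duplicate_for_competing_risk, expand

__all__ = [
    "StudyConfig",
    "AnalysisError",
    "summarize_baseline",
    "run_fracture_grid",
    "run_falls_death",
    "run_age_specific",
    "run_all",
    "format_p",
]

logger = logging.getLogger(__name__)

#: adjustment-set label -> covariate columns added on top of the base model
ADJUSTMENT_SETS = {
    "base": (),
    "+prior_falls": ("prior_falls",),
    "+frax_nobmd": ("log_frax_nobmd",),
    "+frax_bmd": ("log_frax_bmd",),
    "+fn_tscore": ("fn_tscore",),
    "+fat_mass": ("total_fat_mass",),
    "+waist_hip": ("waist_hip_ratio",),
}

_ARM_DUMMIES = (
    "arm_dm_active",
    "arm_dm_placebo",
    "arm_ht_active",
    "arm_ht_placebo",
    "arm_cad_active",
    "arm_cad_placebo",
)


class AnalysisError(RuntimeError):
    """A fit failed; carries the (outcome, adjustment) cell."""


@dataclass
class StudyConfig:
    """Configuration of one full study run."""

    generator: GeneratorParams = field(default_factory=default_params)
    input_dir: str | None = None  # read cohort CSVs instead of simulating
    outcomes: tuple = FRACTURE_CAUSES
    exposure: str = "alm_ht2"  # or "alm", "alm_over_bmi"
    adjustments: tuple = (
        "base",
        "+prior_falls",
        "+frax_nobmd",
        "+frax_bmd",
        "+fn_tscore",
    )
    mortality_extra: tuple = ("+fat_mass", "+waist_hip")
    ages: tuple = (50.0, 60.0, 70.0, 80.0)
    age_specific_outcomes: tuple = ("osteoporotic_fx", "hip_fx", "fall", "death")
    competing_risk_duplication: bool = True
    interval_length: float = MONTH
    frax_log: bool = True  # FRAX probabilities enter models log-transformed
    out_dir: str | None = None

    def __post_init__(self):
        if not self.outcomes:
            raise ValueError("outcomes must be non-empty")
        for label in tuple(self.adjustments) + tuple(self.mortality_extra):
            if label not in ADJUSTMENT_SETS:
                raise ValueError(f"unknown adjustment set {label!r}")


# ---------------------------------------------------------------------------
# covariate preparation
# ---------------------------------------------------------------------------

def prepare_covariates(baseline: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Derived analysis columns: standardized exposure, log FRAX, arm dummies."""
    df = baseline.copy()
    if config.exposure == "alm_ht2":
        raw = df["alm_ht2"]
    elif config.exposure == "alm":
        raw = df["alm"]
    elif config.exposure == "alm_over_bmi":
        raw = df["alm"] / df["bmi"]
    else:
        raise ValueError(f"unknown exposure {config.exposure!r}")
    df[exposure_column(config)] = standardize(raw)
    if config.frax_log:
        df["log_frax_nobmd"] = np.log(df["frax_mof_nobmd"])
        df["log_frax_bmd"] = np.log(df["frax_mof_bmd"])
    else:
        df["log_frax_nobmd"] = df["frax_mof_nobmd"]
        df["log_frax_bmd"] = df["frax_mof_bmd"]
    for trial in ("dm", "ht", "cad"):
        col = f"arm_{trial}"
        if col in df:
            df[f"{col}_active"] = (df[col] == "active").astype(float)
            df[f"{col}_placebo"] = (df[col] == "placebo").astype(float)
    return df


def exposure_column(config: StudyConfig) -> str:
    return f"{config.exposure}_z"


def base_adjustment(baseline: pd.DataFrame) -> tuple:
    """Randomization-arm dummies + observational-study flag (where present)."""
    cols = [c for c in _ARM_DUMMIES if c in baseline]
    if "os_participant" in baseline:
        cols.append("os_participant")
    return tuple(cols)


def _model_columns(config: StudyConfig, labels) -> list:
    cols = {exposure_column(config)}
    for label in labels:
        cols.update(ADJUSTMENT_SETS[label])
    return sorted(cols)


def _person_periods(baseline, followup, outcome, config, covariates):
    if outcome == "fall" and "has_fall_data" in followup:
        followup = followup[followup["has_fall_data"] == 1]
    duplicate = config.competing_risk_duplication and outcome != "death"
    if duplicate:
        return duplicate_for_competing_risk(
            baseline,
            followup,
            outcome,
            interval_length=config.interval_length,
            covariates=covariates,
        )
    censor = (
        frozenset({"dropout", "admin"})
        if outcome == "death"
        else frozenset({"death", "dropout", "admin"})
    )
    spec = ExpansionSpec(
        outcome, censor_causes=censor, interval_length=config.interval_length
    )
    return expand(baseline, followup, spec, covariates=covariates)


def _grid(baseline, followup, outcomes, labels_by_outcome, config) -> pd.DataFrame:
    rows = []
    for outcome in outcomes:
        labels = labels_by_outcome[outcome]
        covs = list(base_adjustment(baseline)) + _model_columns(config, labels)
        pp = _person_periods(baseline, followup, outcome, config, covs)
        for label in labels:
            spec = ModelSpec(
                outcome_cause=outcome,
                exposure=exposure_column(config),
                adjustment=base_adjustment(baseline) + ADJUSTMENT_SETS[label],
                competing_risk_duplication=config.competing_risk_duplication
                and outcome != "death",
            )
            try:
                fit = fit_model(pp, spec)
            except (ValueError, ZeroEventsError) as exc:
                raise AnalysisError(
                    f"fit failed for outcome={outcome!r}, adjustment={label!r}: {exc}"
                ) from exc
            gr = gradient_of_risk(fit)
            logger.info(
                "%s / %s: n=%d events=%d GR=%.3f converged=%s",
                outcome, label, fit.n_participants, fit.n_events, gr.gr, fit.converged,
            )
            rows.append(
                {
                    "outcome": outcome,
                    "adjustment": label,
                    "exposure": config.exposure,
                    "gr": gr.gr,
                    "ci_low": gr.ci_low,
                    "ci_high": gr.ci_high,
                    "p": gr.p,
                    "n": fit.n_participants,
                    "events": fit.n_events,
                    "converged": fit.converged,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# public stages
# ---------------------------------------------------------------------------

_TABLE1_NUMERIC = [
    ("Age (years)", "age_baseline"),
    ("Height (cm)", "height"),
    ("BMI (kg/m2)", "bmi"),
]
_TABLE1_BINARY = [
    ("Prior fracture", "prior_fracture"),
    ("Parental history of hip fracture", "parental_hip_fracture"),
    ("Current smoking", "smoking"),
    ("Corticosteroids", "corticosteroids"),
    ("Rheumatoid arthritis", "rheumatoid_arthritis"),
    ("Excess alcohol intake", "excess_alcohol"),
]
_TABLE1_NUMERIC2 = [
    ("Femoral neck BMD (g/cm2)", "fn_bmd"),
    ("FRAX MOF without BMD", "frax_mof_nobmd"),
    ("FRAX MOF with BMD", "frax_mof_bmd"),
]
_TABLE1_EVENTS = [
    ("Any fracture", "any_fx_event"),
    ("Osteoporotic fracture", "osteoporotic_fx_event"),
    ("MOF", "mof_event"),
    ("Hip fracture", "hip_fx_event"),
    ("Falls", "fall_event"),
    ("Death", "death_event"),
]


def _numeric_row(label, x):
    x = pd.Series(np.asarray(x, dtype=float)).dropna()
    return {
        "variable": label,
        "n": int(len(x)),
        "mean_or_count": float(x.mean()),
        "sd_or_pct": float(x.std(ddof=1)) if len(x) > 1 else 0.0,
        "min": float(x.min()),
        "max": float(x.max()),
    }


def _binary_row(label, x):
    x = pd.Series(np.asarray(x, dtype=float)).dropna()
    count = int(x.sum())
    pct = int(round(100.0 * count / len(x))) if len(x) else 0
    return {
        "variable": label,
        "n": int(len(x)),
        "mean_or_count": count,
        "sd_or_pct": pct,
        "min": np.nan,
        "max": np.nan,
    }


def summarize_baseline(
    baseline: pd.DataFrame, followup: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Cohort characteristics table (the printed-summary layout).

    Numeric rows report n with data / mean / SD / range; binary rows report
    n with data / count / integer percent. With a follow-up table the
    during-follow-up block (follow-up length and event counts) is appended.
    """
    if len(baseline) == 0:
        raise ValueError("empty cohort")
    rows = []
    for label, col in _TABLE1_NUMERIC:
        rows.append(_numeric_row(label, baseline[col]))
    for label, col in _TABLE1_BINARY:
        rows.append(_binary_row(label, baseline[col]))
    for label, col in _TABLE1_NUMERIC2:
        rows.append(_numeric_row(label, baseline[col]))
    rows.append(_binary_row("Prior falls", baseline["prior_falls"]))
    rows.append(_numeric_row("ALM (g)", baseline["alm"]))
    rows.append(_numeric_row("ALM/height2 (g/cm2)", baseline["alm_ht2"]))
    rows.append(
        _numeric_row("ALM/height2 - normalized", standardize(baseline["alm_ht2"]))
    )
    if followup is not None:
        rows.append(_numeric_row("Length of follow-up", followup["followup_end"]))
        for label, col in _TABLE1_EVENTS:
            if col not in followup:
                continue
            x = followup[col]
            if col == "fall_event" and "has_fall_data" in followup:
                x = followup.loc[followup["has_fall_data"] == 1, col]
            rows.append(_binary_row(label, x))
    return pd.DataFrame(rows)


def run_fracture_grid(baseline, followup, config: StudyConfig) -> pd.DataFrame:
    """GR for each fracture outcome x adjustment set (the fracture grid)."""
    outcomes = [o for o in config.outcomes if o in FRACTURE_CAUSES]
    cov = prepare_covariates(baseline, config)
    labels = {o: list(config.adjustments) for o in outcomes}
    return _grid(cov, followup, outcomes, labels, config)


def run_falls_death(baseline, followup, config: StudyConfig) -> pd.DataFrame:
    """GR grids for time-to-first-reported-fall and death.

    Death is modelled directly (no competing-risk duplication); the
    mortality grid appends the post hoc body-composition adjustments.
    """
    cov = prepare_covariates(baseline, config)
    labels = {
        "fall": list(config.adjustments),
        "death": list(config.adjustments) + list(config.mortality_extra),
    }
    outcomes = [o for o in ("fall", "death") if o in labels]
    return _grid(cov, followup, outcomes, labels, config)


def run_age_specific(baseline, followup, config: StudyConfig) -> pd.DataFrame:
    """Age-specific GRs and the exposure x age interaction p per outcome.

    One base-adjusted fit per outcome with an exposure x current_age term;
    GR(age) rows for each configured age, plus one interaction-p row.
    """
    cov = prepare_covariates(baseline, config)
    expz = exposure_column(config)
    rows = []
    for outcome in config.age_specific_outcomes:
        covs = list(base_adjustment(cov)) + [expz]
        pp = _person_periods(cov, followup, outcome, config, covs)
        spec = ModelSpec(
            outcome_cause=outcome,
            exposure=expz,
            adjustment=base_adjustment(cov),
            interactions=("current_age",),
            competing_risk_duplication=config.competing_risk_duplication
            and outcome != "death",
        )
        try:
            fit = fit_model(pp, spec)
        except (ValueError, ZeroEventsError) as exc:
            raise AnalysisError(f"age-interaction fit failed for {outcome!r}: {exc}") from exc
        for age in config.ages:
            gr = gr_at_age(fit, age)
            rows.append(
                {
                    "outcome": outcome,
                    "row": "gr_at_age",
                    "age": age,
                    "gr": gr.gr,
                    "ci_low": gr.ci_low,
                    "ci_high": gr.ci_high,
                    "p": gr.p,
                    "n": fit.n_participants,
                    "events": fit.n_events,
                }
            )
        p_int = interaction_pvalue(fit, f"{expz}:current_age")
        rows.append(
            {
                "outcome": outcome,
                "row": "interaction_p",
                "age": np.nan,
                "gr": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "p": p_int,
                "n": fit.n_participants,
                "events": fit.n_events,
            }
        )
    return pd.DataFrame(rows)


def format_p(p: float) -> str:
    """Printed p-value style: floor at '<.001', cap at '>.30'."""
    if p < 0.001:
        return "p < .001"
    if p > 0.30:
        return "p > .30"
    return f"p = {p:.2g}"


def run_all(config: StudyConfig) -> dict:
    """Generator -> summary -> grids -> age-specific; optionally write CSVs."""
    if config.input_dir is not None:
        baseline, followup, fall_reports = read_cohort(config.input_dir)
    else:
        baseline, followup, fall_reports = generate_cohort(config.generator)
    results = {
        "baseline": baseline,
        "followup": followup,
        "fall_reports": fall_reports,
        "table1": summarize_baseline(baseline, followup),
        "fracture_grid": run_fracture_grid(baseline, followup, config),
        "falls_death": run_falls_death(baseline, followup, config),
        "age_specific": run_age_specific(baseline, followup, config),
    }
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort(baseline, followup, fall_reports, out)
        for name in ("table1", "fracture_grid", "falls_death", "age_specific"):
            results[name].to_csv(out / f"{name}.csv", index=False)
        manifest = {
            "almrisk_version": __version__,
            "seed": config.generator.seed,
            "config": _plain_config(config),
        }
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
    return results


def _plain_config(config: StudyConfig) -> dict:
    raw = asdict(config)

    def conv(x):
        if isinstance(x, dict):
            return {k: conv(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [conv(v) for v in x]
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        return x

    return conv(raw)
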