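import numpy as np
import pytest
from hypothesis import settings

import almrisk as ar
from almrisk.cohort import CauseHazard

settings.register_profile("ci", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("ci")


def null_params(
    n: int,
    seed: int,
    rates: dict,
    log_grs: dict | None = None,
    max_followup: float = 5.0,
    dropout_rate: float = 0.0,
    interactions: dict | None = None,
):
    """GeneratorParams with flat hazards and no covariate effects.

    Used for parameter-recovery harnesses: every structural knob except the
    requested exposure effects is switched off, so the fitted per-SD
    coefficient estimates the configured truth directly.
    """
    log_grs = log_grs or {}
    interactions = interactions or {}
    p = ar.default_params(n=n, seed=seed)
    p.max_followup = max_followup
    p.dropout_rate = dropout_rate
    p.hazard_params = {
        cause: CauseHazard(
            cause,
            baseline_rate=rate,
            exposure_log_gr=log_grs.get(cause, 0.0),
            exposure_age_log_slope=interactions.get(cause, 0.0),
        )
        for cause, rate in rates.items()
    }
    return p


@pytest.fixture(scope="session")
def full_baseline():
    """Default-parameter baseline at the emulated cohort's size."""
    params = ar.default_params(n=11187, seed=42)
    return params, ar.generate_baseline(params)


@pytest.fixture(scope="session")
def small_cohort():
    """A mid-size default cohort shared across read-only tests."""
    params = ar.default_params(n=1200, seed=9)
    baseline, followup, falls = ar.generate_cohort(params)
    return params, baseline, followup, falls
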