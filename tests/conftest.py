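import numpy as np
import pandas as pd
import pytest

from statincea.cohort import CohortSpec, generate_cohort
from statincea.defaults import (
    default_cohort_spec,
    default_econ_params,
    default_survival_params,
    default_treatment_params,
)
from statincea.health_econ import EconParams
from statincea.risk_engine import CauseModel, GompertzHazard, SurvivalParams
from statincea.states import CAUSES


@pytest.fixture(scope="session")
def surv_params():
    return default_survival_params()


@pytest.fixture(scope="session")
def econ_params():
    return default_econ_params()


@pytest.fixture(scope="session")
def treat_params():
    return default_treatment_params()


@pytest.fixture
def profile():
    return pd.Series(
        {
            "age": 55.0,
            "sex": "male",
            "diabetes": False,
            "sbp": 140.0,
            "tc": 6.0,
            "hdl": 1.2,
            "cpd": 10.0,
            "simd": 25.0,
            "famhist": True,
            "on_statin": False,
            "weight": 1.0,
        }
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic synthetic cohort, complete cases only (n=400)."""
    spec = CohortSpec(
        n=400,
        seed=11,
        missingness={"tc": 0.0, "hdl": 0.0, "sbp": 0.0},
        refusal_fraction=0.0,
        under40_fraction=0.0,
        cvd_base=0.0,
        cvd_age_slope=0.0,
    )
    return generate_cohort(spec)


def constant_hazard_params(
    h_chd=0.0, h_cbvd=0.0, h_fatal_cvd=0.0, h_noncvd=0.0, h_post=0.05, max_age=110.0
) -> SurvivalParams:
    """Age- and covariate-independent hazards (closed-form oracle territory)."""
    rates = {
        "nonfatal_chd": h_chd,
        "nonfatal_cbvd": h_cbvd,
        "fatal_cvd": h_fatal_cvd,
        "fatal_noncvd": h_noncvd,
    }
    return SurvivalParams(
        causes={c: CauseModel(GompertzHazard(rates[c], 0.0)) for c in CAUSES},
        post_event_mortality={
            "chd": GompertzHazard(h_post, 0.0),
            "cbvd": GompertzHazard(h_post, 0.0),
        },
        max_age=max_age,
    )


def flat_econ(utility=1.0, rate=0.0) -> EconParams:
    """Uniform utility, configurable discounting, zero costs."""
    return EconParams(
        discount_rate=rate,
        background_utility_bands=((0.0, utility, utility),),
        chronic_decrement={"chd": 0.0, "cbvd": 0.0},
        secondary_event_decrement={"chd": 0.0, "cbvd": 0.0},
        screening_cost=0.0,
        monitoring_cost=0.0,
        diabetes_cost=0.0,
        background_cost=0.0,
        background_cost_age_slope=0.0,
        event_cost_coefficients={
            "pre": {"intercept": 0.0, "age": 0.0, "simd": 0.0, "famhist": 0.0},
            "post": {"intercept": 0.0, "age": 0.0, "simd": 0.0, "famhist": 0.0},
        },
    )
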