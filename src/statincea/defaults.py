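"""Default model parameters.

The survival, utility and cost defaults below are SYNTHETIC: they are
UK-plausible magnitudes chosen to give the model a realistic scale
(adult all-cause mortality broadly Gompertz in age, CVD incidence
rising steeply with age, higher hazards with diabetes, smoking, blood
pressure, deprivation and adverse lipids), not fitted estimates from
any cohort.  Real fitted parameters can be supplied through the same
configuration surface (see :mod:`statincea.config`).

Treatment-effect defaults are the trial-derived moderate-intensity
statin measures: a 26% proportional reduction in non-HDL-C with
relative risks 0.77 / 0.87 / 0.90 per 1.0 mmol/L for nonfatal CHD,
nonfatal cerebrovascular disease and fatal CVD, +0.5% absolute diabetes
risk, 0.002 QALY/year pill disutility and a £13.44/year drug tariff.
"""

from __future__ import annotations

import numpy as np

from .cohort import CohortSpec
from .health_econ import EconParams
from .psa import MeasureDist
from .risk_engine import CauseModel, GompertzHazard, SurvivalParams
from .treatment import TreatmentParams

__all__ = [
    "default_survival_params",
    "default_econ_params",
    "default_treatment_params",
    "default_cohort_spec",
    "default_psa_distributions",
    "default_tornado_bounds",
]

_REFERENCE = {"sbp": 130.0, "tc": 5.5, "hdl": 1.4, "simd": 20.0}


def default_survival_params() -> SurvivalParams:
    """Synthetic Gompertz proportional-hazards model over ASSIGN covariates."""
    causes = {
        "nonfatal_chd": CauseModel(
            baseline=GompertzHazard(0.0040, 0.075, 60.0),
            coefficients={
                "male": 0.45, "diabetes": 0.60, "sbp": 0.012, "tc": 0.18,
                "hdl": -0.45, "cpd": 0.022, "simd": 0.008, "famhist": 0.25,
            },
            reference=dict(_REFERENCE),
        ),
        "nonfatal_cbvd": CauseModel(
            baseline=GompertzHazard(0.0020, 0.085, 60.0),
            coefficients={
                "male": 0.25, "diabetes": 0.50, "sbp": 0.016, "tc": 0.08,
                "hdl": -0.25, "cpd": 0.018, "simd": 0.008, "famhist": 0.15,
            },
            reference=dict(_REFERENCE),
        ),
        "fatal_cvd": CauseModel(
            baseline=GompertzHazard(0.0015, 0.100, 60.0),
            coefficients={
                "male": 0.50, "diabetes": 0.65, "sbp": 0.014, "tc": 0.15,
                "hdl": -0.40, "cpd": 0.025, "simd": 0.010, "famhist": 0.20,
            },
            reference=dict(_REFERENCE),
        ),
        "fatal_noncvd": CauseModel(
            baseline=GompertzHazard(0.0060, 0.092, 60.0),
            coefficients={
                "male": 0.25, "diabetes": 0.30, "hdl": -0.10, "cpd": 0.020,
                "simd": 0.012,
            },
            reference=dict(_REFERENCE),
        ),
    }
    post = {
        "chd": GompertzHazard(0.060, 0.070, 60.0),
        "cbvd": GompertzHazard(0.080, 0.070, 60.0),
    }
    # PSA samples the lipid log-hazard-ratios of the three CVD causes,
    # with equicorrelated uncertainty (shared trial evidence base)
    hr_parameters = tuple(
        (c, v) for c in ("nonfatal_chd", "nonfatal_cbvd", "fatal_cvd") for v in ("tc", "hdl")
    )
    sd = np.array([0.02, 0.05] * 3)
    corr = np.full((6, 6), 0.4)
    np.fill_diagonal(corr, 1.0)
    cov = corr * np.outer(sd, sd)
    return SurvivalParams(
        causes=causes,
        post_event_mortality=post,
        max_age=110.0,
        hr_parameters=hr_parameters,
        hr_covariance=cov,
    )


def default_econ_params() -> EconParams:
    return EconParams()


def default_treatment_params(adherence_scenario: bool = False) -> TreatmentParams:
    """Base-case statin measures; full adherence unless the scenario is on."""
    return TreatmentParams(
        persistence=(0.67, 0.53, 0.50) if adherence_scenario else (),
        bounds=default_tornado_bounds(),
    )


def default_cohort_spec(n: int = 10_000, seed: int = 0) -> CohortSpec:
    return CohortSpec(n=n, seed=seed)


def default_psa_distributions() -> list[MeasureDist]:
    """Sampling distributions for the probabilistic analysis.

    Beta for proportions/utilities, gamma for costs, lognormal for
    relative risks; screening cost and the discount rate are fixed by
    convention.
    """
    return [
        MeasureDist("nonhdl_reduction", 0.26, 0.02, "beta"),
        MeasureDist("rr_nonfatal_chd", 0.77, 0.02, "lognormal"),
        MeasureDist("rr_nonfatal_cbvd", 0.87, 0.02, "lognormal"),
        MeasureDist("rr_fatal_cvd", 0.90, 0.02, "lognormal"),
        MeasureDist("pill_disutility", 0.002, 0.0005, "beta"),
        MeasureDist("diabetes_abs_risk_increase", 0.005, 0.001, "beta"),
        MeasureDist("annual_drug_cost", 13.44, 1.5, "gamma"),
        MeasureDist("monitoring_cost", 30.0, 5.0, "gamma"),
    ]


def default_tornado_bounds() -> dict[str, tuple[float, float]]:
    """Low/high one-way sensitivity bounds per measure."""
    return {
        "nonhdl_reduction": (0.20, 0.32),
        "rr_nonfatal_chd": (0.72, 0.82),
        "rr_nonfatal_cbvd": (0.82, 0.92),
        "rr_fatal_cvd": (0.85, 0.95),
        "pill_disutility": (0.0, 0.008),
        "diabetes_abs_risk_increase": (0.002, 0.010),
        "annual_drug_cost": (10.0, 40.0),
        "monitoring_cost": (10.0, 60.0),
        "discount_rate": (0.015, 0.060),
    }
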