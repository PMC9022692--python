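"""Competing-risk multistate lifetime simulation and 10-year CVD risk scoring.

The engine is an expectation-based (cohort) state-transition model with
annual cycles.  From the CVD-free state an individual faces four
competing cause-specific hazards — nonfatal CHD, nonfatal
cerebrovascular disease (CBVD), fatal CVD and fatal non-CVD — each a
Gompertz baseline in age scaled by a proportional-hazards linear
predictor over ASSIGN-style risk factors.  Survivors of a nonfatal
event occupy a chronic state subject to elevated all-cause mortality.

Within-cycle competing events are resolved exactly for constant
hazards: ``P(event c) = (h_c / Σh) · (1 − exp(−Σh))``.  All outputs are
probability-weighted expectations over the state distribution, not
Monte-Carlo draws, so results are deterministic given parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import health_econ as he
from .health_econ import EconParams
from .states import CAUSES, CVD_CAUSES, HealthState
from .treatment import TreatmentParams, apply_statin_modifiers

__all__ = [
    "GompertzHazard",
    "CauseModel",
    "SurvivalParams",
    "LifetimeOutcome",
    "CohortOutcome",
    "linear_predictor",
    "ten_year_risk",
    "ten_year_cause_risks",
    "annual_transition_probs",
    "simulate_lifetime",
    "simulate_cohort",
]

COST_CATEGORIES = ("cvd", "noncvd", "statin", "monitoring", "screening", "diabetes")


@dataclass
class GompertzHazard:
    """Gompertz hazard ``rate_at_ref · exp(gamma · (age − ref_age))``."""

    rate_at_ref: float
    gamma: float
    ref_age: float = 60.0

    def at(self, age):
        return self.rate_at_ref * np.exp(self.gamma * (np.asarray(age, float) - self.ref_age))


@dataclass
class CauseModel:
    """Cause-specific hazard: Gompertz baseline × exp(linear predictor).

    ``coefficients`` maps covariate names to log-hazard-ratios per unit;
    ``reference`` gives the covariate values at which the baseline
    applies.  The covariate ``male`` is derived from the ``sex`` field.
    """

    baseline: GompertzHazard
    coefficients: dict[str, float] = field(default_factory=dict)
    reference: dict[str, float] = field(default_factory=dict)


@dataclass
class SurvivalParams:
    """Cause-specific survival model parameters plus PSA covariance.

    ``hr_parameters`` names the (cause, covariate) log-hazard-ratios the
    probabilistic analysis samples jointly; ``hr_covariance`` is their
    covariance matrix (symmetric PSD).
    """

    causes: dict[str, CauseModel]
    post_event_mortality: dict[str, GompertzHazard]
    max_age: float = 110.0
    hr_parameters: tuple[tuple[str, str], ...] = ()
    hr_covariance: np.ndarray | None = None

    def __post_init__(self) -> None:
        missing = set(CAUSES) - set(self.causes)
        if missing:
            raise ValueError(f"missing cause models: {sorted(missing)}")
        if self.hr_covariance is not None:
            cov = np.asarray(self.hr_covariance, dtype=float)
            if cov.shape != (len(self.hr_parameters),) * 2:
                raise ValueError("hr_covariance shape must match hr_parameters")
            if not np.allclose(cov, cov.T):
                raise ValueError("hr_covariance must be symmetric")
            self.hr_covariance = cov

    def mean_log_hrs(self) -> np.ndarray:
        return np.array(
            [self.causes[c].coefficients[name] for c, name in self.hr_parameters]
        )

    def with_log_hrs(self, values: np.ndarray) -> "SurvivalParams":
        """Copy of the parameters with the PSA-sampled log-HRs substituted."""
        import copy

        out = copy.deepcopy(self)
        for (cause, name), v in zip(self.hr_parameters, values):
            out.causes[cause].coefficients[name] = float(v)
        return out


def _covariate_value(profiles: pd.DataFrame, name: str) -> np.ndarray:
    if name == "male":
        sex = profiles["sex"]
        return (sex == "male").to_numpy(dtype=float)
    if name not in profiles.columns:
        raise KeyError(f"profile is missing covariate {name!r}")
    vals = profiles[name].to_numpy(dtype=float)
    if np.any(np.isnan(vals)):
        raise ValueError(f"covariate {name!r} has missing values")
    return vals


def _as_frame(profile) -> pd.DataFrame:
    if isinstance(profile, pd.DataFrame):
        return profile
    if isinstance(profile, pd.Series):
        return profile.to_frame().T
    return pd.DataFrame([profile])


def linear_predictor(profile, cause: str, params: SurvivalParams):
    """Additive log-hazard offset for a profile, relative to the reference.

    Age does not enter: it is carried by the Gompertz baseline.
    """
    profiles = _as_frame(profile)
    model = params.causes[cause]
    lp = np.zeros(len(profiles))
    for name, coef in model.coefficients.items():
        ref = model.reference.get(name, 0.0)
        lp += coef * (_covariate_value(profiles, name) - ref)
    return float(lp[0]) if isinstance(profile, (pd.Series, dict)) else lp


def _exp_linear_predictors(
    profiles: pd.DataFrame, params: SurvivalParams
) -> dict[str, np.ndarray]:
    """Precompute exp(linear predictor) per cause (age-independent)."""
    out = {}
    for cause in CAUSES:
        model = params.causes[cause]
        lp = np.zeros(len(profiles))
        for name, coef in model.coefficients.items():
            ref = model.reference.get(name, 0.0)
            lp += coef * (_covariate_value(profiles, name) - ref)
        out[cause] = np.exp(lp)
    return out


def _cause_hazards(
    profiles: pd.DataFrame,
    age: np.ndarray,
    params: SurvivalParams,
    exp_lp: dict[str, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    if exp_lp is None:
        exp_lp = _exp_linear_predictors(profiles, params)
    return {c: params.causes[c].baseline.at(age) * exp_lp[c] for c in CAUSES}


def _competing_exit_probs(hazards: Mapping[str, np.ndarray]):
    """Exact constant-hazard decomposition of within-cycle competing events."""
    total = sum(hazards.values())
    p_exit = -np.expm1(-total)
    safe = np.where(total > 0, total, 1.0)
    probs = {c: np.where(total > 0, h / safe * p_exit, 0.0) for c, h in hazards.items()}
    return probs, p_exit


def annual_transition_probs(
    profile, current_age: float, state: HealthState, params: SurvivalParams
) -> dict[HealthState, float]:
    """One-cycle transition probabilities from a non-absorbing state.

    Beyond ``max_age`` the transition to death is forced.  Probabilities
    (including the stay probability) sum to 1.
    """
    if state.is_absorbing():
        raise ValueError(f"state {state.name} is absorbing")
    if current_age > params.max_age:
        dest = (
            HealthState.DEAD_NONCVD
            if state is HealthState.CVD_FREE
            else HealthState.DEAD_POST_EVENT
        )
        return {dest: 1.0}
    profiles = _as_frame(profile)
    if state is HealthState.CVD_FREE:
        hazards = _cause_hazards(profiles, np.asarray([current_age], float), params)
        probs, p_exit = _competing_exit_probs(hazards)
        return {
            HealthState.CVD_FREE: float(1.0 - p_exit[0]),
            HealthState.CHRONIC_CHD: float(probs["nonfatal_chd"][0]),
            HealthState.CHRONIC_CBVD: float(probs["nonfatal_cbvd"][0]),
            HealthState.DEAD_CVD: float(probs["fatal_cvd"][0]),
            HealthState.DEAD_NONCVD: float(probs["fatal_noncvd"][0]),
        }
    key = "chd" if state is HealthState.CHRONIC_CHD else "cbvd"
    h = float(params.post_event_mortality[key].at(current_age))
    p_die = -np.expm1(-h)
    return {state: 1.0 - p_die, HealthState.DEAD_POST_EVENT: p_die}


def ten_year_cause_risks(
    profiles, params: SurvivalParams, horizon: int = 10
) -> dict[str, np.ndarray]:
    """Cumulative incidence of each first-event type over ``horizon`` years.

    Computed untreated, from the CVD-free state, under competing risks.
    """
    df = _as_frame(profiles)
    age0 = df["age"].to_numpy(dtype=float)
    alive = np.ones(len(df))
    cif = {c: np.zeros(len(df)) for c in CAUSES}
    exp_lp = _exp_linear_predictors(df, params)
    for t in range(horizon):
        age = age0 + t
        hazards = _cause_hazards(df, age, params, exp_lp)
        probs, p_exit = _competing_exit_probs(hazards)
        for c in CAUSES:
            cif[c] += alive * probs[c]
        alive = alive * (1.0 - p_exit)
    return cif


def ten_year_risk(profiles, params: SurvivalParams, horizon: int = 10):
    """10-year cumulative incidence of the composite CVD endpoint.

    The composite counts nonfatal CHD, nonfatal CBVD and fatal CVD as
    first events, under the competing risk of non-CVD death.
    """
    cif = ten_year_cause_risks(profiles, params, horizon)
    out = sum(cif[c] for c in CVD_CAUSES)
    scalar = isinstance(profiles, (pd.Series, dict))
    return float(out[0]) if scalar else out


@dataclass
class LifetimeOutcome:
    """Expected lifetime outcomes for one risk profile under one scenario."""

    qalys: float
    life_years: float
    costs: dict[str, float]
    event_probs: dict[str, float]
    trajectory: pd.DataFrame | None = None

    @property
    def total_cost(self) -> float:
        return sum(self.costs.values())


@dataclass
class CohortOutcome:
    """Per-profile expected outcomes for a cohort (vectorized engine output)."""

    qalys: np.ndarray
    life_years: np.ndarray
    costs: dict[str, np.ndarray]
    event_probs: dict[str, np.ndarray]

    @property
    def total_cost(self) -> np.ndarray:
        return sum(self.costs.values())


def simulate_cohort(
    profiles: pd.DataFrame,
    params: SurvivalParams,
    econ: EconParams,
    treatment: TreatmentParams | None = None,
    scenario: str = "untreated",
    treat_years: int | None = None,
    half_cycle: bool = True,
    record_trajectory: bool = False,
    _trajectory_out: list | None = None,
) -> CohortOutcome:
    """Expectation-based lifetime simulation of every profile in a cohort.

    ``scenario`` is ``"untreated"`` or ``"treated"``; under treatment the
    statin hazard multipliers, pill disutility and drug/monitoring costs
    apply while the individual is CVD-free and still on therapy
    (``treat_years`` cycles from entry; ``None`` = lifelong).  QALYs and
    recurring costs use a half-cycle correction by default; one-off
    entry and event-year costs do not.

    Chronic-state hospitalization costs are linear in age at the primary
    event, so the engine tracks the occupancy-weighted age-at-event sum
    per chronic state, which makes the expected cost exact.
    """
    df = profiles.reset_index(drop=True)
    n = len(df)
    treated = scenario == "treated"
    if treated and treatment is None:
        raise ValueError("treated scenario requires TreatmentParams")

    age0 = df["age"].to_numpy(dtype=float)
    is_male = (df["sex"] == "male").to_numpy()
    simd = df["simd"].to_numpy(dtype=float)
    famhist = df["famhist"].to_numpy(dtype=float)

    if treated:
        nonhdl = (df["tc"] - df["hdl"]).to_numpy(dtype=float)
        mods = apply_statin_modifiers(nonhdl, treatment)
        hmult = {c: np.asarray(mods.hazard_multipliers[c]) for c in CVD_CAUSES}
    else:
        hmult = {}

    infl = 1.0 + econ.inflation_factor
    r = econ.discount_rate
    n_cycles = int(np.ceil(params.max_age - age0.min())) + 1

    # state occupancy masses
    free = np.ones(n)
    chronic = {"chd": np.zeros(n), "cbvd": np.zeros(n)}
    age_sum = {"chd": np.zeros(n), "cbvd": np.zeros(n)}  # mass-weighted age at event
    dead = {k: np.zeros(n) for k in ("cvd", "noncvd", "post")}

    qalys = np.zeros(n)
    life_years = np.zeros(n)
    costs = {k: np.zeros(n) for k in COST_CATEGORIES}
    cif = {c: np.zeros(n) for c in CAUSES}

    # one-off screening (risk assessment) cost at entry, 2014-based
    costs["screening"] += econ.screening_cost * infl

    pre_c = econ.event_cost_coefficients["pre"]
    post_c = econ.event_cost_coefficients["post"]
    traj_rows = []
    exp_lp = _exp_linear_predictors(df, params)

    for t in range(n_cycles):
        age = age0 + t
        disc = (1.0 + r) ** -t
        on_therapy = treated and (treat_years is None or t < treat_years)

        # absorb anyone at or beyond max_age before the cycle accrues
        beyond = age >= params.max_age
        if beyond.any():
            dead["noncvd"] += np.where(beyond, free, 0.0)
            free = np.where(beyond, 0.0, free)
            for k in ("chd", "cbvd"):
                dead["post"] += np.where(beyond, chronic[k], 0.0)
                chronic[k] = np.where(beyond, 0.0, chronic[k])
                age_sum[k] = np.where(beyond, 0.0, age_sum[k])

        hazards = _cause_hazards(df, age, params, exp_lp)
        if on_therapy:
            hazards = {
                c: h * hmult[c] if c in hmult else h for c, h in hazards.items()
            }
        probs, p_exit = _competing_exit_probs(hazards)

        p_die_chronic = {}
        for k in ("chd", "cbvd"):
            h_post = params.post_event_mortality[k].at(age)
            p_die_chronic[k] = -np.expm1(-h_post)

        free_start = free
        chronic_start = {k: chronic[k].copy() for k in chronic}
        inflow = {
            "chd": free_start * probs["nonfatal_chd"],
            "cbvd": free_start * probs["nonfatal_cbvd"],
        }

        free = free_start * (1.0 - p_exit)
        for k in ("chd", "cbvd"):
            surv_frac = 1.0 - p_die_chronic[k]
            dead["post"] += chronic_start[k] * p_die_chronic[k]
            chronic[k] = chronic_start[k] * surv_frac + inflow[k]
            age_sum[k] = age_sum[k] * surv_frac + inflow[k] * age
        dead["cvd"] += free_start * probs["fatal_cvd"]
        dead["noncvd"] += free_start * probs["fatal_noncvd"]

        cif["nonfatal_chd"] += inflow["chd"]
        cif["nonfatal_cbvd"] += inflow["cbvd"]
        cif["fatal_cvd"] += free_start * probs["fatal_cvd"]
        cif["fatal_noncvd"] += free_start * probs["fatal_noncvd"]

        # accrual occupancy (half-cycle corrected for recurring flows)
        if half_cycle:
            acc_free = 0.5 * (free_start + free)
            acc_chronic = {k: 0.5 * (chronic_start[k] + chronic[k]) for k in chronic}
        else:
            acc_free = free_start
            acc_chronic = chronic_start
        alive_acc = acc_free + acc_chronic["chd"] + acc_chronic["cbvd"]

        life_years += alive_acc

        # utilities
        u_free = he.background_utility(age, is_male, econ)
        if on_therapy:
            u_free = u_free - treatment.pill_disutility
        u_free = np.clip(u_free, 0.0, 1.0)
        util = acc_free * u_free
        for k, st in (("chd", "chd"), ("cbvd", "cbvd")):
            u_c = np.clip(
                he.background_utility(age, is_male, econ)
                - econ.chronic_decrement[st]
                - econ.secondary_event_decrement[st],
                0.0,
                1.0,
            )
            util += acc_chronic[k] * u_c
        qalys += disc * util

        # costs (2014-based model costs are inflated to 2020 GBP)
        bg = econ.background_cost + econ.background_cost_age_slope * (age - 40.0)
        costs["noncvd"] += disc * alive_acc * np.maximum(bg, 0.0) * infl

        ev_inflow = inflow["chd"] + inflow["cbvd"]
        pre_cost = (
            pre_c["intercept"] * ev_inflow
            + pre_c["age"] * ev_inflow * age
            + pre_c["simd"] * ev_inflow * simd
            + pre_c["famhist"] * ev_inflow * famhist
        )
        post_cost = np.zeros(n)
        for k in ("chd", "cbvd"):
            mass = acc_chronic[k]
            # age-at-event weighted sum scaled to accrual mass
            with np.errstate(invalid="ignore", divide="ignore"):
                mean_age_ev = np.where(chronic[k] > 0, age_sum[k] / np.where(chronic[k] > 0, chronic[k], 1.0), 0.0)
            post_cost += (
                post_c["intercept"] * mass
                + post_c["age"] * mass * mean_age_ev
                + post_c["simd"] * mass * simd
                + post_c["famhist"] * mass * famhist
            )
        costs["cvd"] += disc * np.maximum(pre_cost, 0.0) * infl
        costs["cvd"] += disc * np.maximum(post_cost, 0.0) * infl

        if on_therapy:
            # drug tariff is already 2020-priced; monitoring is 2014-based
            costs["statin"] += disc * acc_free * treatment.annual_drug_cost
            costs["monitoring"] += disc * acc_free * econ.monitoring_cost * infl
        if treated and treat_years != 0:
            costs["diabetes"] += (
                disc
                * alive_acc
                * treatment.diabetes_abs_risk_increase
                * econ.diabetes_cost
                * infl
            )

        if record_trajectory:
            traj_rows.append(
                {
                    "cycle": t,
                    "age": float(age[0]),
                    "CVD_FREE": float(free[0]),
                    "CHRONIC_CHD": float(chronic["chd"][0]),
                    "CHRONIC_CBVD": float(chronic["cbvd"][0]),
                    "DEAD_CVD": float(dead["cvd"][0]),
                    "DEAD_NONCVD": float(dead["noncvd"][0]),
                    "DEAD_POST_EVENT": float(dead["post"][0]),
                }
            )

        if free.max() + chronic["chd"].max() + chronic["cbvd"].max() < 1e-14:
            break

    out = CohortOutcome(qalys=qalys, life_years=life_years, costs=costs, event_probs=cif)
    if record_trajectory and _trajectory_out is not None:
        _trajectory_out.append(pd.DataFrame(traj_rows))
    return out


def simulate_lifetime(
    profile,
    params: SurvivalParams,
    econ: EconParams,
    treatment: TreatmentParams | None = None,
    scenario: str = "untreated",
    treat_years: int | None = None,
    half_cycle: bool = True,
    record_trajectory: bool = False,
) -> LifetimeOutcome:
    """Expected lifetime outcomes for a single risk profile.

    Thin wrapper over :func:`simulate_cohort`; optionally records the
    full state-occupancy trajectory (cycle × state CSV-ready table).
    """
    df = _as_frame(profile)
    holder: list = []
    res = simulate_cohort(
        df,
        params,
        econ,
        treatment,
        scenario,
        treat_years,
        half_cycle,
        record_trajectory=record_trajectory,
        _trajectory_out=holder,
    )
    return LifetimeOutcome(
        qalys=float(res.qalys[0]),
        life_years=float(res.life_years[0]),
        costs={k: float(v[0]) for k, v in res.costs.items()},
        event_probs={k: float(v[0]) for k, v in res.event_probs.items()},
        trajectory=holder[0] if holder else None,
    )
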