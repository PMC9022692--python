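"""Policy evaluation: scoring, strategy construction and cohort-level outcomes.

Glues the building blocks together: per-profile 10-year risk and ARR
scores, the six statin policies (fixed risk 20/10, count-matched
age-stratified 20/10 and ARR 20/10) plus a no-treatment reference,
expectation-based lifetime outcomes under each policy, and the
probabilistic analysis looping parameter draws through the same
machinery.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .health_econ import EconParams
from .psa import MeasureDist, sample_parameters
from .risk_engine import CohortOutcome, SurvivalParams, simulate_cohort, ten_year_cause_risks
from .states import CVD_CAUSES
from .strategies import StrategyDef, calibrate_to_count, eligible
from .treatment import (
    ArrInputs,
    TreatmentParams,
    arr_10yr,
    combined_hr_per_mmol,
    discontinuation_mixture,
)

__all__ = [
    "profile_scores",
    "build_strategies",
    "component_outcomes",
    "strategy_outcomes",
    "run_psa",
    "apply_measure_overrides",
]

ECON_MEASURES = ("monitoring_cost", "screening_cost", "diabetes_cost", "discount_rate")


def profile_scores(
    cohort: pd.DataFrame, surv: SurvivalParams, treatment: TreatmentParams
) -> pd.DataFrame:
    """Per-profile 10-year risk, untreated survival, combined HR and ARR.

    The ARR uses the modified single-HR equation on the non-HDL-C axis:
    the per-mmol hazard ratio is the cause-risk-share-weighted geometric
    mean of the three statin relative risks, and the proportional
    reduction is the trial non-HDL-C reduction.
    """
    cif = ten_year_cause_risks(cohort, surv)
    risk = sum(cif[c] for c in CVD_CAUSES)
    s_un = 1.0 - risk
    shares = {c: cif[c] for c in CVD_CAUSES}
    hr = combined_hr_per_mmol(treatment.relative_risks, shares)
    nonhdl = (cohort["tc"] - cohort["hdl"]).to_numpy(float)
    arr = arr_10yr(
        ArrInputs(
            s_un=s_un,
            hr_per_mmol=hr,
            lipid_baseline=nonhdl,
            reduction_pct=treatment.nonhdl_reduction,
        )
    )
    return pd.DataFrame(
        {"risk10": risk, "s_un": s_un, "hr_per_mmol": hr, "nonhdl": nonhdl, "arr": arr}
    )


def build_strategies(
    cohort: pd.DataFrame,
    scores: pd.DataFrame,
    risk_thresholds: Sequence[float] = (0.20, 0.10),
) -> dict[str, StrategyDef]:
    """The policy set: no treatment, fixed-risk thresholds, and count-matched
    age-stratified and ARR strategies for each reference threshold."""
    out: dict[str, StrategyDef] = {"none": StrategyDef("none", label="none")}
    weights = cohort["weight"].to_numpy(float)
    risk = scores["risk10"].to_numpy()
    arr = scores["arr"].to_numpy()
    for thr in risk_thresholds:
        pct = int(round(100 * thr))
        ref = StrategyDef("fixed_risk", thr, label=f"assign_{pct}")
        out[ref.label] = ref
        target = float(weights[eligible(ref, cohort, risk=risk)].sum())
        out[f"age_{pct}"] = calibrate_to_count(
            "age_stratified", cohort, target, risk=risk, label=f"age_{pct}"
        )
        out[f"arr_{pct}"] = calibrate_to_count(
            "arr", cohort, target, arr=arr, label=f"arr_{pct}"
        )
    return out


def component_outcomes(
    cohort: pd.DataFrame,
    surv: SurvivalParams,
    econ: EconParams,
    treatment: TreatmentParams,
) -> dict[str, CohortOutcome | dict]:
    """Untreated and (mixture-averaged) treated outcomes per profile.

    Under an adherence schedule the treated outcome is a mixture over
    discontinuation times: initiators who never persist contribute the
    untreated outcome plus first-year drug and monitoring costs only.
    """
    untreated = simulate_cohort(cohort, surv, econ, scenario="untreated")
    mixture = discontinuation_mixture(treatment)
    n = len(cohort)
    q = np.zeros(n)
    costs = {k: np.zeros(n) for k in untreated.costs}
    events = {k: np.zeros(n) for k in untreated.event_probs}
    ly = np.zeros(n)
    infl = 1.0 + econ.inflation_factor
    for w, k in mixture:
        if k == 0:
            comp_q = untreated.qalys
            comp_ly = untreated.life_years
            comp_costs = {c: untreated.costs[c].copy() for c in untreated.costs}
            # first-year pickup: drug (2020 tariff) and monitoring (2014-based)
            comp_costs["statin"] = comp_costs["statin"] + treatment.annual_drug_cost
            comp_costs["monitoring"] = comp_costs["monitoring"] + econ.monitoring_cost * infl
            comp_events = untreated.event_probs
        else:
            comp = simulate_cohort(
                cohort, surv, econ, treatment, scenario="treated", treat_years=k
            )
            comp_q, comp_ly, comp_costs, comp_events = (
                comp.qalys, comp.life_years, comp.costs, comp.event_probs,
            )
        q += w * comp_q
        ly += w * comp_ly
        for c in costs:
            costs[c] += w * comp_costs[c]
        for c in events:
            events[c] += w * comp_events[c]
    treated = CohortOutcome(qalys=q, life_years=ly, costs=costs, event_probs=events)
    return {"untreated": untreated, "treated": treated}


def strategy_outcomes(
    cohort: pd.DataFrame,
    strategy_set: Mapping[str, StrategyDef],
    scores: pd.DataFrame,
    components: Mapping[str, CohortOutcome],
    eligibility: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Weighted mean per-person cost/QALY (and disaggregation) per strategy.

    Eligible profiles take the treated expectation, the rest the
    untreated one; means are over survey weights.  Precomputed
    eligibility masks may be supplied (scenario analyses).
    """
    weights = cohort["weight"].to_numpy(float)
    total_w = weights.sum()
    un, tr = components["untreated"], components["treated"]
    risk = scores["risk10"].to_numpy()
    arr = scores["arr"].to_numpy()
    rows = []
    for label, sdef in strategy_set.items():
        elig = (
            np.asarray(eligibility[label], bool)
            if eligibility is not None
            else eligible(sdef, cohort, risk=risk, arr=arr)
        )
        qaly = np.where(elig, tr.qalys, un.qalys)
        ly = np.where(elig, tr.life_years, un.life_years)
        row = {
            "strategy": label,
            "eligible_weight": float(weights[elig].sum()),
            "pct_eligible": 100.0 * float(weights[elig].sum()) / total_w,
            "qaly": float(weights @ qaly / total_w),
            "life_years": float(weights @ ly / total_w),
        }
        total_cost = np.zeros(len(cohort))
        for cat in un.costs:
            c = np.where(elig, tr.costs[cat], un.costs[cat])
            row[f"cost_{cat}"] = float(weights @ c / total_w)
            total_cost += c
        row["cost"] = float(weights @ total_cost / total_w)
        cvd_events = sum(
            np.where(elig, tr.event_probs[c], un.event_probs[c]) for c in CVD_CAUSES
        )
        row["cvd_events"] = float(weights @ cvd_events / total_w)
        rows.append(row)
    return pd.DataFrame(rows)


def apply_measure_overrides(
    treatment: TreatmentParams, econ: EconParams, measures: Mapping[str, float]
) -> tuple[TreatmentParams, EconParams]:
    """Return copies of the parameter sets with sampled measures substituted."""
    t_over = {k: v for k, v in measures.items() if hasattr(treatment, k) and k not in ECON_MEASURES}
    e_over = {k: v for k, v in measures.items() if k in ECON_MEASURES}
    unknown = set(measures) - set(t_over) - set(e_over)
    if unknown:
        raise KeyError(f"unknown measures: {sorted(unknown)}")
    return replace(treatment, **t_over), replace(econ, **e_over)


def run_psa(
    cohort: pd.DataFrame,
    strategy_set: Mapping[str, StrategyDef],
    scores: pd.DataFrame,
    surv: SurvivalParams,
    econ: EconParams,
    treatment: TreatmentParams,
    distributions: Sequence[MeasureDist],
    n_iter: int,
    master_seed: int,
) -> pd.DataFrame:
    """Probabilistic analysis: per-iteration strategy costs and QALYs.

    Each iteration redraws the treatment/economic measures and the
    correlated lipid log-hazard-ratios, then reruns the lifetime
    simulation.  Strategy thresholds (and hence eligibility) stay fixed
    at their base-case calibration; the scores feeding eligibility are
    base-case scores.
    """
    risk = scores["risk10"].to_numpy()
    arr = scores["arr"].to_numpy()
    eligibility = {
        label: eligible(sdef, cohort, risk=risk, arr=arr)
        for label, sdef in strategy_set.items()
    }
    samples = sample_parameters(
        distributions,
        n_iter,
        master_seed,
        mean_log_hrs=surv.mean_log_hrs() if surv.hr_parameters else None,
        hr_covariance=surv.hr_covariance,
    )
    rows = []
    for s in samples:
        treat_i, econ_i = apply_measure_overrides(treatment, econ, s.measures)
        surv_i = surv.with_log_hrs(s.log_hrs) if s.log_hrs is not None else surv
        comps = component_outcomes(cohort, surv_i, econ_i, treat_i)
        res = strategy_outcomes(cohort, strategy_set, scores, comps, eligibility)
        for _, r in res.iterrows():
            rows.append(
                {
                    "iteration": s.index,
                    "strategy": r["strategy"],
                    "cost": r["cost"],
                    "qaly": r["qaly"],
                }
            )
    return pd.DataFrame(rows)
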