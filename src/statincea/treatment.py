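"""Statin treatment effects and absolute-risk-reduction (ARR) mathematics.

Moderate-intensity statin therapy is modelled through its effect on
non-HDL cholesterol: a proportional reduction of the baseline non-HDL-C
level, combined with per-1.0 mmol/L relative risks for nonfatal CHD,
nonfatal cerebrovascular disease and fatal CVD.  The same lipid axis
drives the ARR prioritization score: a patient's expected 10-year
absolute risk reduction is computed from their untreated 10-year
survival, their baseline lipid level and the hazard ratio per unit
lipid reduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "TreatmentParams",
    "ArrInputs",
    "StatinModifiers",
    "rrr_from_lipid_reduction",
    "lipid_reduction",
    "arr_10yr",
    "combined_hr_per_mmol",
    "apply_statin_modifiers",
    "persistence_fraction",
    "discontinuation_mixture",
]

#: model causes whose hazards statins modify
STATIN_CAUSES = ("nonfatal_chd", "nonfatal_cbvd", "fatal_cvd")


@dataclass
class TreatmentParams:
    """Moderate-intensity statin measures (base case and sensitivity bounds).

    Effect sizes are expressed per 1.0 mmol/L reduction in non-HDL-C.
    ``persistence`` is empty in the base case (full adherence); when set,
    entry ``k`` is the fraction of initiators still on therapy during
    year ``k+1``, with the last entry applying to all later years.
    """

    nonhdl_reduction: float = 0.26
    rr_nonfatal_chd: float = 0.77
    rr_nonfatal_cbvd: float = 0.87
    rr_fatal_cvd: float = 0.90
    diabetes_abs_risk_increase: float = 0.005
    pill_disutility: float = 0.002
    annual_drug_cost: float = 13.44
    persistence: tuple[float, ...] = ()
    #: lo/hi sensitivity-analysis bounds per measure name
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.nonhdl_reduction < 1.0):
            raise ValueError("nonhdl_reduction must lie in [0, 1)")
        for name in ("rr_nonfatal_chd", "rr_nonfatal_cbvd", "rr_fatal_cvd"):
            rr = getattr(self, name)
            if not (0.0 < rr <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {rr}")
        if self.persistence:
            tail = self.persistence[1:]
            if any(b > a for a, b in zip(tail, tail[1:])):
                raise ValueError("persistence must be non-increasing after year 1")

    @property
    def relative_risks(self) -> dict[str, float]:
        return {
            "nonfatal_chd": self.rr_nonfatal_chd,
            "nonfatal_cbvd": self.rr_nonfatal_cbvd,
            "fatal_cvd": self.rr_fatal_cvd,
        }


@dataclass
class ArrInputs:
    """Inputs to the 10-year ARR prioritization equation.

    ``s_un`` is 10-year untreated survival (free of the composite CVD
    endpoint), ``hr_per_mmol`` the hazard ratio per 1.0 mmol/L lipid
    reduction, ``lipid_baseline`` the baseline lipid level (non-HDL-C in
    the modified form) and ``reduction_pct`` the proportional reduction
    statins achieve (0.40 for LDL-C, 0.26 for non-HDL-C).
    """

    s_un: float | np.ndarray
    hr_per_mmol: float | np.ndarray
    lipid_baseline: float | np.ndarray
    reduction_pct: float = 0.26


def rrr_from_lipid_reduction(delta, hr_per_mmol):
    """Relative risk reduction from an absolute lipid reduction ``delta`` (mmol/L).

    The RRR compounds geometrically: ``1 - hr_per_mmol ** delta``.
    Accepts scalars or arrays.
    """
    delta = np.asarray(delta, dtype=float)
    hr = np.asarray(hr_per_mmol, dtype=float)
    if np.any(delta < 0):
        raise ValueError("lipid reduction must be non-negative")
    if np.any((hr <= 0) | (hr > 1)):
        raise ValueError("hazard ratio per mmol/L must lie in (0, 1]")
    out = 1.0 - hr**delta
    return float(out) if out.ndim == 0 else out


def lipid_reduction(baseline, pct):
    """Absolute lipid reduction (mmol/L) from a proportional reduction ``pct``."""
    baseline = np.asarray(baseline, dtype=float)
    if np.any(baseline <= 0):
        raise ValueError("baseline lipid level must be positive")
    pct = np.asarray(pct, dtype=float)
    if np.any((pct < 0) | (pct >= 1)):
        raise ValueError("proportional reduction must lie in [0, 1)")
    out = baseline * pct
    return float(out) if out.ndim == 0 else out


def arr_10yr(inputs: ArrInputs):
    """10-year absolute risk reduction ``S_un**x - S_un`` with ``x = HR**(lipid × pct)``.

    Larger baseline lipid levels and larger baseline risk (smaller
    ``s_un``) both increase the ARR when the hazard ratio is below 1.
    """
    s_un = np.asarray(inputs.s_un, dtype=float)
    hr = np.asarray(inputs.hr_per_mmol, dtype=float)
    ldlb = np.asarray(inputs.lipid_baseline, dtype=float)
    if np.any(s_un <= 0):
        raise ValueError("untreated survival must be positive (degenerate S_un=0)")
    if np.any(s_un > 1):
        raise ValueError("untreated survival must not exceed 1")
    if np.any((hr <= 0) | (hr > 1)):
        raise ValueError("hazard ratio must lie in (0, 1]")
    if np.any(ldlb <= 0):
        raise ValueError("baseline lipid level must be positive")
    x = hr ** (ldlb * inputs.reduction_pct)
    out = s_un**x - s_un
    return float(out) if out.ndim == 0 else out


def combined_hr_per_mmol(
    relative_risks: Mapping[str, float], risk_shares: Mapping[str, float | np.ndarray]
):
    """Single combined-CVD hazard ratio per mmol/L from cause-specific relative risks.

    Computed as the geometric mean of the cause-specific relative risks
    weighted by each cause's share of the composite 10-year CVD risk, so
    the single-HR form of the ARR equation is preserved.  Shares may be
    per-profile arrays; they are renormalized over the statin-modified
    causes.
    """
    shares = {c: np.asarray(risk_shares[c], dtype=float) for c in STATIN_CAUSES}
    total = sum(shares.values())
    log_hr = sum(
        np.where(total > 0, shares[c] / np.where(total > 0, total, 1.0), 1.0 / 3.0)
        * math.log(relative_risks[c])
        for c in STATIN_CAUSES
    )
    out = np.exp(log_hr)
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class StatinModifiers:
    """Per-profile consequences of being on statin therapy for one year."""

    hazard_multipliers: dict[str, float | np.ndarray]
    pill_disutility: float
    annual_drug_cost: float
    diabetes_risk_increase: float

    def is_null(self) -> bool:
        return (
            all(np.all(np.asarray(m) == 1.0) for m in self.hazard_multipliers.values())
            and self.pill_disutility == 0.0
            and self.annual_drug_cost == 0.0
            and self.diabetes_risk_increase == 0.0
        )


def apply_statin_modifiers(nonhdl, params: TreatmentParams) -> StatinModifiers:
    """Hazard, utility and cost modifiers for a profile with baseline ``nonhdl`` (mmol/L).

    The per-cause hazard multiplier is ``rr_c ** delta`` where
    ``delta = nonhdl × nonhdl_reduction`` is the absolute non-HDL-C
    reduction the therapy achieves for this profile.
    """
    nonhdl = np.asarray(nonhdl, dtype=float)
    if np.any(nonhdl <= 0):
        raise ValueError("non-HDL-C must be positive")
    delta = nonhdl * params.nonhdl_reduction
    mult = {c: rr**delta for c, rr in params.relative_risks.items()}
    if np.ndim(nonhdl) == 0:
        mult = {c: float(m) for c, m in mult.items()}
    return StatinModifiers(
        hazard_multipliers=mult,
        pill_disutility=params.pill_disutility,
        annual_drug_cost=params.annual_drug_cost,
        diabetes_risk_increase=params.diabetes_abs_risk_increase,
    )


def persistence_fraction(years_since_initiation: int, params: TreatmentParams) -> float:
    """Fraction of initiators still on therapy during a given year (1-based).

    Under the base case (empty schedule) everyone persists; under the
    adherence scenario the configured schedule applies, with the final
    entry extending to all subsequent years.
    """
    if years_since_initiation < 1:
        raise ValueError("years_since_initiation is 1-based")
    if not params.persistence:
        return 1.0
    idx = min(years_since_initiation - 1, len(params.persistence) - 1)
    return params.persistence[idx]


def discontinuation_mixture(params: TreatmentParams) -> list[tuple[float, int | None]]:
    """Decompose a persistence schedule into (weight, years-treated) components.

    Returns a list of ``(weight, k)`` pairs where ``k`` is the number of
    years on therapy (``None`` meaning lifetime, ``0`` meaning the
    initiator never persisted beyond pickup and contributes first-year
    costs only).  Weights sum to 1.  Under full adherence the mixture is
    a single lifetime component.
    """
    if not params.persistence:
        return [(1.0, None)]
    sched = list(params.persistence)
    components: list[tuple[float, int | None]] = []
    never = 1.0 - sched[0]
    if never > 0:
        components.append((never, 0))
    for k in range(1, len(sched)):
        drop = sched[k - 1] - sched[k]
        if drop > 0:
            components.append((drop, k))
    components.append((sched[-1], None))
    return components
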