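"""Utilities, costs, discounting and inflation.

Converts state trajectories into quality-adjusted life-years and 2020
GBP from a health-sector perspective: age/sex background utility with
chronic-state and secondary-event decrements, linear pre-/post-event
hospitalization cost equations, annual discounting and a one-off
inflation uplift for 2014-based model costs.

The shipped default values are synthetic, UK-plausible magnitudes (see
``configs/econ_default.yaml``); the real fitted cost and utility tables
are accepted as configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .states import HealthState

__all__ = [
    "EconParams",
    "state_utility",
    "background_utility",
    "event_cost",
    "discount_stream",
    "discount_factors",
    "inflate_cost",
]


@dataclass
class EconParams:
    """Economic model parameters.

    ``background_utility_bands`` rows are ``(age_lo, female, male)`` with
    bands extending to the next row's lower edge.  Event-cost equations
    are linear in age at the primary event, deprivation (SIMD) and family
    history, floored at zero; the same equations apply to both chronic
    states.  ``inflation_factor`` uplifts 2014-based model costs to 2020
    prices and is *not* applied to costs already quoted in 2020 GBP
    (e.g. the drug tariff price).
    """

    discount_rate: float = 0.035
    inflation_factor: float = 0.125
    wtp_threshold: float = 20_000.0
    background_utility_bands: tuple[tuple[float, float, float], ...] = (
        (40.0, 0.91, 0.90),
        (50.0, 0.87, 0.86),
        (60.0, 0.82, 0.81),
        (70.0, 0.77, 0.76),
        (80.0, 0.71, 0.70),
        (90.0, 0.64, 0.63),
    )
    chronic_decrement: dict[str, float] = field(
        default_factory=lambda: {"chd": 0.09, "cbvd": 0.13}
    )
    #: expected annual utility loss from secondary CVD events while chronic
    secondary_event_decrement: dict[str, float] = field(
        default_factory=lambda: {"chd": 0.015, "cbvd": 0.012}
    )
    screening_cost: float = 15.0
    monitoring_cost: float = 30.0
    diabetes_cost: float = 350.0
    #: annual non-CVD background healthcare cost while alive (2014 GBP)
    background_cost: float = 900.0
    background_cost_age_slope: float = 25.0  # per year of age above 40
    event_cost_coefficients: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "pre": {"intercept": 3200.0, "age": -12.0, "simd": 8.0, "famhist": 60.0},
            "post": {"intercept": 950.0, "age": -4.0, "simd": 3.0, "famhist": 25.0},
        }
    )

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ValueError("discount rate must be non-negative")
        for _, f, m in self.background_utility_bands:
            if not (0.0 <= f <= 1.0 and 0.0 <= m <= 1.0):
                raise ValueError("background utilities must lie in [0, 1]")
        if any(d < 0 for d in self.chronic_decrement.values()):
            raise ValueError("chronic decrements must be non-negative")


def background_utility(age, is_male, params: EconParams):
    """Age/sex background health-related quality of life (vectorized)."""
    age = np.asarray(age, dtype=float)
    is_male = np.asarray(is_male, dtype=bool)
    edges = np.array([b[0] for b in params.background_utility_bands])
    fem = np.array([b[1] for b in params.background_utility_bands])
    mal = np.array([b[2] for b in params.background_utility_bands])
    idx = np.clip(np.searchsorted(edges, age, side="right") - 1, 0, len(edges) - 1)
    out = np.where(is_male, mal[idx], fem[idx])
    return float(out) if out.ndim == 0 else out


_CHRONIC_KEY = {HealthState.CHRONIC_CHD: "chd", HealthState.CHRONIC_CBVD: "cbvd"}


def state_utility(age, is_male, state: HealthState, params: EconParams):
    """Annual utility for occupants of a health state; dead states yield 0.

    Chronic CVD states take the background utility minus the chronic
    decrement and the expected secondary-event decrement, clipped to
    [0, 1].
    """
    if state.is_dead():
        return 0.0 if np.ndim(age) == 0 else np.zeros(np.shape(age))
    u = background_utility(age, is_male, params)
    if state in _CHRONIC_KEY:
        key = _CHRONIC_KEY[state]
        u = u - params.chronic_decrement[key] - params.secondary_event_decrement[key]
    out = np.clip(u, 0.0, 1.0)
    return float(out) if np.ndim(out) == 0 else out


def event_cost(age_at_event, simd, famhist, phase: str, params: EconParams):
    """Annual hospitalization cost (2014 GBP) around a primary nonfatal event.

    ``phase`` is ``"pre"`` (the event year) or ``"post"`` (each later
    year in the chronic state).  Linear in age at event, SIMD and family
    history; floored at zero.
    """
    if phase not in params.event_cost_coefficients:
        raise KeyError(f"unknown event-cost phase {phase!r}")
    c = params.event_cost_coefficients[phase]
    out = (
        c["intercept"]
        + c["age"] * np.asarray(age_at_event, dtype=float)
        + c["simd"] * np.asarray(simd, dtype=float)
        + c["famhist"] * np.asarray(famhist, dtype=float)
    )
    out = np.maximum(out, 0.0)
    return float(out) if np.ndim(out) == 0 else out


def discount_factors(n_cycles: int, rate: float) -> np.ndarray:
    """Per-cycle discount factors ``1/(1+rate)**t`` with t = 0 for the first cycle."""
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    return (1.0 + rate) ** -np.arange(n_cycles, dtype=float)


def discount_stream(values: Sequence[float], rate: float) -> float:
    """Present value of a per-cycle stream; the first cycle is undiscounted."""
    values = np.asarray(values, dtype=float)
    return float(values @ discount_factors(len(values), rate))


def inflate_cost(cost_2014, params: EconParams):
    """Uplift a 2014-based cost to 2020 prices."""
    cost = np.asarray(cost_2014, dtype=float)
    if np.any(cost < 0):
        raise ValueError("costs must be non-negative")
    out = cost * (1.0 + params.inflation_factor)
    return float(out) if out.ndim == 0 else out
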