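"""Cost-effectiveness synthesis: ICER frontier, NMB, CEAC, tornado, projection.

Strategies are compared with standard decision rules: strategies that
are more costly and no more effective than an alternative are strictly
dominated; strategies whose incremental cost-effectiveness ratio
exceeds that of a more effective alternative are excluded by extended
dominance; the remaining efficiency frontier has strictly increasing
ICERs.  Net monetary benefit (λ·QALY − cost) linearizes the same
decision rule at a given willingness to pay, and the CEAC reports the
fraction of probabilistic iterations in which each strategy is optimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StrategyOutcome",
    "FrontierResult",
    "icer_frontier",
    "nmb",
    "ceac",
    "tornado",
    "project_population",
]


@dataclass
class StrategyOutcome:
    """Mean (and optionally per-iteration) cost/QALY results for one strategy."""

    label: str
    cost: float
    qaly: float
    iteration_costs: np.ndarray | None = None
    iteration_qalys: np.ndarray | None = None
    eligible_count: float | None = None


@dataclass
class FrontierResult:
    """Efficiency frontier: retained strategies, their pairwise ICERs, and flags."""

    frontier: list[str]
    icers: dict[str, float]  # ICER vs the previous frontier member; first is NaN/0
    dominated: dict[str, str]  # excluded label -> "strict" | "extended"
    tied: list[str] = field(default_factory=list)


def icer_frontier(outcomes: Sequence[StrategyOutcome]) -> FrontierResult:
    """Compute the cost-effectiveness frontier with strict and extended dominance.

    Strategies are sorted by cost (stable for exact ties, which are
    flagged); strictly dominated strategies (≥ cost, ≤ QALY vs some
    other, strict in at least one) are removed, then extendedly
    dominated ones until pairwise ICERs increase strictly along the
    frontier.
    """
    if len(outcomes) < 2:
        raise ValueError("frontier needs at least 2 strategies")
    tied = []
    seen: dict[tuple[float, float], str] = {}
    for o in outcomes:
        key = (o.cost, o.qaly)
        if key in seen:
            tied.append(o.label)
        seen[key] = o.label

    dominated: dict[str, str] = {}
    # exactly tied (cost, qaly) pairs: keep the first in stable order
    first_of: dict[tuple[float, float], str] = {}
    for o in outcomes:
        key = (o.cost, o.qaly)
        if key not in first_of:
            first_of[key] = o.label
    outcomes = [o for o in outcomes if first_of[(o.cost, o.qaly)] == o.label]
    # strict dominance
    for o in outcomes:
        for p in outcomes:
            if p.label == o.label:
                continue
            if (
                p.cost <= o.cost
                and p.qaly >= o.qaly
                and (p.cost < o.cost or p.qaly > o.qaly)
            ):
                dominated[o.label] = "strict"
                break
    rest = [o for o in outcomes if o.label not in dominated]
    rest.sort(key=lambda o: (o.cost, o.qaly))
    # extended dominance: repeatedly drop members breaking ICER monotonicity
    changed = True
    while changed and len(rest) > 2:
        changed = False
        icers = [
            (rest[i].cost - rest[i - 1].cost) / (rest[i].qaly - rest[i - 1].qaly)
            for i in range(1, len(rest))
        ]
        for i in range(len(icers) - 1):
            if icers[i] >= icers[i + 1]:
                dominated[rest[i + 1].label] = "extended"
                del rest[i + 1]
                changed = True
                break
    icers_out: dict[str, float] = {rest[0].label: float("nan")}
    for i in range(1, len(rest)):
        icers_out[rest[i].label] = (rest[i].cost - rest[i - 1].cost) / (
            rest[i].qaly - rest[i - 1].qaly
        )
    return FrontierResult(
        frontier=[o.label for o in rest], icers=icers_out, dominated=dominated, tied=tied
    )


def nmb(cost, qaly, wtp: float):
    """Net monetary benefit ``wtp × qaly − cost`` (GBP)."""
    if wtp < 0:
        raise ValueError("willingness to pay must be non-negative")
    out = wtp * np.asarray(qaly, float) - np.asarray(cost, float)
    return float(out) if np.ndim(out) == 0 else out


def ceac(
    iteration_results: pd.DataFrame, wtp_grid: np.ndarray | Sequence[float]
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves over a willingness-to-pay grid.

    ``iteration_results`` has columns ``iteration``, ``strategy``,
    ``cost``, ``qaly``.  At each λ the probability a strategy is optimal
    is the fraction of iterations in which it attains maximal NMB; exact
    ties split the iteration equally, so curves sum to 1 pointwise.
    """
    wide_c = iteration_results.pivot(index="iteration", columns="strategy", values="cost")
    wide_q = iteration_results.pivot(index="iteration", columns="strategy", values="qaly")
    if len(wide_c) < 2:
        raise ValueError("CEAC needs at least 2 iterations")
    strategies = list(wide_c.columns)
    C = wide_c.to_numpy()
    Q = wide_q.to_numpy()
    rows = []
    for lam in np.asarray(wtp_grid, float):
        benefit = lam * Q - C
        best = benefit.max(axis=1, keepdims=True)
        winners = np.isclose(benefit, best, rtol=0.0, atol=1e-9)
        share = winners / winners.sum(axis=1, keepdims=True)
        probs = share.mean(axis=0)
        for s, p in zip(strategies, probs):
            rows.append({"wtp": lam, "strategy": s, "p_optimal": float(p)})
    return pd.DataFrame(rows)


def tornado(
    evaluate: Callable[[Mapping[str, float]], tuple[float, float]],
    base_values: Mapping[str, float],
    bounds: Mapping[str, tuple[float, float]],
    wtp: float,
) -> pd.DataFrame:
    """One-way sensitivity analysis summarized as a tornado table.

    ``evaluate`` maps a measure-override dict to the (incremental cost,
    incremental QALY) of the strategy comparison under study; for every
    measure the model is rerun at its low and high bound holding all
    others at base, and the resulting NMB at ``wtp`` defines the bar.
    Rows are sorted by bar width, widest first.
    """
    missing = set(bounds) - set(base_values)
    if missing:
        raise KeyError(f"bounds given for unknown measures: {sorted(missing)}")
    rows = []
    base_cost, base_qaly = evaluate({})
    base_nmb = nmb(base_cost, base_qaly, wtp)
    for name, (lo, hi) in bounds.items():
        c_lo, q_lo = evaluate({name: lo})
        c_hi, q_hi = evaluate({name: hi})
        nmb_lo, nmb_hi = nmb(c_lo, q_lo, wtp), nmb(c_hi, q_hi, wtp)
        rows.append(
            {
                "measure": name,
                "value_lo": lo,
                "value_hi": hi,
                "nmb_at_lo": nmb_lo,
                "nmb_at_hi": nmb_hi,
                "nmb_base": base_nmb,
                "width": abs(nmb_hi - nmb_lo),
            }
        )
    return pd.DataFrame(rows).sort_values("width", ascending=False).reset_index(drop=True)


def project_population(
    agegroup_outcomes: pd.DataFrame,
    population_counts: Mapping[str, float],
    cvdfree_fractions: Mapping[str, float],
) -> dict[str, float]:
    """Project per-age-group mean simulation outcomes onto a national population.

    ``agegroup_outcomes`` has one row per age group with mean per-person
    outcome columns; national totals are the outcome means multiplied by
    the group's population count and CVD-free fraction, summed over
    groups.  Age groups must align exactly.
    """
    groups = list(agegroup_outcomes["age_band"])
    if set(groups) != set(population_counts) or set(groups) != set(cvdfree_fractions):
        raise ValueError("age bands misaligned between simulation and population tables")
    value_cols = [c for c in agegroup_outcomes.columns if c != "age_band"]
    totals = {c: 0.0 for c in value_cols}
    for _, row in agegroup_outcomes.iterrows():
        g = row["age_band"]
        scale = population_counts[g] * cvdfree_fractions[g]
        for c in value_cols:
            totals[c] += float(row[c]) * scale
    return totals
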