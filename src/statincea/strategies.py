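"""Statin eligibility strategies and threshold calibration.

Three eligibility families are supported: a fixed 10-year risk
threshold (ASSIGN-style scoring), age-stratified risk thresholds that
treat individuals at high risk relative to their 5-year age-band peers,
and absolute-risk-reduction (ARR) thresholds that favour individuals
with elevated non-HDL cholesterol.  Alternative strategies are
calibrated to treat (approximately) the same weighted number of people
as a reference risk-threshold policy, so that policies of equal reach
can be compared on cost-effectiveness alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StrategyDef",
    "STRATEGY_AGE_BANDS",
    "age_band_labels",
    "eligible",
    "calibrate_to_count",
    "eligibility_summary",
    "weighted_quantile",
]

#: 5-year eligibility age bands 40–44 … 75–79, then 80+
STRATEGY_AGE_BANDS: tuple[tuple[float, float], ...] = (
    (40, 45), (45, 50), (50, 55), (55, 60), (60, 65), (65, 70), (70, 75), (75, 80),
    (80, float("inf")),
)


def age_band_labels() -> list[str]:
    labels = [f"{int(lo)}-{int(hi) - 1}" for lo, hi in STRATEGY_AGE_BANDS[:-1]]
    labels.append("80+")
    return labels


def _band_index(age: np.ndarray) -> np.ndarray:
    edges = np.array([b[0] for b in STRATEGY_AGE_BANDS], float)
    idx = np.searchsorted(edges, age, side="right") - 1
    if np.any(idx < 0):
        raise ValueError("age below the first eligibility band (40)")
    return idx


@dataclass
class StrategyDef:
    """An eligibility rule: family, threshold(s) and a display label.

    ``threshold`` is a scalar for ``fixed_risk`` (10-year risk) and
    ``arr`` (ARR probability) families, and a per-band array for
    ``age_stratified``.  ``warning`` is set by calibration when the
    target count could not be matched within tolerance.
    """

    family: str
    threshold: float | tuple[float, ...] | None = None
    label: str = ""
    warning: str | None = None

    def __post_init__(self) -> None:
        if self.family not in ("fixed_risk", "age_stratified", "arr", "none"):
            raise ValueError(f"unknown strategy family {self.family!r}")
        if self.family == "age_stratified":
            thr = np.asarray(self.threshold, float)
            if thr.shape != (len(STRATEGY_AGE_BANDS),):
                raise ValueError("age_stratified needs one threshold per age band")
        elif self.family != "none":
            if self.threshold is None or not 0.0 <= float(self.threshold) <= 1.0:
                raise ValueError("threshold must lie in [0, 1]")
        if not self.label:
            self.label = self.family


def eligible(
    strategy: StrategyDef,
    profiles: pd.DataFrame,
    risk: np.ndarray | None = None,
    arr: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean eligibility per profile; thresholds are inclusive (≥)."""
    n = len(profiles)
    if strategy.family == "none":
        return np.zeros(n, dtype=bool)
    if strategy.family in ("fixed_risk", "age_stratified"):
        if risk is None:
            raise ValueError("risk scores required for risk-based strategies")
        score = np.asarray(risk, float)
    else:
        if arr is None:
            raise ValueError("ARR values required for the arr strategy")
        score = np.asarray(arr, float)
    if strategy.family == "age_stratified":
        thr = np.asarray(strategy.threshold, float)[_band_index(profiles["age"].to_numpy(float))]
    else:
        thr = float(strategy.threshold)
    return score >= thr


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Weighted lower quantile: smallest v with cumulative weight ≥ q·total."""
    order = np.argsort(values)
    v, w = np.asarray(values, float)[order], np.asarray(weights, float)[order]
    cw = np.cumsum(w)
    target = q * cw[-1]
    idx = int(np.searchsorted(cw, target, side="left"))
    return float(v[min(idx, len(v) - 1)])


def _eligible_weight_at(score, weights, thr) -> float:
    return float(weights[score >= thr].sum())


def _calibrate_scalar(score, weights, target, tol_frac) -> tuple[float, str | None]:
    """Pick the inclusive threshold whose eligible weight best matches target."""
    total = float(weights.sum())
    order = np.argsort(score)[::-1]
    s, w = score[order], weights[order]
    cw = np.cumsum(w)
    # candidate thresholds are the observed scores (inclusive ≥) plus 0
    # eligible weight at threshold s_k (with ties grouped) is cw at the
    # last index of that tie group
    uniq, last_idx = np.unique(s[::-1], return_index=True)
    uniq = uniq[::-1]
    grp_weight = np.array([cw[len(s) - 1 - li] for li in last_idx[::-1]])
    cand_thr = np.append(uniq, 0.0)
    cand_w = np.append(grp_weight, total)
    err = np.abs(cand_w - target)
    best = int(np.argmin(err))
    warning = None
    if err[best] > tol_frac * total:
        warning = (
            f"calibration tolerance exceeded: nearest attainable eligible weight "
            f"{cand_w[best]:.1f} vs target {target:.1f}"
        )
    return float(cand_thr[best]), warning


def calibrate_to_count(
    family: str,
    cohort: pd.DataFrame,
    target_weight: float,
    risk: np.ndarray | None = None,
    arr: np.ndarray | None = None,
    tol_frac: float = 0.005,
    label: str = "",
) -> StrategyDef:
    """Calibrate a strategy so its eligible weighted count matches a target.

    ``fixed_risk`` and ``arr`` families place a single threshold at the
    weighted quantile of the score.  ``age_stratified`` solves for a
    single within-band quantile q — treating the top q fraction (by
    weight) of every age band — such that total eligible weight matches
    the target; this targets individuals at high risk relative to their
    age-band peers.  If ties make the target unattainable within
    ``tol_frac`` of total cohort weight, the nearest attainable
    threshold is returned with ``warning`` set.
    """
    weights = cohort["weight"].to_numpy(float)
    total = float(weights.sum())
    if target_weight > total * (1 + 1e-9):
        raise ValueError("target exceeds total cohort weight")
    if family in ("fixed_risk", "arr"):
        score = np.asarray(risk if family == "fixed_risk" else arr, float)
        if target_weight >= total:
            return StrategyDef(family, 0.0, label or family)
        thr, warning = _calibrate_scalar(score, weights, target_weight, tol_frac)
        out = StrategyDef(family, thr, label or family)
        out.warning = warning
        return out
    if family != "age_stratified":
        raise ValueError(f"cannot calibrate family {family!r}")
    if risk is None:
        raise ValueError("risk scores required to calibrate age_stratified")
    score = np.asarray(risk, float)
    bands = _band_index(cohort["age"].to_numpy(float))
    per_band = [(score[bands == b], weights[bands == b]) for b in range(len(STRATEGY_AGE_BANDS))]

    def eligible_weight(q: float) -> float:
        tot = 0.0
        for s_b, w_b in per_band:
            if len(s_b) == 0:
                continue
            thr_b = weighted_quantile(s_b, w_b, 1.0 - q)
            tot += float(w_b[s_b >= thr_b].sum())
        return tot

    # eligible weight is monotone non-decreasing in q: bisect
    lo_q, hi_q = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo_q + hi_q)
        if eligible_weight(mid) < target_weight:
            lo_q = mid
        else:
            hi_q = mid
    q = hi_q
    thr = []
    for s_b, w_b in per_band:
        thr.append(weighted_quantile(s_b, w_b, 1.0 - q) if len(s_b) else 1.0)
    out = StrategyDef("age_stratified", tuple(thr), label or "age_stratified")
    achieved = eligible_weight(q)
    if abs(achieved - target_weight) > tol_frac * total:
        out.warning = (
            f"calibration tolerance exceeded: achieved {achieved:.1f} vs target {target_weight:.1f}"
        )
    return out


def eligibility_summary(
    strategy: StrategyDef,
    cohort: pd.DataFrame,
    risk: np.ndarray | None = None,
    arr: np.ndarray | None = None,
) -> pd.DataFrame:
    """Weighted eligibility prevalence by age band plus an overall row."""
    elig = eligible(strategy, cohort, risk, arr)
    weights = cohort["weight"].to_numpy(float)
    bands = _band_index(cohort["age"].to_numpy(float))
    rows = []
    labels = age_band_labels()
    for b, lab in enumerate(labels):
        sel = bands == b
        tot = float(weights[sel].sum())
        el = float(weights[sel & elig].sum())
        rows.append(
            {
                "strategy": strategy.label,
                "age_band": lab,
                "eligible_weight": el,
                "total_weight": tot,
                "pct_eligible": 100.0 * el / tot if tot > 0 else 0.0,
            }
        )
    tot = float(weights.sum())
    el = float(weights[elig].sum())
    rows.append(
        {
            "strategy": strategy.label,
            "age_band": "all",
            "eligible_weight": el,
            "total_weight": tot,
            "pct_eligible": 100.0 * el / tot if tot > 0 else 0.0,
        }
    )
    return pd.DataFrame(rows)
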