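"""Probabilistic sensitivity analysis machinery.

Parameter uncertainty is propagated by sampling each treatment and
economic measure from its declared distribution (beta for proportions
and utilities, gamma for costs, lognormal for relative risks) and the
covariate log-hazard-ratios from a correlated multivariate normal built
with a Cholesky factor.  Per-iteration seeds are derived from the
master seed by counter-based spawning so iterations are independent,
reproducible and order-insensitive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MeasureDist",
    "PsaSample",
    "sample_parameters",
    "correlated_hr_draw",
    "summarize_psa",
]


@dataclass
class MeasureDist:
    """Distribution of one sampled measure.

    ``dist`` ∈ {normal, beta, gamma, lognormal, fixed}; ``sd = 0`` (or
    ``fixed``) collapses to the base value.  Beta and gamma are
    moment-matched to (base, sd).
    """

    name: str
    base: float
    sd: float = 0.0
    dist: str = "fixed"

    def __post_init__(self) -> None:
        if self.dist not in ("normal", "beta", "gamma", "lognormal", "fixed"):
            raise ValueError(f"measure {self.name!r}: undeclared distribution {self.dist!r}")
        if self.sd < 0:
            raise ValueError(f"measure {self.name!r}: negative sd")

    def draw(self, rng: np.random.Generator) -> float:
        if self.dist == "fixed" or self.sd == 0.0:
            return self.base
        m, s = self.base, self.sd
        if self.dist == "normal":
            return float(rng.normal(m, s))
        if self.dist == "beta":
            v = s**2
            if not 0 < m < 1 or v >= m * (1 - m):
                raise ValueError(f"measure {self.name!r}: beta moments infeasible")
            k = m * (1 - m) / v - 1.0
            return float(rng.beta(m * k, (1 - m) * k))
        if self.dist == "gamma":
            shape = (m / s) ** 2
            return float(rng.gamma(shape, m / shape))
        # lognormal, moment-matched
        sigma2 = np.log1p((s / m) ** 2)
        mu = np.log(m) - 0.5 * sigma2
        return float(rng.lognormal(mu, np.sqrt(sigma2)))


@dataclass
class PsaSample:
    """One parameter draw: measure values plus the sampled log-HR vector."""

    index: int
    measures: dict[str, float]
    log_hrs: np.ndarray | None = None
    seed: tuple[int, int] = (0, 0)


def _iter_rng(master_seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([int(master_seed), int(index)])


def sample_parameters(
    distributions: Sequence[MeasureDist],
    n_iter: int,
    master_seed: int,
    mean_log_hrs: np.ndarray | None = None,
    hr_covariance: np.ndarray | None = None,
) -> list[PsaSample]:
    """Draw ``n_iter`` independent parameter sets, reproducibly.

    Iteration ``i`` uses the generator seeded with ``(master_seed, i)``
    so any subset of iterations can be regenerated independently.
    """
    samples = []
    for i in range(n_iter):
        rng = _iter_rng(master_seed, i)
        measures = {d.name: d.draw(rng) for d in distributions}
        log_hrs = None
        if mean_log_hrs is not None:
            cov = hr_covariance
            if cov is None:
                cov = np.zeros((len(mean_log_hrs),) * 2)
            log_hrs = correlated_hr_draw(mean_log_hrs, cov, rng=rng)
        samples.append(PsaSample(i, measures, log_hrs, seed=(master_seed, i)))
    return samples


def _psd_factor(cov: np.ndarray) -> np.ndarray:
    """Cholesky factor, falling back to an eigen factor for semidefinite input."""
    if not np.allclose(cov, cov.T, atol=1e-12):
        raise ValueError(f"covariance matrix is not symmetric:\n{cov}")
    if np.allclose(cov, 0.0):
        return np.zeros_like(cov)
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(cov)
        if np.any(vals < -1e-10 * max(1.0, vals.max())):
            raise ValueError(f"covariance matrix is not positive semi-definite:\n{cov}")
        return vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))


def correlated_hr_draw(
    mean_log_hrs: np.ndarray,
    covariance: np.ndarray,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One draw of the log-hazard-ratio vector: ``mean + L·z``.

    ``L`` is the Cholesky factor of the covariance, ``z`` iid standard
    normal.  A zero covariance returns the mean exactly.
    """
    mean = np.asarray(mean_log_hrs, float)
    cov = np.asarray(covariance, float)
    if cov.shape != (len(mean), len(mean)):
        raise ValueError("covariance shape must match mean vector")
    L = _psd_factor(cov)
    if rng is None:
        rng = np.random.default_rng(seed)
    if np.allclose(L, 0.0):
        return mean.copy()
    return mean + L @ rng.standard_normal(len(mean))


def summarize_psa(
    results: pd.DataFrame, reference: str, ci: tuple[float, float] = (2.5, 97.5)
) -> pd.DataFrame:
    """Summarize per-iteration (cost, QALY) pairs across strategies.

    ``results`` must have columns ``iteration``, ``strategy``, ``cost``,
    ``qaly``.  For each strategy the base case is the mean over
    iterations; incremental quantities are taken against ``reference``
    and the ICER is the ratio of mean increments.  Percentile intervals
    (linear interpolation) are reported for incremental cost, QALYs and
    the per-iteration ICER distribution.
    """
    if results["iteration"].nunique() < 2:
        raise ValueError("PSA summary needs at least 2 iterations")
    wide_c = results.pivot(index="iteration", columns="strategy", values="cost")
    wide_q = results.pivot(index="iteration", columns="strategy", values="qaly")
    rows = []
    for strat in wide_c.columns:
        dc = wide_c[strat] - wide_c[reference]
        dq = wide_q[strat] - wide_q[reference]
        mean_dc, mean_dq = float(dc.mean()), float(dq.mean())
        icer = mean_dc / mean_dq if mean_dq != 0 else np.nan
        with np.errstate(divide="ignore", invalid="ignore"):
            icers = np.where(dq != 0, dc / dq, np.nan)
        rows.append(
            {
                "strategy": strat,
                "mean_cost": float(wide_c[strat].mean()),
                "mean_qaly": float(wide_q[strat].mean()),
                "mean_inc_cost": mean_dc,
                "mean_inc_qaly": mean_dq,
                "icer_of_means": icer,
                "inc_cost_lo": float(np.percentile(dc, ci[0])),
                "inc_cost_hi": float(np.percentile(dc, ci[1])),
                "inc_qaly_lo": float(np.percentile(dq, ci[0])),
                "inc_qaly_hi": float(np.percentile(dq, ci[1])),
                "icer_lo": float(np.nanpercentile(icers, ci[0])) if strat != reference else np.nan,
                "icer_hi": float(np.nanpercentile(icers, ci[1])) if strat != reference else np.nan,
            }
        )
    return pd.DataFrame(rows)
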