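"""Synthetic cohort generation and preprocessing.

Generates a cohort with the joint risk-factor structure of a national
health survey of CVD-free adults: sex-stratified multivariate-Gaussian
dependence over systolic blood pressure, log non-HDL-C, log HDL-C and
deprivation (so total cholesterol always exceeds HDL-C by
construction), a point-mass-inflated cigarettes-per-day distribution,
age-graded diabetes, prevalent-CVD and statin-use prevalence, and
survey expansion weights.  Nurse-visit sparsity is emulated by
missing-at-random masks on TC, HDL-C and SBP plus a block-missing
"refused nurse visit" subgroup.

The preprocessing chain is fixed: generate → impute → detreat →
exclude.  Statin users are "detreated" by reversing the trial-observed
proportional non-HDL-C reduction before eligibility is assessed, and
individuals meeting the familial-hypercholesterolaemia rule
(TC ≥ 7.5 mmol/L with a family history, or TC ≥ 8.0 mmol/L) are removed
along with under-40s and prevalent CVD.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "ExclusionLog",
    "ImputationLog",
    "generate_cohort",
    "apply_exclusions",
    "detreat_statin_users",
    "impute_stochastic_regression",
    "impute_multiple",
    "preprocess",
]

AGE_BANDS = ((40, 45), (45, 50), (50, 55), (55, 60), (60, 65), (65, 70), (70, 75), (75, 80), (80, 95))
IMPUTED_VARS = ("tc", "hdl", "sbp")
#: fully observed covariates entering the imputation regressions
IMPUTATION_PREDICTORS = ("age", "male", "diabetes", "cpd", "simd", "famhist")
TRUNCATION_BOUNDS = {"sbp": (70.0, 250.0), "tc": (2.0, 12.0), "hdl": (0.4, 4.0)}


@dataclass
class CohortSpec:
    """Configuration of the synthetic survey cohort.

    Defaults emulate a Scottish adult CVD-free population: roughly 54%
    female, blood pressure and lipids rising modestly with age, heavy
    nurse-visit missingness on the three blood measures and a small
    refusal subgroup that is block-missing on all of them.
    """

    n: int = 10_000
    #: probability of each 5-year band (40–44 … 75–79, 80+), ≥40 only
    age_band_probs: tuple[float, ...] = (0.16, 0.15, 0.14, 0.13, 0.12, 0.10, 0.08, 0.06, 0.06)
    #: fraction of generated records below age 40 (exercised by exclusions)
    under40_fraction: float = 0.08
    p_female: float = 0.54
    sbp_mean: float = 128.0
    sbp_sd: float = 16.0
    sbp_age_slope: float = 0.35  # mmHg per year of age over 40
    #: log-scale parameters of non-HDL-C and HDL-C (lognormal marginals)
    nonhdl_logmean: dict[str, float] = field(
        default_factory=lambda: {"female": np.log(3.9), "male": np.log(4.1)}
    )
    nonhdl_logsd: float = 0.24
    hdl_logmean: dict[str, float] = field(
        default_factory=lambda: {"female": np.log(1.6), "male": np.log(1.3)}
    )
    hdl_logsd: float = 0.20
    simd_mean: float = 20.0
    simd_sd: float = 12.0
    #: correlation over (sbp, log nonhdl, log hdl, simd)
    correlation: tuple[tuple[float, ...], ...] = (
        (1.00, 0.12, -0.05, 0.06),
        (0.12, 1.00, -0.18, 0.04),
        (-0.05, -0.18, 1.00, -0.08),
        (0.06, 0.04, -0.08, 1.00),
    )
    smoker_prob: float = 0.22
    cpd_mean: float = 14.0  # among smokers, gamma-distributed
    diabetes_base: float = 0.04
    diabetes_age_slope: float = 0.002  # per year over 40
    famhist_prob: float = 0.30
    cvd_base: float = 0.02
    cvd_age_slope: float = 0.004  # prevalent CVD probability per year over 40
    #: statin-use prevalence per age band (same bands as age_band_probs)
    statin_prevalence: tuple[float, ...] = (0.05, 0.07, 0.10, 0.14, 0.19, 0.24, 0.29, 0.33, 0.35)
    missingness: dict[str, float] = field(
        default_factory=lambda: {"tc": 0.50, "hdl": 0.50, "sbp": 0.40}
    )
    refusal_fraction: float = 0.07
    weight_logsd: float = 0.30
    seed: int = 0

    def validate(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        probs = np.asarray(self.age_band_probs, float)
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0, atol=1e-8):
            raise ValueError("age band probabilities must be non-negative and sum to 1")
        for k, v in self.missingness.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"missingness rate for {k} must lie in [0,1]")
        if not 0.0 <= self.refusal_fraction <= 1.0:
            raise ValueError("refusal fraction must lie in [0,1]")
        if len(self.statin_prevalence) != len(self.age_band_probs):
            raise ValueError("statin prevalence must have one entry per age band")
        corr = np.asarray(self.correlation, float)
        if corr.shape != (4, 4) or not np.allclose(corr, corr.T):
            raise ValueError("correlation must be a symmetric 4×4 matrix")


@dataclass
class ExclusionLog:
    """Counts of records removed by each exclusion rule."""

    generated: int = 0
    age_under_40: int = 0
    prevalent_cvd: int = 0
    fh_rule: int = 0
    retained: int = 0
    detreated: int = 0

    def removed(self) -> int:
        return self.age_under_40 + self.prevalent_cvd + self.fh_rule

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ImputationLog:
    """Bookkeeping for stochastic-regression imputation."""

    n_imputed: dict[str, int] = field(default_factory=dict)
    n_truncated: dict[str, int] = field(default_factory=dict)
    n_lipid_order_fixed: int = 0


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic survey cohort; deterministic given ``spec.seed``.

    Returns one row per respondent with ASSIGN risk factors, a
    prevalent-CVD flag, a current-statin flag, survey weight, a
    nurse-visit refusal flag and (possibly) missing TC/HDL-C/SBP.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    under40 = rng.random(n) < spec.under40_fraction
    band_idx = rng.choice(len(AGE_BANDS), size=n, p=np.asarray(spec.age_band_probs))
    lo = np.array([b[0] for b in AGE_BANDS])[band_idx]
    hi = np.array([b[1] for b in AGE_BANDS])[band_idx]
    age = np.floor(lo + rng.random(n) * (hi - lo))
    age = np.where(under40, np.floor(16 + rng.random(n) * 24), age)

    female = rng.random(n) < spec.p_female
    sex = np.where(female, "female", "male")

    corr = np.asarray(spec.correlation, float)
    z = rng.multivariate_normal(np.zeros(4), corr, size=n, method="cholesky")
    sbp = (
        spec.sbp_mean
        + spec.sbp_age_slope * np.maximum(age - 40.0, 0.0)
        + spec.sbp_sd * z[:, 0]
    )
    sbp = np.clip(sbp, 80.0, 240.0)
    logmean_nh = np.where(female, spec.nonhdl_logmean["female"], spec.nonhdl_logmean["male"])
    logmean_hdl = np.where(female, spec.hdl_logmean["female"], spec.hdl_logmean["male"])
    nonhdl = np.exp(logmean_nh + spec.nonhdl_logsd * z[:, 1])
    hdl = np.exp(logmean_hdl + spec.hdl_logsd * z[:, 2])
    tc = nonhdl + hdl
    simd = np.clip(spec.simd_mean + spec.simd_sd * z[:, 3], 0.0, None)

    smoker = rng.random(n) < spec.smoker_prob
    cpd = np.where(smoker, np.round(rng.gamma(2.5, spec.cpd_mean / 2.5, size=n)), 0.0)
    p_diab = np.clip(spec.diabetes_base + spec.diabetes_age_slope * np.maximum(age - 40, 0), 0, 1)
    diabetes = rng.random(n) < p_diab
    famhist = rng.random(n) < spec.famhist_prob
    p_cvd = np.clip(spec.cvd_base + spec.cvd_age_slope * np.maximum(age - 40, 0), 0, 0.4)
    prevalent_cvd = rng.random(n) < p_cvd

    statin_p = np.asarray(spec.statin_prevalence)[band_idx]
    statin_p = np.where(under40, 0.01, statin_p)
    on_statin = rng.random(n) < statin_p

    weight = rng.lognormal(-0.5 * spec.weight_logsd**2, spec.weight_logsd, size=n)

    refused = rng.random(n) < spec.refusal_fraction
    df = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "diabetes": diabetes,
            "sbp": sbp,
            "tc": tc,
            "hdl": hdl,
            "cpd": cpd,
            "simd": simd,
            "famhist": famhist,
            "on_statin": on_statin,
            "prevalent_cvd": prevalent_cvd,
            "refused_nurse_visit": refused,
            "weight": weight,
        }
    )
    # missingness: refusal subgroup is block-missing on all three measures;
    # others are independently missing-at-random at the configured rates
    for var in IMPUTED_VARS:
        mar = rng.random(n) < spec.missingness[var]
        df.loc[mar | refused, var] = np.nan
    return df


def apply_exclusions(cohort: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLog]:
    """Remove under-40s, prevalent CVD and familial-hypercholesterolaemia.

    The FH rule is TC ≥ 7.5 mmol/L with a family history of (premature)
    CVD, or TC ≥ 8.0 mmol/L regardless.  Requires observed (or imputed)
    TC.  Idempotent.  Each removed row is counted once, attributed to
    the first matching rule in the order age < 40 → prevalent CVD → FH.
    """
    log = ExclusionLog(generated=len(cohort))
    young = cohort["age"] < 40
    cvd = cohort.get("prevalent_cvd", pd.Series(False, index=cohort.index)).astype(bool)
    tc = cohort["tc"]
    fh = ((tc >= 7.5) & cohort["famhist"].astype(bool)) | (tc >= 8.0)
    fh = fh.fillna(False)
    log.age_under_40 = int(young.sum())
    log.prevalent_cvd = int((cvd & ~young).sum())
    log.fh_rule = int((fh & ~cvd & ~young).sum())
    keep = ~(young | cvd | fh)
    out = cohort.loc[keep].reset_index(drop=True)
    log.retained = len(out)
    return out, log


def detreat_statin_users(cohort: pd.DataFrame, nonhdl_reduction: float = 0.26) -> pd.DataFrame:
    """Back-calculate pre-treatment cholesterol for current statin users.

    Divides the observed non-HDL-C of statin users by
    ``1 − nonhdl_reduction``; HDL-C is unchanged and TC is updated
    consistently.  Rows with missing cholesterol are left untouched (the
    pipeline imputes first).
    """
    if not 0.0 <= nonhdl_reduction < 1.0:
        raise ValueError("nonhdl_reduction must lie in [0, 1)")
    out = cohort.copy()
    if nonhdl_reduction == 0.0:
        return out
    mask = out["on_statin"].astype(bool) & out["tc"].notna() & out["hdl"].notna()
    nonhdl = (out.loc[mask, "tc"] - out.loc[mask, "hdl"]) / (1.0 - nonhdl_reduction)
    out.loc[mask, "tc"] = out.loc[mask, "hdl"] + nonhdl
    return out


def _design_matrix(df: pd.DataFrame) -> np.ndarray:
    cols = [np.ones(len(df))]
    for name in IMPUTATION_PREDICTORS:
        if name == "male":
            cols.append((df["sex"] == "male").to_numpy(float))
        else:
            cols.append(df[name].to_numpy(float))
    return np.column_stack(cols)


def impute_stochastic_regression(
    cohort: pd.DataFrame, seed: int, min_complete: int = 30
) -> tuple[pd.DataFrame, ImputationLog]:
    """Fill missing TC/HDL-C/SBP by stochastic regression imputation.

    Each sparse variable is regressed (OLS) on the fully observed
    covariates among complete cases; missing entries get the linear
    prediction plus a Gaussian residual draw.  Out-of-bound draws are
    redrawn (up to 100 times) then clipped, and the lipid ordering
    TC > HDL-C is enforced; both interventions are logged.
    """
    rng = np.random.default_rng(seed)
    out = cohort.copy().reset_index(drop=True)
    log = ImputationLog()
    X_all = _design_matrix(out)
    for var in IMPUTED_VARS:
        missing = out[var].isna().to_numpy()
        log.n_imputed[var] = int(missing.sum())
        log.n_truncated[var] = 0
        if not missing.any():
            continue
        obs = ~out[var].isna()
        if int(obs.sum()) < min_complete:
            raise ValueError(
                f"too few complete cases ({int(obs.sum())}) to impute {var!r}"
            )
        y = out.loc[obs, var].to_numpy(float)
        X = X_all[obs.to_numpy()]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = max(len(y) - X.shape[1], 1)
        sigma = float(np.sqrt(resid @ resid / dof))
        lo, hi = TRUNCATION_BOUNDS[var]
        pred = X_all[missing] @ beta
        draw = pred + sigma * rng.standard_normal(missing.sum())
        bad = (draw < lo) | (draw > hi)
        tries = 0
        while bad.any() and tries < 100:
            draw[bad] = pred[bad] + sigma * rng.standard_normal(int(bad.sum()))
            bad = (draw < lo) | (draw > hi)
            tries += 1
        if bad.any():
            log.n_truncated[var] += int(bad.sum())
            draw = np.clip(draw, lo, hi)
        out.loc[missing, var] = draw
    # enforce lipid ordering on imputed rows: TC must exceed HDL-C
    bad_order = out["tc"] <= out["hdl"]
    if bad_order.any():
        log.n_lipid_order_fixed = int(bad_order.sum())
        out.loc[bad_order, "tc"] = out.loc[bad_order, "hdl"] + 0.1
    return out, log


def impute_multiple(
    cohort: pd.DataFrame, m: int, seed: int
) -> list[pd.DataFrame]:
    """Multiple imputation for the nurse-visit refusal subgroup.

    Ordinary missing-at-random values are singly imputed (identically
    across completions); the block-missing refusal subgroup receives
    ``m`` stochastically distinct completions.  Downstream results are
    averaged over the completions.
    """
    if m < 2:
        raise ValueError("multiple imputation requires m >= 2")
    cohort = cohort.reset_index(drop=True)
    refused = cohort.get(
        "refused_nurse_visit", pd.Series(False, index=cohort.index)
    ).astype(bool)
    base_imp, _ = impute_stochastic_regression(cohort, seed)
    if not refused.any():
        return [base_imp.copy() for _ in range(m)]
    completions = []
    for i in range(m):
        comp = cohort.copy()
        # keep the single imputation for non-refusal rows
        nonref = (~refused).to_numpy()
        comp.loc[nonref, list(IMPUTED_VARS)] = base_imp.loc[nonref, list(IMPUTED_VARS)].to_numpy()
        comp_i, _ = impute_stochastic_regression(comp, seed=int(seed) * 1000 + 7 * i + 1)
        completions.append(comp_i)
    return completions


def preprocess(
    spec: CohortSpec, nonhdl_reduction: float = 0.26, imputation_seed: int | None = None
) -> tuple[pd.DataFrame, ExclusionLog, ImputationLog]:
    """Full preprocessing chain: generate → impute → detreat → exclude.

    The FH exclusion is evaluated on detreated cholesterol, so the
    ordering is load-bearing.  Deterministic given ``spec.seed``.
    """
    raw = generate_cohort(spec)
    imp_seed = spec.seed + 1 if imputation_seed is None else imputation_seed
    completed, imp_log = impute_stochastic_regression(raw, seed=imp_seed)
    detreated = detreat_statin_users(completed, nonhdl_reduction)
    final, excl_log = apply_exclusions(detreated)
    excl_log.detreated = int(detreated["on_statin"].astype(bool).sum())
    return final, excl_log, imp_log
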