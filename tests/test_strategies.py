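"""Eligibility rules and count-matched threshold calibration."""

import numpy as np
import pandas as pd
import pytest

from statincea.strategies import (
    STRATEGY_AGE_BANDS,
    StrategyDef,
    calibrate_to_count,
    eligibility_summary,
    eligible,
    weighted_quantile,
)


def toy_cohort(risks, ages=None, weights=None):
    n = len(risks)
    return pd.DataFrame(
        {
            "age": ages if ages is not None else [50.0] * n,
            "weight": weights if weights is not None else [1.0] * n,
        }
    )


class TestEligible:
    def test_threshold_is_inclusive(self):
        cohort = toy_cohort([0.0])
        s = StrategyDef("fixed_risk", 0.20)
        assert eligible(s, cohort, risk=np.array([0.20]))[0]
        assert not eligible(s, cohort, risk=np.array([0.1999]))[0]

    def test_zero_threshold_treats_everyone(self):
        cohort = toy_cohort([0] * 5)
        s = StrategyDef("fixed_risk", 0.0)
        assert eligible(s, cohort, risk=np.random.default_rng(0).random(5)).all()

    def test_none_family_treats_nobody(self):
        cohort = toy_cohort([0] * 5)
        assert not eligible(StrategyDef("none"), cohort, risk=np.ones(5)).any()

    def test_age_stratified_uses_band_threshold(self):
        thr = [0.5] * len(STRATEGY_AGE_BANDS)
        thr[0] = 0.1  # 40-44 band
        s = StrategyDef("age_stratified", tuple(thr))
        cohort = toy_cohort([0, 0], ages=[42.0, 60.0])
        out = eligible(s, cohort, risk=np.array([0.2, 0.2]))
        assert out[0] and not out[1]

    def test_age_below_bands_rejected(self):
        s = StrategyDef("age_stratified", tuple([0.1] * len(STRATEGY_AGE_BANDS)))
        with pytest.raises(ValueError):
            eligible(s, toy_cohort([0], ages=[30.0]), risk=np.array([0.5]))

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            StrategyDef("quantum", 0.1)


class TestCalibration:
    def test_target_equal_total_weight_gives_zero_threshold(self):
        risks = np.linspace(0.01, 0.5, 10)
        cohort = toy_cohort(risks)
        s = calibrate_to_count("fixed_risk", cohort, 10.0, risk=risks)
        assert s.threshold == 0.0
        assert eligible(s, cohort, risk=risks).all()

    def test_toy_threshold_matches_brute_force(self):
        rng = np.random.default_rng(4)
        risks = rng.permutation(np.linspace(0.05, 0.50, 10))
        cohort = toy_cohort(risks)
        s = calibrate_to_count("fixed_risk", cohort, 3.0, risk=risks)
        # brute force: try every observed risk as an inclusive threshold
        best = min(
            list(risks) + [0.0],
            key=lambda t: abs((risks >= t).sum() - 3),
        )
        assert eligible(s, cohort, risk=risks).sum() == (risks >= best).sum() == 3
        assert s.threshold == pytest.approx(np.sort(risks)[-3])

    def test_weighted_calibration_respects_expansion_weights(self):
        risks = np.array([0.4, 0.3, 0.2, 0.1])
        weights = np.array([10.0, 1.0, 1.0, 1.0])
        cohort = toy_cohort(risks, weights=weights)
        s = calibrate_to_count("fixed_risk", cohort, 10.0, risk=risks)
        elig = eligible(s, cohort, risk=risks)
        assert weights[elig].sum() == pytest.approx(10.0)

    def test_unattainable_target_sets_warning(self):
        risks = np.array([0.3, 0.3, 0.3, 0.3])
        cohort = toy_cohort(risks)
        s = calibrate_to_count("fixed_risk", cohort, 2.0, risk=risks, tol_frac=0.005)
        assert s.warning is not None

    def test_target_above_total_weight_rejected(self):
        risks = np.array([0.1, 0.2])
        with pytest.raises(ValueError):
            calibrate_to_count("fixed_risk", toy_cohort(risks), 5.0, risk=risks)

    def test_age_stratified_hits_target_within_half_percent(self):
        rng = np.random.default_rng(7)
        n = 5000
        ages = rng.uniform(40, 90, n)
        risks = np.clip(0.005 * (ages - 35) + rng.normal(0, 0.05, n), 0.001, 0.95)
        cohort = toy_cohort(risks, ages=ages, weights=rng.lognormal(0, 0.3, n))
        total = cohort["weight"].sum()
        target = 0.3 * total
        s = calibrate_to_count("age_stratified", cohort, target, risk=risks)
        achieved = cohort["weight"][eligible(s, cohort, risk=risks)].sum()
        assert abs(achieved - target) <= 0.005 * total
        assert s.warning is None

    def test_monotone_nesting_in_threshold(self):
        rng = np.random.default_rng(1)
        risks = rng.random(200)
        cohort = toy_cohort(risks)
        prev = None
        for thr in (0.8, 0.6, 0.4, 0.2, 0.0):
            cur = set(np.nonzero(eligible(StrategyDef("fixed_risk", thr), cohort, risk=risks))[0])
            if prev is not None:
                assert prev <= cur
            prev = cur


class TestQualitativeShifts:
    """Count-matched alternatives re-target treatment as intended."""

    @pytest.fixture(scope="class")
    @staticmethod
    def scored_cohort():
        from statincea.cohort import preprocess
        from statincea.defaults import (
            default_cohort_spec,
            default_survival_params,
            default_treatment_params,
        )
        from statincea.evaluate import profile_scores

        cohort, _, _ = preprocess(default_cohort_spec(n=4000, seed=3))
        scores = profile_scores(
            cohort, default_survival_params(), default_treatment_params()
        )
        return cohort, scores

    def test_age_stratified_treats_younger(self, scored_cohort):
        cohort, scores = scored_cohort
        risk = scores["risk10"].to_numpy()
        w = cohort["weight"].to_numpy()
        ref = StrategyDef("fixed_risk", 0.20)
        target = w[eligible(ref, cohort, risk=risk)].sum()
        alt = calibrate_to_count("age_stratified", cohort, target, risk=risk)
        e_ref = eligible(ref, cohort, risk=risk)
        e_alt = eligible(alt, cohort, risk=risk)
        mean_age = lambda m: np.average(cohort["age"][m], weights=w[m])
        assert mean_age(e_alt) <= mean_age(e_ref)

    def test_arr_treats_higher_nonhdl(self, scored_cohort):
        cohort, scores = scored_cohort
        risk, arr = scores["risk10"].to_numpy(), scores["arr"].to_numpy()
        w = cohort["weight"].to_numpy()
        ref = StrategyDef("fixed_risk", 0.20)
        target = w[eligible(ref, cohort, risk=risk)].sum()
        alt = calibrate_to_count("arr", cohort, target, arr=arr)
        e_ref = eligible(ref, cohort, risk=risk)
        e_alt = eligible(alt, cohort, arr=arr)
        nonhdl = scores["nonhdl"].to_numpy()
        assert np.average(nonhdl[e_alt], weights=w[e_alt]) >= np.average(
            nonhdl[e_ref], weights=w[e_ref]
        )


class TestEligibilitySummary:
    def test_none_strategy_all_zero(self):
        cohort = toy_cohort([0] * 10, ages=np.linspace(41, 85, 10))
        tbl = eligibility_summary(StrategyDef("none"), cohort, risk=np.ones(10))
        assert (tbl["pct_eligible"] == 0).all()

    def test_zero_threshold_all_hundred(self):
        cohort = toy_cohort([0] * 10, ages=np.linspace(41, 85, 10))
        tbl = eligibility_summary(StrategyDef("fixed_risk", 0.0), cohort, risk=np.ones(10))
        occupied = tbl[tbl["total_weight"] > 0]
        assert (occupied["pct_eligible"] == 100.0).all()

    def test_matches_hand_count_on_toy_table(self):
        ages = [42, 43, 47, 52, 57, 62, 67, 72, 77, 82]
        risks = np.array([0.05, 0.25, 0.10, 0.30, 0.15, 0.40, 0.02, 0.22, 0.18, 0.50])
        cohort = toy_cohort(risks, ages=[float(a) for a in ages])
        tbl = eligibility_summary(StrategyDef("fixed_risk", 0.20), cohort, risk=risks).set_index("age_band")
        # hand count: eligible risks >= 0.20 are rows 1,3,5,7,9
        assert tbl.loc["all", "eligible_weight"] == 5
        assert tbl.loc["40-44", "eligible_weight"] == 1  # ages 42,43 -> risk 0.25 only
        assert tbl.loc["40-44", "pct_eligible"] == pytest.approx(50.0)
        assert tbl.loc["65-69", "eligible_weight"] == 0


def test_weighted_quantile_reduces_to_order_statistics():
    v = np.array([3.0, 1.0, 2.0])
    w = np.ones(3)
    assert weighted_quantile(v, w, 1 / 3) == 1.0
    assert weighted_quantile(v, w, 1.0) == 3.0
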