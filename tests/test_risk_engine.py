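"""Multistate engine: hazards, 10-year risk, and the lifetime expectation."""

import numpy as np
import pandas as pd
import pytest

from statincea.health_econ import EconParams
from statincea.risk_engine import (
    CauseModel,
    GompertzHazard,
    SurvivalParams,
    annual_transition_probs,
    linear_predictor,
    simulate_cohort,
    simulate_lifetime,
    ten_year_risk,
)
from statincea.states import CAUSES, HealthState
from statincea.treatment import TreatmentParams

from conftest import constant_hazard_params, flat_econ

STATE_COLS = [s.name for s in HealthState]


def toy_params(coeffs):
    return SurvivalParams(
        causes={
            c: CauseModel(GompertzHazard(0.01, 0.0), coefficients=dict(coeffs))
            for c in CAUSES
        },
        post_event_mortality={"chd": GompertzHazard(0.05, 0.0), "cbvd": GompertzHazard(0.05, 0.0)},
    )


class TestLinearPredictor:
    def test_zero_coefficients_give_zero(self, profile):
        assert linear_predictor(profile, "nonfatal_chd", toy_params({})) == 0.0

    def test_hand_computed_dot_product(self, profile):
        params = toy_params({"sbp": 0.01, "cpd": 0.02, "male": 0.4})
        expected = 0.01 * 140.0 + 0.02 * 10.0 + 0.4 * 1.0
        assert linear_predictor(profile, "nonfatal_chd", params) == pytest.approx(expected)

    def test_doubling_a_coefficient_doubles_its_contribution(self, profile):
        base = linear_predictor(profile, "nonfatal_chd", toy_params({"sbp": 0.01}))
        double = linear_predictor(profile, "nonfatal_chd", toy_params({"sbp": 0.02}))
        assert double == pytest.approx(2 * base)

    def test_missing_covariate_raises(self, profile):
        bad = profile.drop("sbp")
        with pytest.raises((KeyError, ValueError)):
            linear_predictor(bad, "nonfatal_chd", toy_params({"sbp": 0.01}))


class TestTenYearRisk:
    def test_zero_cvd_hazards_give_zero_risk(self, profile):
        params = constant_hazard_params(h_noncvd=0.02)
        assert ten_year_risk(profile, params) == pytest.approx(0.0)

    def test_dominant_competing_risk_absorbs(self, profile):
        params = constant_hazard_params(h_chd=0.01, h_noncvd=50.0)
        assert ten_year_risk(profile, params) < 1e-3

    def test_constant_hazard_closed_form(self, profile):
        # CIF_cvd(10) = h_cvd/(h_cvd+h_other) * (1 - exp(-10*(h_cvd+h_other)))
        params = constant_hazard_params(h_chd=0.02, h_noncvd=0.01)
        expected = (0.02 / 0.03) * (1.0 - np.exp(-0.3))
        assert ten_year_risk(profile, params) == pytest.approx(expected, rel=1e-12)

    def test_risk_increases_with_positive_coefficient(self, profile, surv_params):
        hotter = profile.copy()
        hotter["sbp"] += 30.0
        assert ten_year_risk(hotter, surv_params) > ten_year_risk(profile, surv_params)


class TestAnnualTransitions:
    def test_zero_hazards_stay_put(self, profile):
        probs = annual_transition_probs(profile, 50.0, HealthState.CVD_FREE, constant_hazard_params())
        assert probs[HealthState.CVD_FREE] == pytest.approx(1.0)

    def test_probabilities_sum_to_one_random_params(self, profile):
        rng = np.random.default_rng(3)
        for _ in range(25):
            h = rng.uniform(0.0, 0.3, size=4)
            params = constant_hazard_params(*h, h_post=rng.uniform(0, 0.5))
            for state in (HealthState.CVD_FREE, HealthState.CHRONIC_CHD, HealthState.CHRONIC_CBVD):
                probs = annual_transition_probs(profile, 60.0, state, params)
                assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)
                assert all(p >= 0 for p in probs.values())

    def test_single_cause_exponential_exit(self, profile):
        h = 0.07
        params = constant_hazard_params(h_chd=h)
        probs = annual_transition_probs(profile, 50.0, HealthState.CVD_FREE, params)
        assert probs[HealthState.CHRONIC_CHD] == pytest.approx(1 - np.exp(-h))

    def test_absorbing_state_rejected(self, profile):
        with pytest.raises(ValueError):
            annual_transition_probs(profile, 50.0, HealthState.DEAD_CVD, constant_hazard_params())

    def test_beyond_max_age_forces_death(self, profile):
        probs = annual_transition_probs(profile, 111.0, HealthState.CVD_FREE, constant_hazard_params())
        assert probs == {HealthState.DEAD_NONCVD: 1.0}


def matrix_chain_oracle(h, h_post, age0, max_age, utility, rate, n_states=6):
    """Independent evaluation by explicit transition-matrix products."""
    P = np.zeros((6, 6))
    H = sum(h.values())
    p_exit = 1 - np.exp(-H)
    share = {c: (h[c] / H if H > 0 else 0.0) for c in h}
    P[0, 0] = 1 - p_exit
    P[0, 1] = share["nonfatal_chd"] * p_exit
    P[0, 2] = share["nonfatal_cbvd"] * p_exit
    P[0, 3] = share["fatal_cvd"] * p_exit
    P[0, 4] = share["fatal_noncvd"] * p_exit
    p_die = 1 - np.exp(-h_post)
    for s in (1, 2):
        P[s, s] = 1 - p_die
        P[s, 5] = p_die
    for s in (3, 4, 5):
        P[s, s] = 1.0
    occ = np.zeros(6)
    occ[0] = 1.0
    qalys = life_years = 0.0
    u = np.array([utility, utility, utility, 0, 0, 0])
    for t in range(int(max_age - age0)):
        qalys += (occ @ u) / (1 + rate) ** t
        life_years += occ[:3].sum()
        occ = occ @ P
    return qalys, life_years


class TestSimulateLifetime:
    def test_zero_hazards_full_lifespan(self, profile):
        out = simulate_lifetime(
            profile, constant_hazard_params(), flat_econ(utility=1.0, rate=0.0), half_cycle=False
        )
        assert out.life_years == pytest.approx(110 - 55)
        assert out.qalys == pytest.approx(110 - 55)

    @pytest.mark.parametrize("rate", [0.0, 0.035])
    def test_matches_matrix_chain_oracle(self, profile, rate):
        h = {"nonfatal_chd": 0.02, "nonfatal_cbvd": 0.01, "fatal_cvd": 0.008, "fatal_noncvd": 0.03}
        params = constant_hazard_params(*h.values(), h_post=0.09)
        out = simulate_lifetime(profile, params, flat_econ(utility=0.8, rate=rate), half_cycle=False)
        q_exp, ly_exp = matrix_chain_oracle(h, 0.09, 55.0, 110.0, 0.8, rate)
        assert out.qalys == pytest.approx(q_exp, rel=1e-6)
        assert out.life_years == pytest.approx(ly_exp, rel=1e-6)

    def test_occupancy_conserved_every_cycle(self, profile, surv_params, econ_params):
        out = simulate_lifetime(profile, surv_params, econ_params, record_trajectory=True)
        total = out.trajectory[STATE_COLS].sum(axis=1)
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_null_treatment_effect_costs_only(self, profile, surv_params):
        econ = flat_econ(utility=0.9, rate=0.035)
        null = TreatmentParams(
            nonhdl_reduction=0.0, rr_nonfatal_chd=1.0, rr_nonfatal_cbvd=1.0,
            rr_fatal_cvd=1.0, diabetes_abs_risk_increase=0.0, pill_disutility=0.0,
            annual_drug_cost=5.0,
        )
        untreated = simulate_lifetime(profile, surv_params, econ, scenario="untreated")
        treated = simulate_lifetime(profile, surv_params, econ, null, scenario="treated")
        assert treated.qalys == pytest.approx(untreated.qalys, rel=1e-12)
        assert treated.life_years == pytest.approx(untreated.life_years, rel=1e-12)
        assert treated.costs["statin"] > untreated.costs["statin"]
        for cat in ("cvd", "noncvd", "screening"):
            assert treated.costs[cat] == pytest.approx(untreated.costs[cat], rel=1e-12)

    def test_higher_hazard_lowers_life_expectancy(self, profile):
        econ = flat_econ()
        lo = simulate_lifetime(profile, constant_hazard_params(h_noncvd=0.02), econ)
        hi = simulate_lifetime(profile, constant_hazard_params(h_noncvd=0.04), econ)
        assert hi.life_years < lo.life_years

    def test_treatment_reduces_composite_cvd_and_gains_qalys(
        self, profile, surv_params, econ_params, treat_params
    ):
        # cause-specific lifetime risks can shift either way under
        # competing risks (longer life = longer exposure), but the
        # composite lifetime CVD probability, QALYs and life-years all
        # move the right way
        un = simulate_lifetime(profile, surv_params, econ_params, scenario="untreated")
        tr = simulate_lifetime(profile, surv_params, econ_params, treat_params, scenario="treated")
        cvd = lambda o: sum(o.event_probs[c] for c in ("nonfatal_chd", "nonfatal_cbvd", "fatal_cvd"))
        assert cvd(tr) < cvd(un)
        assert tr.qalys > un.qalys
        assert tr.life_years > un.life_years

    def test_cohort_and_single_profile_agree(self, small_cohort, surv_params, econ_params):
        sub = small_cohort.head(5)
        batch = simulate_cohort(sub, surv_params, econ_params)
        for i in range(len(sub)):
            single = simulate_lifetime(sub.iloc[i], surv_params, econ_params)
            assert single.qalys == pytest.approx(batch.qalys[i], rel=1e-12)
            assert single.total_cost == pytest.approx(batch.total_cost[i], rel=1e-12)
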