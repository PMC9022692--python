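"""Frontier construction, NMB, CEAC, tornado and population projection."""

import numpy as np
import pandas as pd
import pytest

from statincea.cea import (
    StrategyOutcome,
    ceac,
    icer_frontier,
    nmb,
    project_population,
    tornado,
)


def outcomes_from(pairs):
    return [StrategyOutcome(label=f"s{i}", cost=c, qaly=q) for i, (c, q) in enumerate(pairs)]


def brute_force_frontier(pairs):
    """Independent enumeration: strict dominance filter, then convex-hull walk."""
    items = [(f"s{i}", c, q) for i, (c, q) in enumerate(pairs)]
    nondom = [
        (l, c, q)
        for (l, c, q) in items
        if not any(
            (c2 <= c and q2 >= q and (c2 < c or q2 > q)) for (_, c2, q2) in items
        )
    ]
    nondom.sort(key=lambda x: (x[1], x[2]))
    frontier = [nondom[0]]
    rest = nondom[1:]
    while rest:
        lab, c0, q0 = frontier[-1]
        icers = [((c - c0) / (q - q0), i) for i, (_, c, q) in enumerate(rest)]
        best_icer, best_i = min(icers)
        frontier.append(rest[best_i])
        rest = rest[best_i + 1 :]
    return [l for l, _, _ in frontier]


class TestFrontier:
    def test_strictly_dominated_pair(self):
        out = icer_frontier(outcomes_from([(0.0, 5.0), (10.0, 4.0)]))
        assert out.frontier == ["s0"]
        assert out.dominated["s1"] == "strict"

    def test_worked_four_strategy_example(self):
        # {(0,0), (100,10), (500,12), (400,13)}: (500,12) strictly dominated
        out = icer_frontier(outcomes_from([(0, 0), (100, 10), (500, 12), (400, 13)]))
        assert out.frontier == ["s0", "s1", "s3"]
        assert out.dominated == {"s2": "strict"}
        assert out.icers["s1"] == pytest.approx(10.0)
        assert out.icers["s3"] == pytest.approx(100.0)

    def test_extended_dominance_removal(self):
        # middle strategy has higher ICER than the next step -> extended
        out = icer_frontier(outcomes_from([(0, 0), (100, 1), (120, 3)]))
        assert out.frontier == ["s0", "s2"]
        assert out.dominated["s1"] == "extended"

    def test_agrees_with_enumeration_on_random_sets(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            k = rng.integers(2, 7)
            pairs = [(float(rng.uniform(0, 1000)), float(rng.uniform(0, 10))) for _ in range(k)]
            got = icer_frontier(outcomes_from(pairs))
            assert got.frontier == brute_force_frontier(pairs)
            icers = [v for v in got.icers.values() if not np.isnan(v)]
            assert all(b > a for a, b in zip(icers, icers[1:]))

    def test_adding_dominated_strategy_preserves_frontier(self):
        base = [(0, 0), (100, 10), (400, 13)]
        with_dud = base + [(450, 9.0)]
        a = icer_frontier(outcomes_from(base))
        b = icer_frontier(outcomes_from(with_dud))
        assert a.frontier == b.frontier
        assert [b.icers[l] for l in b.frontier[1:]] == [a.icers[l] for l in a.frontier[1:]]

    def test_exact_ties_flagged(self):
        out = icer_frontier(outcomes_from([(0, 0), (0, 0), (10, 1)]))
        assert out.tied


class TestNmb:
    def test_break_even(self):
        assert nmb(20_000.0, 1.0, 20_000.0) == 0.0

    def test_linearity(self):
        assert nmb(2 * 100.0, 2 * 0.5, 1000.0) == pytest.approx(2 * nmb(100.0, 0.5, 1000.0))

    def test_agrees_with_icer_decision_rule(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            dc, dq = rng.uniform(0, 1000), rng.uniform(0.01, 2.0)
            lam = rng.uniform(0, 2000)
            icer = dc / dq
            prefers_by_nmb = nmb(dc, dq, lam) > 0
            assert prefers_by_nmb == (icer < lam)

    def test_negative_wtp_rejected(self):
        with pytest.raises(ValueError):
            nmb(0.0, 0.0, -1.0)


class TestCeac:
    @staticmethod
    def frame(data):
        rows = []
        for i, per_strategy in enumerate(data):
            for strat, (c, q) in per_strategy.items():
                rows.append({"iteration": i, "strategy": strat, "cost": c, "qaly": q})
        return pd.DataFrame(rows)

    def test_single_strategy_probability_one(self):
        df = self.frame([{"only": (10.0, 1.0)}, {"only": (12.0, 1.1)}])
        out = ceac(df, [0.0, 10_000.0])
        assert (out["p_optimal"] == 1.0).all()

    def test_probabilities_sum_to_one_pointwise(self):
        rng = np.random.default_rng(0)
        df = self.frame(
            [
                {s: (float(rng.uniform(0, 100)), float(rng.uniform(0, 2))) for s in "abc"}
                for _ in range(20)
            ]
        )
        out = ceac(df, np.linspace(0, 50_000, 11))
        sums = out.groupby("wtp")["p_optimal"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_hand_computed_two_strategy_curve(self):
        # strategy b costs 100 more; QALY gains (2, 1, 0.5, 0.25).
        # At λ=100: b wins iteration 1 (NMB 100 vs 0), ties iteration 2
        # (split 0.5), loses the rest -> (1 + 0.5)/4 = 0.375.
        # At λ=400: wins 3, ties the gain-0.25 iteration -> 0.875.
        df = self.frame(
            [
                {"a": (0.0, 0.0), "b": (100.0, 2.0)},
                {"a": (0.0, 0.0), "b": (100.0, 1.0)},
                {"a": (0.0, 0.0), "b": (100.0, 0.5)},
                {"a": (0.0, 0.0), "b": (100.0, 0.25)},
            ]
        )
        out = ceac(df, [100.0]).set_index("strategy")
        assert out.loc["b", "p_optimal"] == pytest.approx(0.375)
        out400 = ceac(df, [400.0]).set_index("strategy")
        assert out400.loc["b", "p_optimal"] == pytest.approx(0.875)

    def test_nmb_ties_split_equally(self):
        df = self.frame([{"a": (0.0, 1.0), "b": (0.0, 1.0)}, {"a": (0.0, 1.0), "b": (0.0, 1.0)}])
        out = ceac(df, [10_000.0]).set_index("strategy")
        assert out.loc["a", "p_optimal"] == pytest.approx(0.5)


class TestTornado:
    @staticmethod
    def evaluator(base):
        def evaluate(overrides):
            v = {**base, **overrides}
            # toy incremental model: cost rises with drug price, QALYs
            # fall with disutility
            return 100.0 + 10.0 * v["drug"], 1.0 - 5.0 * v["disutility"]

        return evaluate

    def test_degenerate_bounds_zero_width(self):
        base = {"drug": 13.44, "disutility": 0.002}
        out = tornado(self.evaluator(base), base, {"drug": (13.44, 13.44)}, 20_000.0)
        assert out.loc[0, "width"] == 0.0

    def test_widths_match_one_at_a_time_reruns(self):
        base = {"drug": 13.44, "disutility": 0.002}
        bounds = {"drug": (10.0, 40.0), "disutility": (0.0, 0.008)}
        ev = self.evaluator(base)
        out = tornado(ev, base, bounds, 20_000.0).set_index("measure")
        for m, (lo, hi) in bounds.items():
            nmb_lo = nmb(*ev({m: lo}), 20_000.0)
            nmb_hi = nmb(*ev({m: hi}), 20_000.0)
            assert out.loc[m, "width"] == pytest.approx(abs(nmb_hi - nmb_lo))
        assert out["width"].is_monotonic_decreasing

    def test_higher_drug_cost_lowers_nmb(self):
        base = {"drug": 13.44, "disutility": 0.002}
        out = tornado(self.evaluator(base), base, {"drug": (10.0, 40.0)}, 20_000.0).iloc[0]
        assert out["nmb_at_hi"] < out["nmb_at_lo"]

    def test_unknown_measure_rejected(self):
        base = {"drug": 13.44}
        with pytest.raises(KeyError):
            tornado(self.evaluator({**base, "disutility": 0}), base, {"price": (0, 1)}, 100.0)


class TestProjection:
    def test_zero_population_zero_totals(self):
        sim = pd.DataFrame({"age_band": ["40-49", "50-59"], "qaly_gain": [0.1, 0.2]})
        totals = project_population(sim, {"40-49": 0, "50-59": 0}, {"40-49": 0.9, "50-59": 0.8})
        assert totals["qaly_gain"] == 0.0

    def test_single_band_arithmetic(self):
        sim = pd.DataFrame({"age_band": ["40-49"], "qaly_gain": [0.1]})
        totals = project_population(sim, {"40-49": 1000}, {"40-49": 1.0})
        assert totals["qaly_gain"] == pytest.approx(100.0)

    def test_three_band_hand_computation(self):
        sim = pd.DataFrame(
            {"age_band": ["a", "b", "c"], "events_prevented": [0.01, 0.02, 0.03]}
        )
        pop = {"a": 1000, "b": 2000, "c": 500}
        free = {"a": 0.9, "b": 0.8, "c": 0.7}
        totals = project_population(sim, pop, free)
        expected = 0.01 * 1000 * 0.9 + 0.02 * 2000 * 0.8 + 0.03 * 500 * 0.7
        assert totals["events_prevented"] == pytest.approx(expected)

    def test_misaligned_bands_rejected(self):
        sim = pd.DataFrame({"age_band": ["a"], "x": [1.0]})
        with pytest.raises(ValueError):
            project_population(sim, {"b": 10}, {"b": 1.0})
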