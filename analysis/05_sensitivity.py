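#!/usr/bin/env python
"""One-way and scenario sensitivity analyses.

Builds tornado tables (NMB change between each measure's low and high
bound) for the 20%- and 10%-tier ARR-vs-fixed-risk comparisons, then
runs the adherence, diabetes-exclusion, pill-disutility-sweep and
threshold-sweep scenarios.
"""

from _common import N, RESULTS, SEED, WTP, base_params, load_or_build_cohort

from statincea.cea import tornado
from statincea.defaults import default_tornado_bounds
from statincea.evaluate import build_strategies, profile_scores
from statincea.pipeline import _incremental_evaluator, scenario_runner


def main():
    RESULTS.mkdir(exist_ok=True)
    cohort = load_or_build_cohort()
    surv, econ, treat = base_params()
    scores = profile_scores(cohort, surv, treat)
    strategy_set = build_strategies(cohort, scores)

    bounds = default_tornado_bounds()
    base_values = {
        **{k: getattr(treat, k) for k in (
            "nonhdl_reduction", "rr_nonfatal_chd", "rr_nonfatal_cbvd",
            "rr_fatal_cvd", "pill_disutility", "diabetes_abs_risk_increase",
            "annual_drug_cost",
        )},
        "monitoring_cost": econ.monitoring_cost,
        "discount_rate": econ.discount_rate,
    }
    for pair, tag in ((("none", "arr_20"), "arr20"), (("assign_10", "arr_10"), "arr10")):
        ev = _incremental_evaluator(cohort, strategy_set, scores, surv, econ, treat, pair)
        tbl = tornado(ev, base_values, bounds, WTP)
        tbl.to_csv(RESULTS / f"tornado_{tag}.csv", index=False)
        top = tbl.iloc[0]
        print(
            f"Tornado {pair[1]} vs {pair[0]}: widest bar {top['measure']} "
            f"(NMB swing £{top['width']:.1f} per person)"
        )

    cfg = {"n": N, "seed": SEED}
    for scen in ("adherence", "exclude_diabetes", "pill_disutility_sweep", "threshold_sweep"):
        res = scenario_runner(cfg, scen, output_dir=RESULTS)
        if scen == "adherence":
            tbl = res["outcomes"].set_index("strategy")
            gain = tbl.loc["arr_10", "qaly"] - tbl.loc["none", "qaly"]
            print(f"Adherence scenario: arr_10 QALY gain {1000 * gain:.1f}/1000 persons (reduced persistence).")
        elif scen == "pill_disutility_sweep":
            piv = res["sweep"].pivot(index="pill_disutility", columns="strategy", values="nmb")
            cross = piv[piv["arr_20"] > piv["arr_10"]]
            if len(cross):
                print(f"Pill-disutility sweep: arr_20 overtakes arr_10 at disutility {cross.index[0]:.3f}.")
            else:
                print("Pill-disutility sweep: arr_10 retains the higher NMB across the grid.")
        elif scen == "threshold_sweep":
            print("Threshold sweep written (20% down to treat-all in 1% steps).")
    print("Wrote tornado and scenario tables under results/")


if __name__ == "__main__":
    main()
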