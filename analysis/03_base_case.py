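#!/usr/bin/env python
"""Deterministic base-case lifetime outcomes and the cost-effectiveness frontier.

Simulates expected lifetime QALYs and disaggregated health-sector costs
for every profile, untreated and treated, and aggregates them under each
policy.  Applies standard dominance rules to report the efficiency
frontier and pairwise ICERs.
"""

import json

import numpy as np

from _common import RESULTS, base_params, load_or_build_cohort

from statincea.cea import StrategyOutcome, icer_frontier
from statincea.evaluate import (
    build_strategies,
    component_outcomes,
    profile_scores,
    strategy_outcomes,
)


def main():
    RESULTS.mkdir(exist_ok=True)
    cohort = load_or_build_cohort()
    surv, econ, treat = base_params()
    scores = profile_scores(cohort, surv, treat)
    strategy_set = build_strategies(cohort, scores)
    comps = component_outcomes(cohort, surv, econ, treat)
    base = strategy_outcomes(cohort, strategy_set, scores, comps)
    base.to_csv(RESULTS / "base_case.csv", index=False)

    tbl = base.set_index("strategy")
    gain = (tbl["qaly"] - tbl.loc["none", "qaly"]) * 1000
    dcost = tbl["cost"] - tbl.loc["none", "cost"]
    print("Per 1,000 weighted persons vs no treatment:")
    for s in tbl.index:
        if s == "none":
            continue
        print(
            f"  {s:10s}: +{gain[s]:7.1f} QALYs, +£{1000 * dcost[s]:>10.0f}, "
            f"CVD events {1000 * tbl.loc[s, 'cvd_events']:.1f}/1000 "
            f"(vs {1000 * tbl.loc['none', 'cvd_events']:.1f} untreated)"
        )

    outcomes = [
        StrategyOutcome(label=s, cost=float(tbl.loc[s, "cost"]), qaly=float(tbl.loc[s, "qaly"]))
        for s in tbl.index
    ]
    fr = icer_frontier(outcomes)
    (RESULTS / "frontier_base.json").write_text(
        json.dumps(
            {
                "frontier": fr.frontier,
                "icers": {k: (None if np.isnan(v) else round(v)) for k, v in fr.icers.items()},
                "dominated": fr.dominated,
            },
            indent=2,
        )
    )
    print(f"Efficiency frontier: {' -> '.join(fr.frontier)}")
    for s in fr.frontier[1:]:
        print(f"  ICER {s}: £{fr.icers[s]:,.0f}/QALY")
    for s, kind in fr.dominated.items():
        print(f"  {s}: {kind}ly dominated")
    print("Wrote results/base_case.csv and frontier_base.json")


if __name__ == "__main__":
    main()
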