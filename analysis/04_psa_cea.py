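#!/usr/bin/env python
"""Probabilistic sensitivity analysis and cost-effectiveness acceptability.

Propagates parameter uncertainty (treatment measures and correlated
lipid log-hazard-ratios) through the lifetime model in independent
iterations, summarizes strategy results with percentile intervals,
recomputes the frontier from PSA means, and traces acceptability curves
over willingness-to-pay £0–£50,000/QALY.
"""

import json

import numpy as np

from _common import PSA_ITERATIONS, RESULTS, SEED, WTP, base_params, load_or_build_cohort

from statincea.cea import StrategyOutcome, ceac, icer_frontier
from statincea.defaults import default_psa_distributions
from statincea.evaluate import build_strategies, profile_scores, run_psa
from statincea.psa import summarize_psa


def main():
    RESULTS.mkdir(exist_ok=True)
    cohort = load_or_build_cohort()
    surv, econ, treat = base_params()
    scores = profile_scores(cohort, surv, treat)
    strategy_set = build_strategies(cohort, scores)

    psa_raw = run_psa(
        cohort, strategy_set, scores, surv, econ, treat,
        default_psa_distributions(), PSA_ITERATIONS, SEED,
    )
    psa_raw.to_csv(RESULTS / "psa_raw.csv", index=False)
    summary = summarize_psa(psa_raw, reference="none")
    summary.to_csv(RESULTS / "psa_summary.csv", index=False)

    means = psa_raw.groupby("strategy")[["cost", "qaly"]].mean()
    fr = icer_frontier(
        [StrategyOutcome(s, float(r["cost"]), float(r["qaly"])) for s, r in means.iterrows()]
    )
    (RESULTS / "frontier_psa.json").write_text(
        json.dumps(
            {
                "frontier": fr.frontier,
                "icers": {k: (None if np.isnan(v) else round(v)) for k, v in fr.icers.items()},
                "dominated": fr.dominated,
            },
            indent=2,
        )
    )

    grid = np.arange(0.0, 50_000.0 + 1e-9, 500.0)
    curves = ceac(psa_raw, grid)
    curves.to_csv(RESULTS / "ceac.csv", index=False)

    print(f"{PSA_ITERATIONS} PSA iterations on {len(cohort)} profiles (seed {SEED}).")
    print(f"Frontier from PSA means: {' -> '.join(fr.frontier)}")
    for s in fr.frontier[1:]:
        print(f"  ICER {s}: £{fr.icers[s]:,.0f}/QALY")
    at_wtp = curves[np.isclose(curves["wtp"], WTP)].set_index("strategy")["p_optimal"]
    best = at_wtp.idxmax()
    print(
        f"At £{WTP:,.0f}/QALY, {best} is optimal in {100 * at_wtp[best]:.0f}% of iterations."
    )
    print("Wrote results/psa_raw.csv, psa_summary.csv, frontier_psa.json, ceac.csv")


if __name__ == "__main__":
    main()
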