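#!/usr/bin/env python
"""Score every profile and calibrate the six statin policies.

Computes each profile's 10-year CVD risk (competing-risk cumulative
incidence) and expected 10-year ARR from statin therapy, then builds
the policy set: fixed risk thresholds at 20% and 10%, and age-stratified
and ARR policies calibrated to treat the same weighted head count.
Writes scores, strategy definitions and eligibility tables.
"""

import json

import pandas as pd

from _common import RESULTS, base_params, load_or_build_cohort

from statincea.evaluate import build_strategies, profile_scores
from statincea.strategies import eligibility_summary


def main():
    RESULTS.mkdir(exist_ok=True)
    cohort = load_or_build_cohort()
    surv, econ, treat = base_params()
    scores = profile_scores(cohort, surv, treat)
    scores.to_csv(RESULTS / "scores.csv", index=False)

    strategy_set = build_strategies(cohort, scores)
    defs = [
        {
            "label": s.label,
            "family": s.family,
            "threshold": s.threshold if not isinstance(s.threshold, tuple) else list(s.threshold),
            "warning": s.warning,
        }
        for s in strategy_set.values()
    ]
    (RESULTS / "strategies.json").write_text(json.dumps(defs, indent=2))

    risk = scores["risk10"].to_numpy()
    arr = scores["arr"].to_numpy()
    tables = pd.concat(
        [eligibility_summary(s, cohort, risk, arr) for s in strategy_set.values()],
        ignore_index=True,
    )
    tables.to_csv(RESULTS / "eligibility.csv", index=False)

    print(f"Median 10-year risk {scores['risk10'].median():.3f}; median ARR {scores['arr'].median():.4f}.")
    overall = tables[tables["age_band"] == "all"].set_index("strategy")["pct_eligible"]
    print("Eligibility (% of weighted cohort):")
    print(overall.round(1).to_string())
    w = cohort["weight"].to_numpy()
    for pct in (20, 10):
        from statincea.strategies import eligible

        e_fix = eligible(strategy_set[f"assign_{pct}"], cohort, risk=risk)
        e_age = eligible(strategy_set[f"age_{pct}"], cohort, risk=risk)
        e_arr = eligible(strategy_set[f"arr_{pct}"], cohort, arr=arr)
        import numpy as np

        print(
            f"At the {pct}% tier: mean age of treated {np.average(cohort['age'][e_fix], weights=w[e_fix]):.1f} (fixed) "
            f"vs {np.average(cohort['age'][e_age], weights=w[e_age]):.1f} (age-stratified); "
            f"mean non-HDL-C {np.average(scores['nonhdl'][e_fix], weights=w[e_fix]):.2f} (fixed) "
            f"vs {np.average(scores['nonhdl'][e_arr], weights=w[e_arr]):.2f} mmol/L (ARR)."
        )
    print("Wrote results/scores.csv, strategies.json, eligibility.csv")


if __name__ == "__main__":
    main()
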