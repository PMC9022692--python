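# statincea

Cost-effectiveness modelling of statin prioritization strategies for the
primary prevention of cardiovascular disease (CVD).

Most guidelines prioritize preventive statin therapy by a 10-year CVD
risk threshold (e.g. an ASSIGN score ≥ 20% or ≥ 10%). Two alternatives
have been proposed: **age-stratified risk thresholds**, which treat
people at high risk relative to their age-group peers, and **absolute
risk reduction (ARR)–guided therapy**, which combines 10-year risk with
baseline cholesterol, since the relative risk reduction (RRR) from
statins is roughly constant per 1.0 mmol/L of lipid lowering and so is
larger for patients with more cholesterol to lose. This package
implements a full decision-analytic pipeline for comparing such
policies on lifetime quality-adjusted life-years (QALYs) and
health-sector costs: a competing-risk multistate cohort simulator, the
ARR prioritization equation, count-matched strategy calibration,
probabilistic sensitivity analysis (PSA) and standard
cost-effectiveness decision rules. A synthetic survey-cohort generator
stands in for confidential health-survey microdata, and the shipped
survival/cost parameters are synthetic, UK-plausible values — real
fitted parameters can be supplied through the same YAML configuration
surface.

## The model in brief

**Multistate engine.** Individuals enter CVD-free and face four
competing cause-specific hazards — nonfatal CHD, nonfatal
cerebrovascular disease (CBVD), fatal CVD, fatal non-CVD — each a
Gompertz baseline in age times a proportional-hazards term over the
ASSIGN risk factors (age, sex, diabetes, SBP, TC, HDL-C,
cigarettes/day, deprivation, family history). Within a one-year cycle,
`P(event c) = (h_c/Σh)(1 − e^(−Σh))`. Survivors of a nonfatal event
occupy a chronic state with elevated all-cause mortality. Outcomes are
exact expectations over the state distribution (cohort method), with
annual cycles to age 110, half-cycle correction, 3.5%/year discounting
and a 12.5% uplift of 2014-based costs to 2020 GBP.

**Treatment.** Moderate-intensity statins reduce non-HDL-C by 26% and
carry relative risks 0.77 / 0.87 / 0.90 per 1.0 mmol/L non-HDL-C
reduction for nonfatal CHD, nonfatal stroke and fatal CVD, so the
per-cause hazard multiplier for a patient with non-HDL-C level `x` is
`rr_c^(0.26·x)`. Side effects: +0.5% absolute diabetes risk (costed) and
a 0.002 QALY/year pill-taking disutility. Drug cost £13.44/year.

**ARR score.** Expected 10-year ARR from therapy is

```
ARR = S_un^x − S_un,   x = HR^(lipid_baseline × reduction)
```

where `S_un` is 10-year untreated CVD-free survival and `HR` the hazard
ratio per 1.0 mmol/L reduction (here the risk-share-weighted geometric
mean of the three cause-specific relative risks, on the non-HDL-C axis
with reduction 0.26).

**Policies.** `assign_20`/`assign_10` treat at fixed 10-year risk ≥
20%/10%; `age_20`/`age_10` and `arr_20`/`arr_10` are calibrated so the
weighted number treated matches the corresponding fixed-risk policy.
Policies are compared by dominance rules (strict and extended), ICERs
along the efficiency frontier, net monetary benefit
(`NMB = λ·QALY − cost`) and cost-effectiveness acceptability curves.

## Worked example

```python
from statincea.treatment import lipid_reduction, rrr_from_lipid_reduction

for ldl in (4.0, 2.0):
    delta = lipid_reduction(ldl, 0.40)          # 40% LDL-C reduction
    rrr = rrr_from_lipid_reduction(delta, 0.78)  # HR 0.78 per mmol/L
    print(f"baseline {ldl} mmol/L: reduction {delta:.1f} mmol/L, RRR {100*rrr:.0f}%")
```

prints

```
baseline 4.0 mmol/L: reduction 1.6 mmol/L, RRR 33%
baseline 2.0 mmol/L: reduction 0.8 mmol/L, RRR 18%
```

— two patients with the same 10-year risk but different cholesterol get
very different relative (and hence absolute) benefit, which is the case
for ARR-guided prioritization.

## Running the analysis

The numbered drivers under `analysis/` run the study end to end on the
default synthetic cohort (10,000 generated records, seed 1):

```
cd analysis
python 01_build_cohort.py        # generate, impute, detreat, exclude
python 02_score_and_calibrate.py # 10-year risk + ARR scores, 6 policies
python 03_base_case.py           # lifetime outcomes, frontier, ICERs
python 04_psa_cea.py             # 200-iteration PSA, CEAC curves
python 05_sensitivity.py         # tornado + adherence/diabetes/sweeps
```

Each writes its tables under `results/`. On the default synthetic
cohort the base-case frontier is `none → arr_20 → arr_10` with ICERs of
roughly £3,400 and £4,500 per QALY: the count-matched ARR policies
deliver more QALYs than the fixed-risk policies of equal reach, and at
high pill-taking disutility (≈0.015 QALY/year) treating fewer people
(`arr_20`) overtakes `arr_10` on net monetary benefit. These numbers
characterize the synthetic study conditions, not any real population.

The same pipeline is available programmatically via
`statincea.pipeline.run_pipeline(config, output_dir)` with a YAML
configuration (see `src/statincea/configs/demo.yaml`).

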