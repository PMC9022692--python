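# Methods

This note documents the model, its parameters, the synthetic data
generator, and the numerical and design choices made where the design
was genuinely open. It states no empirical result that the test suite
and analysis scripts do not themselves compute.

## Multistate competing-risk model

The engine is an expectation-based (cohort) state-transition model with
six states: CVD-free, chronic CHD, chronic CBVD, and three absorbing
death states (fatal CVD as first event, non-CVD death from the CVD-free
state, and post-event all-cause death). From the CVD-free state four
first-event causes compete: nonfatal CHD, nonfatal CBVD, fatal CVD and
fatal non-CVD.

Each cause-specific hazard is a Gompertz baseline in current age,
`h0(a) = rate_ref · exp(γ(a − 60))`, multiplied by
`exp(Σ β_k (x_k − ref_k))` over the ASSIGN-style covariates (sex,
diabetes, SBP, TC, HDL-C, cigarettes/day, SIMD, family history). Age
enters only through the baseline, so linear predictors are computed
once per simulation. Within an annual cycle, competing events are
resolved exactly for constant hazards:
`P(event c) = (h_c/Σh)(1 − exp(−Σh))`. Chronic-state occupants face a
single post-event all-cause Gompertz mortality per state. Secondary CVD
events inside the chronic states are represented as expected annual
utility decrements and costs, not as explicit sub-states. Risk factors
are held at their baseline values for life (no drift), and the horizon
runs to a maximum age of 110: any mass at or beyond that age is
absorbed into death at the start of the cycle, so a zero-hazard profile
lives exactly `110 − age` years.

The 10-year risk score is the model's own cumulative incidence of the
composite CVD endpoint (nonfatal CHD + nonfatal CBVD + fatal CVD) under
the competing risk of non-CVD death, evaluated untreated. The same
engine supplies both the eligibility score and the outcome simulation,
so a policy is judged by the risk measure it screens with.

## Treatment model

Statin therapy lowers non-HDL-C by a proportion (default 0.26) and
multiplies the three CVD cause-specific hazards by `rr_c^δ`, where
`δ = non-HDL-C × reduction` is the absolute lipid reduction achieved
and `rr_c` ∈ {0.77, 0.87, 0.90} per 1.0 mmol/L. Effects, pill
disutility (0.002 QALY/year) and drug/monitoring costs apply while the
individual is CVD-free and on therapy; the one-off +0.5% absolute
diabetes risk at initiation is carried as an expected annual diabetes
management cost while alive. Treatment efficacy, side effects and
monitoring costs accrue to persistent users only.

Adherence is modelled as a mixture over discontinuation times derived
from the persistence schedule (default scenario 67% in year 1, 53% in
year 2, 50% thereafter, interpreted as stop-at-year-boundary): weight
`1 − p₁` never persists and contributes the untreated outcome plus
first-year drug and monitoring costs only; weight `p_k − p_{k+1}` is
treated for k years; weight `p_∞` for life. The base case assumes full
adherence (a single lifetime component).

## ARR prioritization

Expected 10-year ARR is `S_un^x − S_un` with
`x = HR^(lipid_baseline × reduction)`, where `S_un` is 10-year
untreated survival of the composite CVD endpoint. The equation requires
a single hazard ratio per mmol/L, which the treatment model does not
directly provide; we use the geometric mean of the three cause-specific
relative risks weighted by each profile's cause shares of its 10-year
CVD risk. This preserves the single-HR form while reflecting that a
profile dominated by CHD risk benefits more per mmol/L than one
dominated by stroke risk. Whether `S_un` should be composite or
fatal-only survival is configurable; composite is the default, used
consistently with the risk score. Note the ARR curve `S^x − S` is
unimodal in `S` with its maximum near `S ≈ 0.37`; over the clinically
relevant range (10-year risk below ~38%) ARR increases with baseline
risk, and it increases with baseline lipid level everywhere.

## Strategies and calibration

Fixed-risk and ARR policies place one inclusive (≥) threshold on their
score. Age-stratified policies hold one threshold per 5-year band
(40–44 … 75–79, 80+). Count-matching calibrates the alternative
policies to the weighted head count of the reference fixed-risk policy:
scalar families take the best inclusive threshold among observed scores
(weighted); the age-stratified family solves, by bisection, for a
single within-band quantile q — treating the top q of every band by
weight — the only rule consistent with "high risk relative to age-group
peers" plus a count constraint. Tolerance is ±0.5% of total cohort
weight; an unattainable target (mass ties) returns the nearest
attainable threshold with a machine-readable warning. All counts use
survey expansion weights, not raw rows.

## Health economics

Utilities: age/sex background utility bands, minus a chronic-state
decrement and an expected secondary-event decrement in the chronic
states, clipped to [0, 1]; dead states contribute zero. Costs are
health-sector: a one-off screening (risk-assessment) cost at entry for
everyone; annual background non-CVD care while alive (linear in age);
hospitalization costs around a primary nonfatal event predicted by
linear equations in age at event, SIMD and family history — a one-off
"pre-event" cost in the event year and an annual "post-event" cost in
the chronic state; statin drug, monitoring and diabetes-attributable
costs while treated. Because the post-event equation is linear in age
at event, the engine tracks the occupancy-mass-weighted age-at-event
sum per chronic state, which makes the expected cost exact under
proportional within-state mortality (no per-entry-cohort bookkeeping
needed).

Discounting is 3.5%/year with the first cycle undiscounted (t = 0);
either convention is defensible, this one is pinned for
reproducibility. QALYs and recurring costs use a half-cycle correction
(toggleable, and disabled in the oracle tests so the matrix-product
oracle is exact); one-off entry and event-year costs are not
half-cycled. Model costs stated in 2014 GBP are inflated by 12.5% to
2020 prices; the £13.44 drug tariff is already 2020-priced and is not
inflated. The willingness-to-pay reference is £20,000/QALY.

## Synthetic cohort generator

The generator emulates the joint risk-factor structure of a national
health survey of adults, as needed by the pipeline: sex-stratified
multivariate-Gaussian dependence over (SBP, log non-HDL-C, log HDL-C,
SIMD) — parameterizing the lipid axis as (non-HDL-C, HDL-C) enforces
TC > HDL-C by construction; point-mass-inflated cigarettes/day (gamma
among smokers); diabetes, prevalent CVD and statin use with age-graded
prevalence; lognormal survey weights; an under-40 fraction to exercise
the age exclusion. Nurse-visit sparsity is emulated by
missing-at-random masks on TC/HDL-C/SBP (default rates 0.50/0.50/0.40)
plus a 7% block-missing refusal subgroup. Defaults (n = 10,000
generated, ~54% female, mean non-HDL-C ≈ 4.1 mmol/L, statin use rising
from 5% to 35% across age bands) are fixed study conditions, not tuning
knobs.

What it does **not** emulate: real survey design effects and weighting
methodology, nurse-visit selection beyond the single refusal flag,
measurement error, or risk-factor drift. Passing tests therefore
demonstrate internal correctness and qualitative behaviour of the
method under realistic joint structure — not calibration to any real
population; population-scale ICERs and eligible counts from fitted
national data are out of scope by design.

Preprocessing order is fixed and load-bearing: generate → impute →
detreat → exclude. Imputation is stochastic regression (OLS on the
fully observed covariates among complete cases, plus a Gaussian
residual draw); missing cigarettes/famhist/diabetes are never imputed.
Imputed draws outside plausibility bounds (SBP 70–250 mmHg, TC 2–12,
HDL-C 0.4–4 mmol/L) are redrawn up to 100 times then clipped, with
counts logged; the TC > HDL-C ordering is enforced afterwards (logged).
Detreatment divides statin users' non-HDL-C by (1 − 0.26) so the FH
exclusion (TC ≥ 7.5 with family history, or TC ≥ 8.0 mmol/L) is
evaluated on inferred pre-treatment cholesterol; "premature" family
history collapses to the famhist flag since no age cut-off is
available. The refusal subgroup supports m-fold multiple imputation
(non-refusal values held at their single imputation so a zero-refusal
cohort yields m identical completions).

## Probabilistic and one-way sensitivity analysis

PSA samples the treatment/economic measures — beta for proportions and
utilities, gamma for costs, lognormal for relative risks, each
moment-matched to (base, sd) — and the lipid log-hazard-ratios of the
three CVD causes from a multivariate normal with an equicorrelated
(ρ = 0.4) covariance via its Cholesky factor (an eigenvalue factor
backs up the semidefinite case; asymmetric or indefinite input is an
error naming the matrix). Per-iteration generators are seeded
`(master_seed, i)`, so iterations are independent, reproducible and
order-insensitive, and a zero-variance PSA reproduces the deterministic
base case bit-exactly. Strategy thresholds stay at their base-case
calibration across iterations; only outcomes vary. Summaries report
means, the ICER of mean increments (not the mean of ICERs), and
2.5/97.5 percentile intervals via linear interpolation. CEACs split
exact NMB ties equally, so curves sum to one at every λ over the
£0–£50,000 grid (step £500).

The frontier removes strictly dominated strategies, dedupes exactly
tied (cost, QALY) pairs (flagged), then applies extended dominance
until pairwise ICERs increase strictly. A strategy pair with negative
incremental QALYs is reported through dominance flags, never as a
signed ICER. Tornado tables rerun the deterministic model at each
measure's low/high bound holding others at base and report the NMB
swing, widest first.

## Problem sizes and verification

Default analysis conditions: 10,000 generated records (≈7,900
retained), 200 PSA iterations, annual cycles to age 110. The engine is
vectorized across profiles, so a full treated-plus-untreated lifetime
evaluation of the default cohort takes well under a second; the
five analysis scripts complete in a few minutes total.

Verification strategy: constant-hazard configurations are compared to
closed forms (exponential exits, the competing-risk CIF formula) and to
an independent transition-matrix-product oracle at 1e-6 relative
error; occupancy conservation is checked every cycle across random
Gompertz configurations; the frontier is checked against exhaustive
dominance enumeration on random strategy sets; calibration against
brute-force threshold search; imputation by simulate-then-recover under
a planted linear model. Known limitations: no risk-factor drift, no
explicit secondary-event states, chronic-state background utility uses
current age but not time-since-event, and the synthetic parameter
defaults are not fitted to any cohort.
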