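"""End-to-end pipeline orchestration and reproducibility plumbing.

``run_pipeline`` executes the whole chain — synthetic cohort generation
and preprocessing, risk/ARR scoring, strategy calibration, base-case
and probabilistic lifetime simulation, and cost-effectiveness synthesis
— and writes every result table (CSV/JSON) plus a run manifest tying
the outputs to the configuration hash and master seed.  All randomness
flows from the single master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cea import StrategyOutcome, ceac, icer_frontier, nmb
from .cohort import preprocess
from .config import (
    ConfigError,
    cohort_spec_from_config,
    econ_from_config,
    load_config,
    survival_from_config,
    treatment_from_config,
    validate_config,
)
from .defaults import default_psa_distributions
from .evaluate import (
    apply_measure_overrides,
    build_strategies,
    component_outcomes,
    profile_scores,
    run_psa,
    strategy_outcomes,
)
from .psa import summarize_psa
from .strategies import StrategyDef, eligible, eligibility_summary

__all__ = ["RunManifest", "run_pipeline", "scenario_runner"]


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    config_hash: str
    master_seed: int
    version: str
    started: str
    finished: str = ""
    outputs: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def _config_hash(cfg: Mapping[str, Any]) -> str:
    canon = yaml.safe_dump(dict(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, manifest: RunManifest) -> None:
    df.to_csv(path, index=False)
    manifest.outputs.append(path.name)


def run_pipeline(config_path: str | Path | Mapping[str, Any], output_dir: str | Path) -> RunManifest:
    """Run the full analysis described by a configuration; fail fast on errors.

    Emits: the exclusion log, strategy definitions, per-strategy
    eligibility tables, base-case outcomes, the PSA raw draws and
    summary, the frontier and CEAC, and the run manifest.
    """
    if isinstance(config_path, Mapping):
        cfg = dict(config_path)
        validate_config(cfg)
    else:
        cfg = load_config(config_path)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest = RunManifest(
        config_hash=_config_hash(cfg),
        master_seed=seed,
        version=__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    t0 = time.time()
    spec = cohort_spec_from_config(cfg)
    treat = treatment_from_config(cfg)
    econ = econ_from_config(cfg)
    surv = survival_from_config(cfg)
    cohort, excl_log, imp_log = preprocess(spec, treat.nonhdl_reduction)
    (out / "exclusion_log.json").write_text(
        json.dumps(
            {
                **excl_log.to_dict(),
                "imputed": imp_log.n_imputed,
                "truncated": imp_log.n_truncated,
                "lipid_order_fixed": imp_log.n_lipid_order_fixed,
            },
            indent=2,
        )
    )
    manifest.outputs.append("exclusion_log.json")
    _write_csv(cohort, out / "cohort.csv", manifest)
    manifest.stage_seconds["preprocess"] = round(time.time() - t0, 3)

    t0 = time.time()
    scores = profile_scores(cohort, surv, treat)
    thresholds = tuple(cfg.get("risk_thresholds", (0.20, 0.10)))
    strategy_set = build_strategies(cohort, scores, thresholds)
    for sdef in strategy_set.values():
        if sdef.warning:
            manifest.warnings.append(f"{sdef.label}: {sdef.warning}")
    sdefs = pd.DataFrame(
        [
            {
                "label": s.label,
                "family": s.family,
                "threshold": json.dumps(s.threshold if not isinstance(s.threshold, tuple) else list(s.threshold)),
            }
            for s in strategy_set.values()
        ]
    )
    _write_csv(sdefs, out / "strategies.csv", manifest)
    risk = scores["risk10"].to_numpy()
    arr = scores["arr"].to_numpy()
    elig_tables = pd.concat(
        [eligibility_summary(s, cohort, risk, arr) for s in strategy_set.values()],
        ignore_index=True,
    )
    _write_csv(elig_tables, out / "eligibility.csv", manifest)
    manifest.stage_seconds["calibrate"] = round(time.time() - t0, 3)

    t0 = time.time()
    comps = component_outcomes(cohort, surv, econ, treat)
    base = strategy_outcomes(cohort, strategy_set, scores, comps)
    _write_csv(base, out / "base_case.csv", manifest)
    manifest.stage_seconds["base_case"] = round(time.time() - t0, 3)

    t0 = time.time()
    n_iter = int(cfg.get("psa_iterations", 1000))
    psa_raw = run_psa(
        cohort, strategy_set, scores, surv, econ, treat,
        default_psa_distributions(), n_iter, seed,
    )
    _write_csv(psa_raw, out / "psa_raw.csv", manifest)
    psa_summary = summarize_psa(psa_raw, reference="none")
    _write_csv(psa_summary, out / "psa_summary.csv", manifest)
    manifest.stage_seconds["psa"] = round(time.time() - t0, 3)

    t0 = time.time()
    # frontier over PSA means ("base case results from the mean values")
    mean_tbl = psa_raw.groupby("strategy")[["cost", "qaly"]].mean()
    outcomes = [
        StrategyOutcome(label=s, cost=float(r["cost"]), qaly=float(r["qaly"]))
        for s, r in mean_tbl.iterrows()
    ]
    frontier = icer_frontier(outcomes)
    (out / "frontier.json").write_text(
        json.dumps(
            {
                "frontier": frontier.frontier,
                "icers": {k: (None if np.isnan(v) else v) for k, v in frontier.icers.items()},
                "dominated": frontier.dominated,
            },
            indent=2,
        )
    )
    manifest.outputs.append("frontier.json")
    grid_cfg = cfg.get("wtp_grid") or {}
    grid = np.arange(
        grid_cfg.get("lo", 0.0),
        grid_cfg.get("hi", 50_000.0) + 1e-9,
        grid_cfg.get("step", 500.0),
    )
    ceac_tbl = ceac(psa_raw, grid)
    _write_csv(ceac_tbl, out / "ceac.csv", manifest)
    manifest.stage_seconds["cea"] = round(time.time() - t0, 3)

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def _incremental_evaluator(
    cohort, strategy_set, scores, surv, econ, treat, pair: tuple[str, str]
):
    """Deterministic (Δcost, ΔQALY) for a strategy pair under measure overrides."""

    def evaluate(overrides: Mapping[str, float]) -> tuple[float, float]:
        t_i, e_i = apply_measure_overrides(treat, econ, overrides)
        comps = component_outcomes(cohort, surv, e_i, t_i)
        res = strategy_outcomes(cohort, strategy_set, scores, comps).set_index("strategy")
        a, b = pair
        return (
            float(res.loc[b, "cost"] - res.loc[a, "cost"]),
            float(res.loc[b, "qaly"] - res.loc[a, "qaly"]),
        )

    return evaluate


def scenario_runner(
    config: Mapping[str, Any] | str | Path, scenario: str, output_dir: str | Path | None = None
) -> dict[str, Any]:
    """Run one named sensitivity scenario and return its result tables.

    ``adherence`` applies the persistence schedule; ``exclude_diabetes``
    removes diabetic profiles from prioritization and treats them under
    every policy; ``pill_disutility_sweep`` traces strategy NMB over a
    disutility grid; ``threshold_sweep`` walks the risk threshold from
    20% down to treat-all in 1% steps, reporting incremental ICERs.
    """
    cfg = dict(load_config(config)) if not isinstance(config, Mapping) else dict(config)
    if scenario not in {"adherence", "exclude_diabetes", "pill_disutility_sweep", "threshold_sweep"}:
        raise ConfigError(f"unknown scenario {scenario!r}")
    cfg["scenario"] = scenario if scenario in ("adherence",) else cfg.get("scenario")
    validate_config(cfg)
    spec = cohort_spec_from_config(cfg)
    treat = treatment_from_config({**cfg, "scenario": "adherence" if scenario == "adherence" else None})
    econ = econ_from_config(cfg)
    surv = survival_from_config(cfg)
    cohort, _, _ = preprocess(spec, treat.nonhdl_reduction)
    scores = profile_scores(cohort, surv, treat)
    thresholds = tuple(cfg.get("risk_thresholds", (0.20, 0.10)))
    wtp = float(cfg.get("wtp", 20_000.0))
    result: dict[str, Any] = {"scenario": scenario}

    if scenario in ("adherence", "exclude_diabetes"):
        if scenario == "exclude_diabetes":
            diab = cohort["diabetes"].astype(bool).to_numpy()
            sub = cohort.loc[~diab]
            sub_scores = scores.loc[~diab]
            strategy_set = build_strategies(sub, sub_scores, thresholds)
            risk = scores["risk10"].to_numpy()
            arr = scores["arr"].to_numpy()
            eligibility = {
                label: eligible(sdef, cohort, risk=risk, arr=arr) | diab
                for label, sdef in strategy_set.items()
            }
        else:
            strategy_set = build_strategies(cohort, scores, thresholds)
            eligibility = None
        comps = component_outcomes(cohort, surv, econ, treat)
        result["outcomes"] = strategy_outcomes(
            cohort, strategy_set, scores, comps, eligibility
        )
    elif scenario == "pill_disutility_sweep":
        strategy_set = build_strategies(cohort, scores, thresholds)
        grid = np.linspace(0.0, 0.02, 21)
        rows = []
        for d in grid:
            comps = component_outcomes(cohort, surv, econ, dataclasses.replace(treat, pill_disutility=float(d)))
            res = strategy_outcomes(cohort, strategy_set, scores, comps)
            for _, r in res.iterrows():
                rows.append(
                    {
                        "pill_disutility": float(d),
                        "strategy": r["strategy"],
                        "nmb": nmb(r["cost"], r["qaly"], wtp),
                    }
                )
        result["sweep"] = pd.DataFrame(rows)
    else:  # threshold_sweep
        weights = cohort["weight"].to_numpy(float)
        risk = scores["risk10"].to_numpy()
        comps = component_outcomes(cohort, surv, econ, treat)
        rows = []
        prev = None
        for thr in np.arange(0.20, -1e-9, -0.01):
            sdef = StrategyDef("fixed_risk", max(float(thr), 0.0), label=f"risk_{thr:.2f}")
            res = strategy_outcomes(
                cohort, {sdef.label: sdef}, scores, comps
            ).iloc[0]
            row = {
                "threshold": round(float(thr), 2),
                "pct_eligible": res["pct_eligible"],
                "cost": res["cost"],
                "qaly": res["qaly"],
            }
            if prev is not None:
                dq = row["qaly"] - prev["qaly"]
                row["incremental_icer"] = (row["cost"] - prev["cost"]) / dq if dq != 0 else np.nan
            prev = row
            rows.append(row)
        result["sweep"] = pd.DataFrame(rows)

    if output_dir is not None:
        outp = Path(output_dir)
        outp.mkdir(parents=True, exist_ok=True)
        for key, val in result.items():
            if isinstance(val, pd.DataFrame):
                val.to_csv(outp / f"scenario_{scenario}_{key}.csv", index=False)
    return result
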