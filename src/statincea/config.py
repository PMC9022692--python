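"""YAML configuration loading, validation and parameter construction.

A run configuration is a plain YAML mapping with a fixed vocabulary of
top-level keys; unknown keys (at any level that maps onto a parameter
dataclass) raise a :class:`ConfigError` naming the offending field
before any computation starts.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Mapping

import yaml

from .cohort import CohortSpec
from .defaults import (
    default_econ_params,
    default_survival_params,
    default_treatment_params,
)
from .health_econ import EconParams
from .risk_engine import CauseModel, GompertzHazard, SurvivalParams
from .treatment import TreatmentParams

__all__ = [
    "ConfigError",
    "load_config",
    "validate_config",
    "cohort_spec_from_config",
    "treatment_from_config",
    "econ_from_config",
    "survival_from_config",
    "survival_to_dict",
]

TOP_LEVEL_KEYS = {
    "n",
    "seed",
    "psa_iterations",
    "wtp",
    "wtp_grid",
    "risk_thresholds",
    "cohort",
    "treatment",
    "econ",
    "survival",
    "scenario",
}
SCENARIOS = {"adherence", "exclude_diabetes", "pill_disutility_sweep", "threshold_sweep"}


class ConfigError(ValueError):
    """Invalid run configuration."""


def load_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    validate_config(cfg)
    return cfg


def _check_fields(section: Mapping[str, Any], cls, name: str) -> None:
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ConfigError(f"unknown field(s) in '{name}': {sorted(unknown)}")


def validate_config(cfg: Mapping[str, Any]) -> None:
    """Schema-validate a configuration mapping; raises ConfigError."""
    if not isinstance(cfg, Mapping):
        raise ConfigError("configuration must be a mapping")
    unknown = set(cfg) - TOP_LEVEL_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    if "n" in cfg and (not isinstance(cfg["n"], int) or cfg["n"] <= 0):
        raise ConfigError("field 'n' must be a positive integer")
    if "psa_iterations" in cfg and (
        not isinstance(cfg["psa_iterations"], int) or cfg["psa_iterations"] < 2
    ):
        raise ConfigError("field 'psa_iterations' must be an integer >= 2")
    if "scenario" in cfg and cfg["scenario"] is not None and cfg["scenario"] not in SCENARIOS:
        raise ConfigError(
            f"field 'scenario': unknown scenario {cfg['scenario']!r} "
            f"(expected one of {sorted(SCENARIOS)})"
        )
    if "risk_thresholds" in cfg:
        thrs = cfg["risk_thresholds"]
        if not isinstance(thrs, (list, tuple)) or not all(0 < t <= 1 for t in thrs):
            raise ConfigError("field 'risk_thresholds' must be a list of proportions in (0,1]")
    for section, cls in (("cohort", CohortSpec), ("treatment", TreatmentParams), ("econ", EconParams)):
        if section in cfg and cfg[section]:
            if not isinstance(cfg[section], Mapping):
                raise ConfigError(f"field '{section}' must be a mapping")
            _check_fields(cfg[section], cls, section)
    if "wtp_grid" in cfg and cfg["wtp_grid"]:
        bad = set(cfg["wtp_grid"]) - {"lo", "hi", "step"}
        if bad:
            raise ConfigError(f"unknown field(s) in 'wtp_grid': {sorted(bad)}")


def _coerce(section: Mapping[str, Any] | None) -> dict:
    out = dict(section or {})
    for k, v in out.items():
        if isinstance(v, list):
            out[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
    return out


def cohort_spec_from_config(cfg: Mapping[str, Any]) -> CohortSpec:
    over = _coerce(cfg.get("cohort"))
    if "n" in cfg:
        over.setdefault("n", cfg["n"])
    if "seed" in cfg:
        over.setdefault("seed", cfg["seed"])
    return CohortSpec(**over)


def treatment_from_config(cfg: Mapping[str, Any]) -> TreatmentParams:
    base = default_treatment_params(adherence_scenario=cfg.get("scenario") == "adherence")
    over = _coerce(cfg.get("treatment"))
    return dataclasses.replace(base, **over)


def econ_from_config(cfg: Mapping[str, Any]) -> EconParams:
    over = _coerce(cfg.get("econ"))
    return dataclasses.replace(default_econ_params(), **over)


def survival_from_config(cfg: Mapping[str, Any]) -> SurvivalParams:
    """Build survival parameters from the 'survival' section, if present.

    The section mirrors :func:`survival_to_dict`; omitted parts fall
    back to the synthetic defaults.
    """
    sec = cfg.get("survival")
    base = default_survival_params()
    if not sec:
        return base
    causes = dict(base.causes)
    for cname, cdict in (sec.get("causes") or {}).items():
        if cname not in causes:
            raise ConfigError(f"unknown cause {cname!r} in 'survival.causes'")
        b = cdict.get("baseline", {})
        baseline = GompertzHazard(
            b.get("rate_at_ref", causes[cname].baseline.rate_at_ref),
            b.get("gamma", causes[cname].baseline.gamma),
            b.get("ref_age", causes[cname].baseline.ref_age),
        )
        causes[cname] = CauseModel(
            baseline=baseline,
            coefficients=dict(cdict.get("coefficients", causes[cname].coefficients)),
            reference=dict(cdict.get("reference", causes[cname].reference)),
        )
    post = dict(base.post_event_mortality)
    for k, p in (sec.get("post_event_mortality") or {}).items():
        post[k] = GompertzHazard(p["rate_at_ref"], p["gamma"], p.get("ref_age", 60.0))
    return SurvivalParams(
        causes=causes,
        post_event_mortality=post,
        max_age=sec.get("max_age", base.max_age),
        hr_parameters=base.hr_parameters,
        hr_covariance=base.hr_covariance,
    )


def survival_to_dict(params: SurvivalParams) -> dict:
    return {
        "max_age": params.max_age,
        "causes": {
            c: {
                "baseline": {
                    "rate_at_ref": m.baseline.rate_at_ref,
                    "gamma": m.baseline.gamma,
                    "ref_age": m.baseline.ref_age,
                },
                "coefficients": dict(m.coefficients),
                "reference": dict(m.reference),
            }
            for c, m in params.causes.items()
        },
        "post_event_mortality": {
            k: {"rate_at_ref": h.rate_at_ref, "gamma": h.gamma, "ref_age": h.ref_age}
            for k, h in params.post_event_mortality.items()
        },
    }
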