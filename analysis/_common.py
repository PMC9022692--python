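"""Shared constants and helpers for the numbered analysis scripts.

All scripts run on the same study conditions: the default synthetic
cohort at n = 10,000 generated records with master seed 1, the shipped
synthetic survival/cost parameters, and trial-derived statin measures.
"""

from pathlib import Path

import pandas as pd

from statincea.cohort import preprocess
from statincea.defaults import (
    default_cohort_spec,
    default_econ_params,
    default_survival_params,
    default_treatment_params,
)

N = 10_000
SEED = 1
PSA_ITERATIONS = 200
WTP = 20_000.0

RESULTS = Path(__file__).resolve().parent.parent / "results"

BOOL_COLS = ["diabetes", "famhist", "on_statin", "prevalent_cvd", "refused_nurse_visit"]


def load_or_build_cohort():
    """Reuse results/cohort.csv when present, else rebuild it (same seed)."""
    path = RESULTS / "cohort.csv"
    if path.exists():
        df = pd.read_csv(path)
        for c in BOOL_COLS:
            df[c] = df[c].astype(bool)
        return df
    cohort, _, _ = preprocess(default_cohort_spec(n=N, seed=SEED))
    return cohort


def base_params():
    return default_survival_params(), default_econ_params(), default_treatment_params()
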