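"""Health-state enumeration for the multistate CVD policy model.

Individuals enter CVD-free and may transition to one of four primary
event types: nonfatal coronary heart disease, nonfatal cerebrovascular
disease, fatal CVD or fatal non-CVD.  Survivors of a nonfatal event
occupy a chronic state until death from any cause.
"""

from __future__ import annotations

from enum import IntEnum

__all__ = ["HealthState", "CAUSES", "CVD_CAUSES", "N_STATES"]

#: primary-event causes, in the column order used by the engine
CAUSES = ("nonfatal_chd", "nonfatal_cbvd", "fatal_cvd", "fatal_noncvd")
#: causes counting toward the composite CVD endpoint
CVD_CAUSES = ("nonfatal_chd", "nonfatal_cbvd", "fatal_cvd")


class HealthState(IntEnum):
    CVD_FREE = 0
    CHRONIC_CHD = 1
    CHRONIC_CBVD = 2
    DEAD_CVD = 3
    DEAD_NONCVD = 4
    DEAD_POST_EVENT = 5

    def is_dead(self) -> bool:
        return self >= HealthState.DEAD_CVD

    def is_absorbing(self) -> bool:
        return self.is_dead()


N_STATES = len(HealthState)
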