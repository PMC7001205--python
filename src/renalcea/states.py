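"""Health states, perspectives and engine conventions shared across modules."""
from __future__ import annotations

from enum import Enum


class HealthState(str, Enum):
    """Principal Markov states of the end-stage renal disease model.

    Three dialysis modalities, a combined transplant/post-transplant state,
    and absorbing death.
    """

    PD = "PD"
    HOSP_HD = "HOSP_HD"
    HOME_HD = "HOME_HD"
    TRANSPLANT = "TRANSPLANT"
    DEATH = "DEATH"


DIALYSIS_STATES: tuple[HealthState, ...] = (
    HealthState.PD,
    HealthState.HOSP_HD,
    HealthState.HOME_HD,
)
ALIVE_STATES: tuple[HealthState, ...] = DIALYSIS_STATES + (HealthState.TRANSPLANT,)

#: Modality switches ruled out by the model structure: no observed data for
#: home HD back to PD, and transplanted patients never return to dialysis.
FORBIDDEN_SWITCHES: frozenset[tuple[HealthState, HealthState]] = frozenset(
    {(HealthState.HOME_HD, HealthState.PD)}
    | {(HealthState.TRANSPLANT, s) for s in DIALYSIS_STATES}
)


class Perspective(str, Enum):
    PROVIDER = "PROVIDER"
    SOCIETAL = "SOCIETAL"


class RateConversion(str, Enum):
    """How an event rate (cases per 100 person-years) becomes an annual probability."""

    EXPONENTIAL = "EXPONENTIAL"  # p = 1 - exp(-rate/100), constant-hazard assumption
    LINEAR = "LINEAR"  # p = min(rate/100, 1)


class HomeHDMortalityMode(str, Enum):
    """Treatment of death risk while on nocturnal home haemodialysis.

    TABLE_RATE applies the registry mortality rate directly to the home-HD
    state.  ZERO_ROUTED_VIA_HOSP encodes the structural assumption that
    deteriorating home-HD patients are first admitted and switched to
    hospital HD before dying: the death mass of the home-HD row is diverted
    to hospital HD instead.
    """

    TABLE_RATE = "TABLE_RATE"
    ZERO_ROUTED_VIA_HOSP = "ZERO_ROUTED_VIA_HOSP"
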