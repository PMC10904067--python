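"""Health states, management flags, and the joint model state space.

The disease model distinguishes six health states — no retinopathy (NO_DR),
nonproliferative retinopathy (NPDR), proliferative retinopathy (PDR),
diabetic macular edema (DME), severe visual impairment (SVI, bilateral
best-corrected acuity < 6/60), and death — with forward-only progression:

    NO_DR -> {NPDR, PDR};  NPDR -> {PDR, DME};  PDR -> {DME, SVI};
    DME -> {SVI};  any alive state -> DEATH.

Because detection changes both costs (annual follow-up, treatment) and
progression rates (treated PDR/DME progress to SVI more slowly), the engine
tracks the product of health state and management flag.  SVI is split into a
first-year and an established sub-state so the higher first-year cost of
visual impairment can be charged exactly once.
"""

from __future__ import annotations

from enum import Enum


class HealthState(Enum):
    """The six clinical states of the progression model."""

    NO_DR = "no_dr"
    NPDR = "npdr"
    PDR = "pdr"
    DME = "dme"
    SVI = "svi"
    DEATH = "death"


class ManagementFlag(Enum):
    """Detection/treatment status attached to a health state.

    DIAGNOSED_FOLLOWUP only attaches to NPDR (annual observation, no
    treatment), TREATED_PDR only to PDR (photocoagulation), TREATED_DME only
    to DME (intravitreal anti-VEGF).  Everyone else is UNDIAGNOSED.
    """

    UNDIAGNOSED = "undiagnosed"
    DIAGNOSED_FOLLOWUP = "diagnosed_followup"
    TREATED_PDR = "treated_pdr"
    TREATED_DME = "treated_dme"


# Allowed forward transitions between health states (recovery is not modelled).
ALLOWED_PROGRESSION: dict[HealthState, tuple[HealthState, ...]] = {
    HealthState.NO_DR: (HealthState.NPDR, HealthState.PDR),
    HealthState.NPDR: (HealthState.PDR, HealthState.DME),
    HealthState.PDR: (HealthState.DME, HealthState.SVI),
    HealthState.DME: (HealthState.SVI,),
    HealthState.SVI: (),
    HealthState.DEATH: (),
}

# Indices of the expanded model state space used by the cohort engine and the
# microsimulation.  Order is load-bearing: transition matrices, cost and
# utility vectors, and traces all use it.
NO_DR = 0        # (NO_DR, UNDIAGNOSED)
NPDR_U = 1       # (NPDR, UNDIAGNOSED)
NPDR_DX = 2      # (NPDR, DIAGNOSED_FOLLOWUP)
PDR_U = 3        # (PDR, UNDIAGNOSED)
PDR_TX = 4       # (PDR, TREATED_PDR)
DME_U = 5        # (DME, UNDIAGNOSED)
DME_TX = 6       # (DME, TREATED_DME)
SVI_NEW = 7      # first year of severe visual impairment
SVI_EST = 8      # subsequent years of severe visual impairment
DEATH = 9

N_STATES = 10

STATE_LABELS: tuple[str, ...] = (
    "no_dr",
    "npdr_undiagnosed",
    "npdr_followup",
    "pdr_undiagnosed",
    "pdr_treated",
    "dme_undiagnosed",
    "dme_treated",
    "svi_first_year",
    "svi_established",
    "death",
)

#: health state of each expanded index
HEALTH_OF_STATE: tuple[HealthState, ...] = (
    HealthState.NO_DR,
    HealthState.NPDR,
    HealthState.NPDR,
    HealthState.PDR,
    HealthState.PDR,
    HealthState.DME,
    HealthState.DME,
    HealthState.SVI,
    HealthState.SVI,
    HealthState.DEATH,
)

#: management flag of each expanded index (None for SVI/DEATH)
MANAGEMENT_OF_STATE: tuple[ManagementFlag | None, ...] = (
    ManagementFlag.UNDIAGNOSED,
    ManagementFlag.UNDIAGNOSED,
    ManagementFlag.DIAGNOSED_FOLLOWUP,
    ManagementFlag.UNDIAGNOSED,
    ManagementFlag.TREATED_PDR,
    ManagementFlag.UNDIAGNOSED,
    ManagementFlag.TREATED_DME,
    None,
    None,
    None,
)

ALIVE_STATES: tuple[int, ...] = tuple(range(DEATH))
SVI_STATES: tuple[int, ...] = (SVI_NEW, SVI_EST)
#: states eligible for population screening: alive, undiagnosed, not yet SVI
SCREENABLE_STATES: tuple[int, ...] = (NO_DR, NPDR_U, PDR_U, DME_U)
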