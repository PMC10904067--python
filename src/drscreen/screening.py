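"""Screening policies and the test-referral-treatment cascade.

A screening round works on the undiagnosed, not-yet-visually-impaired part
of the cohort: a fraction (uptake) attends and incurs the per-person
programme cost; attendees called positive by the test who accept referral
(referral acceptance) receive a full hospital ophthalmologic examination,
assumed perfectly accurate.  Confirmed NPDR enters annual follow-up
observation, confirmed PDR receives photocoagulation, confirmed DME
receives intravitreal anti-VEGF; false positives pay the examination only,
false negatives stay undiagnosed until a later round.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ModelParameters, TestCharacteristics
from .states import (
    DME_TX,
    DME_U,
    NO_DR,
    NPDR_DX,
    NPDR_U,
    N_STATES,
    PDR_TX,
    PDR_U,
    SCREENABLE_STATES,
)

STRATEGIES = ("none", "community", "telemedicine")


@dataclass(frozen=True)
class ScreeningPolicy:
    """What to screen with and how often.

    ``interval=None`` means one-off screening at the first cycle; an integer
    k means screening at cycles 0, k, 2k, ...  Compliance overrides default
    to the values in the parameter set.
    """

    strategy: str = "none"
    interval: int | None = None
    uptake: float | None = None
    referral_acceptance: float | None = None

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; expected {STRATEGIES}")
        if self.interval is not None and self.interval < 1:
            raise ValueError(f"screening interval must be >= 1 year, got {self.interval}")

    @property
    def interval_label(self) -> str:
        if self.strategy == "none":
            return "-"
        return "one-off" if self.interval is None else f"every {self.interval}y"


@dataclass
class ClassificationMatrix:
    """Called-grade distribution and DME flag probability per true state.

    ``grades`` has one row per true health state (no_dr, npdr, pdr, dme) and
    columns called_normal / called_npdr / called_pdr summing to one; any
    residual probability mass is assigned to called_normal.
    ``dme_positive`` is the probability of a positive DME call per true
    state (sensitivity for true DME, 1 - specificity otherwise).
    """

    grades: pd.DataFrame
    dme_positive: pd.Series


def classification_matrix(test: TestCharacteristics) -> ClassificationMatrix:
    """Build the misclassification table of one screening modality."""
    rows = {
        "no_dr": {"called_npdr": test.normal_called_npdr.base, "called_pdr": 0.0},
        "npdr": {"called_npdr": 1.0 - test.npdr_called_normal.base, "called_pdr": 0.0},
        "pdr": {
            "called_npdr": test.pdr_called_npdr.base,
            "called_pdr": 1.0 - test.pdr_called_npdr.base - test.pdr_called_normal.base,
        },
        "dme": {"called_npdr": 0.0, "called_pdr": 0.0},
    }
    grades = pd.DataFrame(rows).T
    grades.insert(0, "called_normal", 1.0 - grades.sum(axis=1))
    bad = (grades < -1e-12) | (grades > 1 + 1e-12)
    if bad.any().any():
        raise ValueError(f"classification probabilities outside [0, 1]:\n{grades}")
    grades = grades.clip(lower=0.0)
    dme_positive = pd.Series(
        {
            "no_dr": 1.0 - test.dme_specificity.base,
            "npdr": 1.0 - test.dme_specificity.base,
            "pdr": 1.0 - test.dme_specificity.base,
            "dme": test.dme_sensitivity.base,
        }
    )
    return ClassificationMatrix(grades=grades, dme_positive=dme_positive)


def referral_probabilities(policy: ScreeningPolicy, params: ModelParameters) -> np.ndarray:
    """Probability that an attendee in each model state is called positive.

    Indexed by expanded model state; nonzero only for screenable states.
    By default a grade call of NPDR/PDR triggers referral for true
    NO_DR/NPDR/PDR and a positive DME call triggers referral for true DME.
    With ``options.dme_false_positive_referrals`` the DME flag also refers
    false positives in the non-DME states (1 - specificity each round).
    """
    test = params.tests[policy.strategy]
    cm = classification_matrix(test)
    r = np.zeros(N_STATES)
    for state, key in ((NO_DR, "no_dr"), (NPDR_U, "npdr"), (PDR_U, "pdr")):
        grade_positive = 1.0 - cm.grades.loc[key, "called_normal"]
        if params.options.dme_false_positive_referrals:
            r[state] = 1.0 - (1.0 - grade_positive) * (1.0 - cm.dme_positive[key])
        else:
            r[state] = grade_positive
    r[DME_U] = cm.dme_positive["dme"]
    return r


def resolve_compliance(policy: ScreeningPolicy, params: ModelParameters) -> tuple[float, float]:
    comp = params.economics.compliance
    uptake = comp.uptake.base if policy.uptake is None else policy.uptake
    accept = (
        comp.referral_acceptance.base
        if policy.referral_acceptance is None
        else policy.referral_acceptance
    )
    return uptake, accept


def schedule(policy: ScreeningPolicy, cycle: int) -> bool:
    """Whether a screening round takes place at the start of ``cycle``."""
    if cycle < 0:
        raise ValueError(f"cycle index must be >= 0, got {cycle}")
    if policy.strategy == "none":
        return False
    if policy.interval is None:
        return cycle == 0
    return cycle % policy.interval == 0


def apply_screening_event(
    occupancy: np.ndarray, policy: ScreeningPolicy, params: ModelParameters
) -> tuple[np.ndarray, float]:
    """One screening round applied to a cohort occupancy vector.

    Returns the post-screening occupancy (health states unchanged, management
    flags updated for confirmed cases) and the event cost per cohort member:
    programme cost for attendees, hospital examination for accepted
    referrals, and treatment initiation for confirmed PDR/DME.
    """
    if policy.strategy == "none":
        return occupancy.copy(), 0.0
    occ = np.asarray(occupancy, dtype=float)
    if occ.shape != (N_STATES,) or np.any(occ < -1e-12):
        raise ValueError("invalid occupancy vector")
    uptake, accept = resolve_compliance(policy, params)
    screen_cost = params.costs.screening_per_person[policy.strategy].base
    exam_cost = params.costs.hospital_exam_total.base

    r = referral_probabilities(policy, params)
    new = occ.copy()
    attending = uptake * occ[list(SCREENABLE_STATES)].sum()
    cost = attending * screen_cost

    referred = {s: occ[s] * uptake * r[s] * accept for s in SCREENABLE_STATES}
    cost += sum(referred.values()) * exam_cost
    # hospital confirmation is perfect: referred true disease changes flag,
    # referred NO_DR returns home with a clean bill
    new[NPDR_U] -= referred[NPDR_U]
    new[NPDR_DX] += referred[NPDR_U]
    new[PDR_U] -= referred[PDR_U]
    new[PDR_TX] += referred[PDR_U]
    cost += referred[PDR_U] * params.costs.photocoagulation.base
    new[DME_U] -= referred[DME_U]
    new[DME_TX] += referred[DME_U]
    cost += referred[DME_U] * params.costs.anti_vegf.base
    return new, float(cost)
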