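"""Deterministic cohort state-transition engine.

Runs a unit cohort of diabetic patients from the starting age through
annual cycles over the expanded (health state x management flag) space.
Within each cycle: any scheduled screening round first (management flags
and one-off event costs), then mortality, then disease progression among
survivors (competing-risk ordering).  Utilities and recurring costs are
half-cycle corrected — valued at the trapezoidal average of cycle-start and
cycle-end occupancy — while one-off event costs (screening, examination,
treatment initiation, the first year of visual impairment) are charged in
full at the cycle they occur.  Costs and QALYs are discounted annually.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import screening as scr
from .parameters import ModelParameters, MortalityModel
from .states import (
    ALIVE_STATES,
    DEATH,
    DME_TX,
    DME_U,
    HealthState,
    NO_DR,
    NPDR_DX,
    NPDR_U,
    N_STATES,
    PDR_TX,
    PDR_U,
    STATE_LABELS,
    SVI_EST,
    SVI_NEW,
)

_ROW_SUM_TOL = 1e-12


@dataclass
class StrategyResult:
    """Discounted per-person totals for one (setting, strategy, interval)."""

    setting: str
    strategy: str
    interval: int | None
    cost_per_person: float
    qalys_per_person: float

    @property
    def interval_label(self) -> str:
        if self.strategy == "none":
            return "-"
        return "one-off" if self.interval is None else f"every {self.interval}y"


@dataclass
class CohortTrace:
    """Per-cycle cohort occupancy and accumulated outcomes.

    ``occupancy[c]`` is the distribution at the start of cycle ``c`` after
    any screening round that cycle; ``occupancy[n_cycles]`` is the final
    distribution.  Costs and QALYs are per cohort member.
    """

    ages: np.ndarray
    occupancy: np.ndarray
    cycle_cost: np.ndarray
    cycle_qaly: np.ndarray
    disc_cost_cum: np.ndarray
    disc_qaly_cum: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        n = len(self.cycle_cost)
        df = pd.DataFrame(self.occupancy[:n], columns=STATE_LABELS)
        df.insert(0, "age", self.ages[:n])
        df.insert(0, "cycle", np.arange(n))
        df["cost"] = self.cycle_cost
        df["qaly"] = self.cycle_qaly
        df["disc_cost_cum"] = self.disc_cost_cum
        df["disc_qaly_cum"] = self.disc_qaly_cum
        return df


def initial_distribution(params: ModelParameters) -> np.ndarray:
    """Prevalence-defined starting occupancy of an unscreened cohort."""
    p = params.prevalence
    total = p.npdr.base + p.pdr.base + p.dme.base
    if total >= 1.0:
        raise ValueError(f"prevalence sum {total} >= 1 leaves no mass for NO_DR")
    occ = np.zeros(N_STATES)
    occ[NPDR_U] = p.npdr.base
    occ[PDR_U] = p.pdr.base
    occ[DME_U] = p.dme.base
    occ[NO_DR] = 1.0 - total
    return occ


def cycle_mortality(age: float, health: HealthState, mort: MortalityModel) -> float:
    """Annual death probability at ``age`` in a given health state.

    Background mortality is multiplied by the diabetes risk ratio, replaced
    by (or, in 'multiply' mode, additionally multiplied by) the severe
    visual impairment risk ratio for SVI patients, and capped at 1.
    """
    if health is HealthState.DEATH:
        return 1.0
    q = mort.background_q(age)
    if health is HealthState.SVI:
        rr = mort.rr_svi.base
        if mort.svi_multiplier_mode == "multiply":
            rr *= mort.rr_diabetes.base
    else:
        rr = mort.rr_diabetes.base
    return min(1.0, q * rr)


def _death_probabilities(params: ModelParameters, age: float) -> np.ndarray:
    pd_ = np.empty(N_STATES)
    mort = params.mortality
    q = mort.background_q(age)
    rr_svi = mort.rr_svi.base
    if mort.svi_multiplier_mode == "multiply":
        rr_svi *= mort.rr_diabetes.base
    pd_[:] = min(1.0, q * mort.rr_diabetes.base)
    pd_[SVI_NEW] = pd_[SVI_EST] = min(1.0, q * rr_svi)
    pd_[DEATH] = 1.0
    return pd_


def build_transition_matrix(params: ModelParameters, age: float) -> np.ndarray:
    """One-cycle transition matrix over the expanded state space at ``age``.

    Mortality applies first; surviving mass is allocated to progression
    events at the annual probabilities of the parameter set (treated states
    use the treated progression rates); the residual stays put.
    """
    t = params.transitions
    pdie = _death_probabilities(params, age)
    M = np.zeros((N_STATES, N_STATES))
    moves: dict[int, list[tuple[int, float]]] = {
        NO_DR: [(NPDR_U, t.normal_to_npdr.base), (PDR_U, t.normal_to_pdr.base)],
        NPDR_U: [(PDR_U, t.npdr_to_pdr.base), (DME_U, t.npdr_to_dme.base)],
        # progression of a patient under annual follow-up is detected and
        # treated at once (clinical surveillance, not re-screening)
        NPDR_DX: [(PDR_TX, t.npdr_to_pdr.base), (DME_TX, t.npdr_to_dme.base)],
        PDR_U: [(DME_U, t.pdr_to_dme.base), (SVI_NEW, t.pdr_to_svi.base)],
        PDR_TX: [(SVI_NEW, t.treated_pdr_to_svi.base)],
        DME_U: [(SVI_NEW, t.dme_to_svi.base)],
        DME_TX: [(SVI_NEW, t.treated_dme_to_svi.base)],
        SVI_NEW: [(SVI_EST, 1.0)],
        SVI_EST: [],
    }
    if params.options.treated_pdr_to_dme:
        moves[PDR_TX].append((DME_TX, t.pdr_to_dme.base))
    for i in ALIVE_STATES:
        survive = 1.0 - pdie[i]
        M[i, DEATH] = pdie[i]
        out = 0.0
        for j, p in moves[i]:
            M[i, j] += survive * p
            out += p
        if out > 1.0 + _ROW_SUM_TOL:
            raise ValueError(
                f"outgoing probabilities from {STATE_LABELS[i]} sum to {out} > 1"
            )
        M[i, i] += survive * (1.0 - min(out, 1.0))
    M[DEATH, DEATH] = 1.0
    rowsum = M.sum(axis=1)
    if np.any(np.abs(rowsum - 1.0) > 1e-9):
        raise AssertionError(f"transition matrix rows not stochastic: {rowsum}")
    return M


def utility_vector(params: ModelParameters) -> np.ndarray:
    """QALY weight of each expanded state."""
    u = params.utilities
    return np.array(
        [
            u.no_dr.base,
            u.npdr.base,
            u.npdr.base,
            u.pdr.base,
            u.pdr.base,
            u.dme.base,
            u.dme.base,
            u.svi.base,
            u.svi.base,
            0.0,
        ]
    )


def recurring_cost_vector(params: ModelParameters) -> np.ndarray:
    """Annual recurring cost of occupying each expanded state.

    Annual follow-up observation for diagnosed NPDR and the subsequent-year
    cost of severe visual impairment; the first SVI year is charged as a
    one-off at entry (see :func:`flow_cost_matrix`).
    """
    rec = np.zeros(N_STATES)
    rec[NPDR_DX] = params.costs.followup_maintain.base
    rec[SVI_EST] = params.costs.svi_subsequent_year.base
    return rec


def flow_cost_matrix(params: ModelParameters) -> np.ndarray:
    """One-off cost attached to each transition (charged on the moving mass)."""
    F = np.zeros((N_STATES, N_STATES))
    F[NPDR_DX, PDR_TX] = params.costs.photocoagulation.base
    F[NPDR_DX, DME_TX] = params.costs.anti_vegf.base
    if params.options.treated_pdr_to_dme:
        F[PDR_TX, DME_TX] = params.costs.anti_vegf.base
    for i in (PDR_U, PDR_TX, DME_U, DME_TX):
        F[i, SVI_NEW] = params.costs.svi_first_year.base
    return F


def run_cohort(
    params: ModelParameters, policy: scr.ScreeningPolicy
) -> tuple[CohortTrace, StrategyResult]:
    """Run the cohort model under one screening policy.

    Returns the full trace and the discounted per-person totals.
    """
    econ = params.economics
    n = econ.n_cycles
    v = 1.0 / (1.0 + econ.discount_rate)
    u = utility_vector(params)
    rec = recurring_cost_vector(params)
    F = flow_cost_matrix(params)

    occ = initial_distribution(params)
    occupancy = np.zeros((n + 1, N_STATES))
    ages = econ.start_age + np.arange(n + 1)
    cycle_cost = np.zeros(n)
    cycle_qaly = np.zeros(n)
    disc_cost_cum = np.zeros(n)
    disc_qaly_cum = np.zeros(n)
    disc_cost = 0.0
    disc_qaly = 0.0

    for c in range(n):
        event_cost = 0.0
        if scr.schedule(policy, c):
            occ, event_cost = scr.apply_screening_event(occ, policy, params)
        occupancy[c] = occ
        M = build_transition_matrix(params, age=econ.start_age + c)
        occ_end = occ @ M
        if abs(occ_end.sum() - occ.sum()) > 1e-9:
            raise AssertionError("cohort mass not conserved by transition")
        oneoff = float(np.einsum("i,ij,ij->", occ, M, F))
        recur = 0.5 * (rec @ occ + rec @ occ_end)
        util = 0.5 * (u @ occ + u @ occ_end)
        cycle_cost[c] = event_cost + oneoff + recur
        cycle_qaly[c] = util
        disc_cost += event_cost * v**c + (oneoff + recur) * v ** (c + 1)
        disc_qaly += util * v ** (c + 1)
        disc_cost_cum[c] = disc_cost
        disc_qaly_cum[c] = disc_qaly
        occ = occ_end
    occupancy[n] = occ

    trace = CohortTrace(
        ages=ages,
        occupancy=occupancy,
        cycle_cost=cycle_cost,
        cycle_qaly=cycle_qaly,
        disc_cost_cum=disc_cost_cum,
        disc_qaly_cum=disc_qaly_cum,
    )
    result = StrategyResult(
        setting=params.setting,
        strategy=policy.strategy,
        interval=policy.interval,
        cost_per_person=float(disc_cost),
        qalys_per_person=float(disc_qaly),
    )
    return trace, result
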