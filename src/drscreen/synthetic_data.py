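"""Synthetic inputs and the individual-level microsimulation oracle.

The published evidence base leaves three things unprinted: an age-specific
background mortality schedule, screening/referral compliance, and any
individual-level data.  This module supplies stand-ins with the right
shape — a Gompertz life table, lognormally perturbed but internally
consistent parameter sets for testing — and an individual-level
microsimulation that re-derives every transition from the raw annual
probabilities.  The microsimulation shares the cost/utility valuation
vectors with the cohort engine but none of its state-propagation algebra,
so agreement between the two is a genuine check of the transition
arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import screening as scr
from .markov_engine import (
    flow_cost_matrix,
    initial_distribution,
    recurring_cost_vector,
    utility_vector,
)
from .parameters import (
    ModelParameters,
    iter_uncertain_parameters,
    repair_parameters,
    validate_parameters,
)
from .states import (
    DEATH,
    DME_TX,
    DME_U,
    NO_DR,
    NPDR_DX,
    NPDR_U,
    PDR_TX,
    PDR_U,
    SCREENABLE_STATES,
    SVI_EST,
    SVI_NEW,
)


@dataclass
class SyntheticLifeTable:
    """Annual background mortality by single year of age."""

    ages: np.ndarray
    q: np.ndarray
    a: float | None = None
    b: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "q": self.q})


def make_life_table(
    a: float = 0.004, b: float = 0.085, age_min: int = 50, age_max: int = 110
) -> SyntheticLifeTable:
    """Gompertz mortality schedule q(age) = min(1, a * exp(b * (age - age_min))).

    The defaults give roughly 0.4% annual mortality at age 50 doubling about
    every eight years — a plausible adult schedule before the diabetes and
    visual-impairment multipliers are applied.
    """
    if a <= 0:
        raise ValueError(f"baseline hazard a must be > 0, got {a}")
    if b < 0:
        raise ValueError(f"slope b must be >= 0, got {b}")
    if age_max < age_min:
        raise ValueError("age_max must be >= age_min")
    ages = np.arange(age_min, age_max + 1, dtype=float)
    q = np.minimum(1.0, a * np.exp(b * (ages - age_min)))
    return SyntheticLifeTable(ages=ages, q=q, a=a, b=b)


def perturb_parameters(
    params: ModelParameters, relative_sd: float, seed: int
) -> ModelParameters:
    """Randomly perturbed but internally consistent parameter set.

    Every uncertain scalar is multiplied by an independent lognormal factor
    with the given relative standard deviation, clipped to its support, and
    the joint invariants are repaired (treated rates capped at untreated,
    complement rows recomputed, prevalence renormalized).  Deterministic
    given ``seed``.
    """
    if relative_sd < 0:
        raise ValueError(f"relative_sd must be >= 0, got {relative_sd}")
    out = params.copy()
    if relative_sd == 0:
        return out
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(relative_sd**2))
    for ref in iter_uncertain_parameters(out):
        v = ref.get(out)
        factor = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma)
        lo, hi = ref.support()
        ref.set_base(out, float(np.clip(v.base * factor, lo, hi)))
    repair_parameters(out)
    violations = validate_parameters(out, fixture_checks=False)
    if violations:  # pragma: no cover - repair should always succeed
        raise AssertionError("perturbation left invalid parameters: " + "; ".join(violations))
    return out


@dataclass
class MicrosimConfig:
    n_individuals: int
    seed: int
    params: ModelParameters
    policy: scr.ScreeningPolicy

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")


@dataclass
class MicrosimResult:
    mean_cost: float
    mean_qaly: float
    se_cost: float
    se_qaly: float
    n_individuals: int

    def report(self) -> str:
        return (
            f"microsimulation of {self.n_individuals} individuals\n"
            f"  cost per person: {self.mean_cost:.2f} (SE {self.se_cost:.3f})\n"
            f"  QALYs per person: {self.mean_qaly:.5f} (SE {self.se_qaly:.5f})\n"
        )


def _sample_progression(
    rng: np.random.Generator,
    s: np.ndarray,
    params: ModelParameters,
    age: float,
) -> np.ndarray:
    """One year of per-individual mortality and progression draws.

    Independent re-derivation of the cycle dynamics: a death draw first
    (background mortality times the state's risk ratio), then a progression
    draw for survivors using the raw annual probabilities.
    """
    t = params.transitions
    mort = params.mortality
    q = mort.background_q(age)
    rr_svi = mort.rr_svi.base
    if mort.svi_multiplier_mode == "multiply":
        rr_svi *= mort.rr_diabetes.base
    p_die = np.full(s.shape, min(1.0, q * mort.rr_diabetes.base))
    p_die[np.isin(s, (SVI_NEW, SVI_EST))] = min(1.0, q * rr_svi)

    alive = s != DEATH
    new = s.copy()
    die = alive & (rng.random(s.shape) < p_die)
    new[die] = DEATH

    u = rng.random(s.shape)
    moves = {
        NO_DR: ((NPDR_U, t.normal_to_npdr.base), (PDR_U, t.normal_to_pdr.base)),
        NPDR_U: ((PDR_U, t.npdr_to_pdr.base), (DME_U, t.npdr_to_dme.base)),
        NPDR_DX: ((PDR_TX, t.npdr_to_pdr.base), (DME_TX, t.npdr_to_dme.base)),
        PDR_U: ((DME_U, t.pdr_to_dme.base), (SVI_NEW, t.pdr_to_svi.base)),
        PDR_TX: ((SVI_NEW, t.treated_pdr_to_svi.base),)
        + (((DME_TX, t.pdr_to_dme.base),) if params.options.treated_pdr_to_dme else ()),
        DME_U: ((SVI_NEW, t.dme_to_svi.base),),
        DME_TX: ((SVI_NEW, t.treated_dme_to_svi.base),),
        SVI_NEW: ((SVI_EST, 1.0),),
        SVI_EST: (),
    }
    for state, options in moves.items():
        mask = alive & ~die & (s == state)
        if not mask.any() or not options:
            continue
        lo = 0.0
        for target, p in options:
            hit = mask & (u >= lo) & (u < lo + p)
            new[hit] = target
            lo += p
    return new


def microsimulate(config: MicrosimConfig) -> MicrosimResult:
    """Monte-Carlo estimate of per-person discounted cost and QALYs.

    Mirrors the cohort engine's event ordering, valuation, half-cycle
    correction, and discounting on individually simulated trajectories.
    """
    params = config.params
    policy = config.policy
    econ = params.economics
    n = config.n_individuals
    rng = np.random.default_rng(config.seed)
    v = 1.0 / (1.0 + econ.discount_rate)

    u_vec = utility_vector(params)
    rec_vec = recurring_cost_vector(params)
    F = flow_cost_matrix(params)

    init = initial_distribution(params)
    s = rng.choice(len(init), size=n, p=init)
    cost = np.zeros(n)
    qaly = np.zeros(n)

    uptake, accept = scr.resolve_compliance(policy, params)
    if policy.strategy != "none":
        screen_cost = params.costs.screening_per_person[policy.strategy].base
        exam_cost = params.costs.hospital_exam_total.base
        refer_p = scr.referral_probabilities(policy, params)

    for c in range(econ.n_cycles):
        if scr.schedule(policy, c):
            eligible = np.isin(s, SCREENABLE_STATES)
            attend = eligible & (rng.random(n) < uptake)
            cost[attend] += screen_cost * v**c
            called = attend & (rng.random(n) < refer_p[s])
            referred = called & (rng.random(n) < accept)
            cost[referred] += exam_cost * v**c
            for src, dst, fee in (
                (NPDR_U, NPDR_DX, 0.0),
                (PDR_U, PDR_TX, params.costs.photocoagulation.base),
                (DME_U, DME_TX, params.costs.anti_vegf.base),
            ):
                hit = referred & (s == src)
                s[hit] = dst
                cost[hit] += fee * v**c
        s_start = s.copy()
        s = _sample_progression(rng, s_start, params, age=econ.start_age + c)
        cost += F[s_start, s] * v ** (c + 1)
        cost += 0.5 * (rec_vec[s_start] + rec_vec[s]) * v ** (c + 1)
        qaly += 0.5 * (u_vec[s_start] + u_vec[s]) * v ** (c + 1)

    return MicrosimResult(
        mean_cost=float(cost.mean()),
        mean_qaly=float(qaly.mean()),
        se_cost=float(cost.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        se_qaly=float(qaly.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        n_individuals=n,
    )
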