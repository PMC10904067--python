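"""Deterministic and probabilistic sensitivity analysis.

One-way analysis perturbs each uncertain parameter to the ends of its
range (±10% for probabilities, utilities and test accuracy; ±20% or ±50%
for costs depending on the cost class) and records the resulting ICUR
swing, producing a tornado ordering.  Probabilistic analysis draws every
uncertain parameter from a method-of-moments beta (probabilities,
utilities, prevalence, accuracy) or gamma (costs) distribution, reruns all
strategies per draw, and summarizes ICUR uncertainty with percentile
bootstrap intervals and cost-effectiveness acceptability curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cea
from .markov_engine import run_cohort
from .parameters import (
    ModelParameters,
    ParamRef,
    iter_uncertain_parameters,
    repair_parameters,
    validate_parameters,
)
from .screening import ScreeningPolicy

_Z95 = 1.959964  # normal quantile backing the 95% interval -> sd conversion


class DistributionFitError(ValueError):
    """The stated mean/interval cannot be matched by the requested family."""


@dataclass
class ParameterDistribution:
    """A fitted sampling distribution for one uncertain parameter."""

    name: str
    base: float
    lo95: float
    hi95: float
    family: str  # beta | gamma | fixed
    shape: tuple[float, ...] = ()

    @property
    def sd(self) -> float:
        return (self.hi95 - self.lo95) / (2.0 * _Z95)

    def mean(self) -> float:
        if self.family == "beta":
            a, b = self.shape
            return a / (a + b)
        if self.family == "gamma":
            k, theta = self.shape
            return k * theta
        return self.base

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "beta":
            return rng.beta(*self.shape, size=size)
        if self.family == "gamma":
            return rng.gamma(self.shape[0], self.shape[1], size=size)
        if size is None:
            return self.base
        return np.full(size, self.base)


def fit_distribution(
    base: float, lo95: float, hi95: float, family: str, name: str = ""
) -> ParameterDistribution:
    """Method-of-moments fit with mean ``base`` and sd (hi95-lo95)/(2*1.96).

    A zero-width interval degenerates to a fixed (point-mass) parameter.
    """
    if not lo95 <= base <= hi95:
        raise DistributionFitError(
            f"{name or 'parameter'}: base {base} outside [{lo95}, {hi95}]"
        )
    sd = (hi95 - lo95) / (2.0 * _Z95)
    var = sd * sd
    if var == 0.0 or family == "fixed":
        return ParameterDistribution(name, base, lo95, hi95, "fixed")
    m = base
    if family == "beta":
        if not 0.0 < m < 1.0:
            raise DistributionFitError(
                f"{name or 'parameter'}: beta mean must be in (0, 1), got {m}"
            )
        if var >= m * (1.0 - m):
            raise DistributionFitError(
                f"{name or 'parameter'}: variance {var:.3g} too large for a beta "
                f"with mean {m} (needs var < {m * (1 - m):.3g})"
            )
        nu = m * (1.0 - m) / var - 1.0
        return ParameterDistribution(name, base, lo95, hi95, "beta", (m * nu, (1 - m) * nu))
    if family == "gamma":
        if m <= 0:
            raise DistributionFitError(
                f"{name or 'parameter'}: gamma mean must be > 0, got {m}"
            )
        return ParameterDistribution(name, base, lo95, hi95, "gamma", (m * m / var, var / m))
    raise DistributionFitError(f"unknown family {family!r} for {name or 'parameter'}")


def fit_all_distributions(params: ModelParameters) -> list[tuple[ParamRef, ParameterDistribution]]:
    out = []
    for ref in iter_uncertain_parameters(params):
        v = ref.get(params)
        out.append((ref, fit_distribution(v.base, v.lo, v.hi, ref.family, ref.name)))
    return out


# ---------------------------------------------------------------------------
# one-way deterministic sensitivity analysis


@dataclass
class TornadoEntry:
    """ICUR swing when one parameter moves across its one-way range."""

    name: str
    low_input: float
    high_input: float
    icur_low: float
    icur_high: float

    @property
    def span(self) -> float:
        if np.isnan(self.icur_low) or np.isnan(self.icur_high):
            return 0.0
        return abs(self.icur_high - self.icur_low)


def _icur_at(
    params: ModelParameters,
    comparator: ScreeningPolicy,
    reference: ScreeningPolicy,
) -> float:
    _, res_ref = run_cohort(params, reference)
    _, res_cmp = run_cohort(params, comparator)
    return cea.icur(res_cmp, res_ref, wtp_1x=params.economics.wtp_1x).icur


def one_way_dsa(
    params: ModelParameters,
    comparator: ScreeningPolicy,
    reference: ScreeningPolicy = ScreeningPolicy("none"),
) -> list[TornadoEntry]:
    """Tornado table for one pairwise comparison, sorted by decreasing span.

    Each parameter is set in turn to base*(1 - f) and base*(1 + f), clipped
    to its support; joint invariants are repaired by clipping (never by
    aborting), and both strategies are rerun.
    """
    entries = []
    for ref in iter_uncertain_parameters(params):
        base = ref.get(params).base
        f = ref.dsa_fraction(params)
        lo_sup, hi_sup = ref.support()
        bounds = (
            float(np.clip(base * (1.0 - f), lo_sup, hi_sup)),
            float(np.clip(base * (1.0 + f), lo_sup, hi_sup)),
        )
        icurs = []
        for bound in bounds:
            perturbed = params.copy()
            ref.set_base(perturbed, bound)
            repair_parameters(perturbed)
            icurs.append(_icur_at(perturbed, comparator, reference))
        entries.append(
            TornadoEntry(
                name=ref.name,
                low_input=bounds[0],
                high_input=bounds[1],
                icur_low=icurs[0],
                icur_high=icurs[1],
            )
        )
    entries.sort(key=lambda e: e.span, reverse=True)
    return entries


def tornado_table(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.name,
                "low_input": e.low_input,
                "high_input": e.high_input,
                "icur_at_low": e.icur_low,
                "icur_at_high": e.icur_high,
                "span": e.span,
            }
            for e in entries
        ]
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass
class PsaComparisonSummary:
    """Distributional summary of one pairwise comparison over PSA draws."""

    name: str
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    icur_draws: np.ndarray          # defined-ICUR draws only
    fraction_undefined: float
    icur_ci: tuple[float, float]
    lambdas: np.ndarray
    ceac: np.ndarray
    p_dominant: float               # comparator cheaper AND more effective

    def acceptability_at(self, wtp: float) -> float:
        """Fraction of draws with positive net monetary benefit at ``wtp``."""
        return float(np.mean(wtp * self.delta_qaly - self.delta_cost > 0.0))


@dataclass
class PsaResult:
    policy_labels: list[str]
    costs: np.ndarray               # (n_iter, n_policies)
    qalys: np.ndarray
    comparisons: dict[str, PsaComparisonSummary]
    n_redraws: int
    seed: int
    draws: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_iter(self) -> int:
        return self.costs.shape[0]


def _policy_label(p: ScreeningPolicy) -> str:
    if p.strategy == "none":
        return "none"
    return f"{p.strategy}_{'oneoff' if p.interval is None else f'{p.interval}y'}"


def run_psa(
    params: ModelParameters,
    policies: list[ScreeningPolicy],
    n_iter: int = 1000,
    seed: int = 0,
    comparisons: list[tuple[int, int]] | None = None,
    lambdas: np.ndarray | None = None,
    keep_draws: bool = False,
) -> PsaResult:
    """Probabilistic sensitivity analysis.

    Per iteration every uncertain parameter is drawn independently from its
    fitted distribution (complement rows recomputed, see the parameters
    module); a draw violating a joint invariant is rejected and redrawn.
    All policies are rerun per draw.  ``comparisons`` are (comparator,
    reference) indices into ``policies`` and default to everything vs the
    first policy plus each policy vs its predecessor.  Reproducible given
    ``seed``.
    """
    if n_iter < 2:
        raise ValueError(f"n_iter must be >= 2, got {n_iter}")
    fits = fit_all_distributions(params)
    rng = np.random.default_rng(seed)
    if lambdas is None:
        lambdas = np.linspace(0.0, 3.0 * params.economics.wtp_1x, 61)
    lambdas = np.asarray(lambdas, dtype=float)

    n_pol = len(policies)
    costs = np.zeros((n_iter, n_pol))
    qalys = np.zeros((n_iter, n_pol))
    n_redraws = 0
    draw_rows = [] if keep_draws else None

    for i in range(n_iter):
        for _attempt in range(1000):
            drawn = params.copy()
            for ref, dist in fits:
                ref.set_base(drawn, float(dist.sample(rng)))
            for modality, test in drawn.tests.items():
                test.normal_called_normal.base = 1.0 - test.normal_called_npdr.base
            if not validate_parameters(drawn, fixture_checks=False):
                break
            n_redraws += 1
        else:  # pragma: no cover
            raise RuntimeError("could not draw a valid parameter set in 1000 attempts")
        if keep_draws:
            draw_rows.append(
                {ref.name: ref.get(drawn).base for ref, _ in fits}
            )
        for j, policy in enumerate(policies):
            _, res = run_cohort(drawn, policy)
            costs[i, j] = res.cost_per_person
            qalys[i, j] = res.qalys_per_person

    if comparisons is None:
        comparisons = [(j, 0) for j in range(1, n_pol)]
        comparisons += [(j, j - 1) for j in range(2, n_pol)]

    summaries = {}
    for c_idx, r_idx in comparisons:
        dc = costs[:, c_idx] - costs[:, r_idx]
        dq = qalys[:, c_idx] - qalys[:, r_idx]
        defined = np.abs(dq) > cea.DELTA_QALY_TOL
        icur_draws = dc[defined] / dq[defined]
        ci = (
            (float(np.percentile(icur_draws, 2.5)), float(np.percentile(icur_draws, 97.5)))
            if icur_draws.size
            else (float("nan"), float("nan"))
        )
        ceac = np.array([np.mean(lam * dq - dc > 0.0) for lam in lambdas])
        name = f"{_policy_label(policies[c_idx])}_vs_{_policy_label(policies[r_idx])}"
        summaries[name] = PsaComparisonSummary(
            name=name,
            delta_cost=dc,
            delta_qaly=dq,
            icur_draws=icur_draws,
            fraction_undefined=float(1.0 - defined.mean()),
            icur_ci=ci,
            lambdas=lambdas,
            ceac=ceac,
            p_dominant=float(np.mean((dc < 0) & (dq > 0))),
        )

    return PsaResult(
        policy_labels=[_policy_label(p) for p in policies],
        costs=costs,
        qalys=qalys,
        comparisons=summaries,
        n_redraws=n_redraws,
        seed=seed,
        draws=pd.DataFrame(draw_rows) if keep_draws else None,
    )


def psa_outcomes_table(result: PsaResult) -> pd.DataFrame:
    """Per-iteration cost/QALY pairs for every strategy (delimited export)."""
    cols = {}
    for j, label in enumerate(result.policy_labels):
        cols[f"cost_{label}"] = result.costs[:, j]
        cols[f"qaly_{label}"] = result.qalys[:, j]
    df = pd.DataFrame(cols)
    df.insert(0, "iteration", np.arange(result.n_iter))
    return df


def ceac_table(summary: PsaComparisonSummary) -> pd.DataFrame:
    return pd.DataFrame({"wtp": summary.lambdas, "probability": summary.ceac})
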