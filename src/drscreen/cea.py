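"""Incremental cost-utility comparisons and threshold verdicts.

The incremental cost-utility ratio (ICUR) of a comparator strategy against
a reference is the difference in discounted per-person costs divided by the
difference in discounted per-person QALYs.  A comparator that costs less
and gains QALYs dominates (no ratio is needed); the reverse is dominated.
An intervention is called significantly cost-effective below one times
per-capita GDP per QALY and cost-effective below three times (the WHO
convention); the thresholds come from the setting's economic parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import isnan

import pandas as pd

from .markov_engine import StrategyResult

#: QALY differences smaller than this are treated as zero (guards the ratio)
DELTA_QALY_TOL = 1e-9


@dataclass
class CeaComparison:
    """One pairwise incremental comparison.

    ``dominance`` is ``None`` for an ordinary ratio, 'comparator_dominant'
    (cheaper and more effective), 'reference_dominant' (pricier and less
    effective), or 'undefined' (no QALY difference but a cost difference).
    """

    comparator: StrategyResult
    reference: StrategyResult
    delta_cost: float
    delta_qaly: float
    icur: float
    dominance: str | None
    wtp_1x: float
    wtp_3x: float

    @property
    def significantly_cost_effective(self) -> bool:
        return self._cost_effective(self.wtp_1x)

    @property
    def cost_effective(self) -> bool:
        return self._cost_effective(self.wtp_3x)

    def _cost_effective(self, wtp: float) -> bool:
        """Whether the comparator is preferred to the reference at ``wtp``.

        Equivalent to positive net monetary benefit: in the north-east
        quadrant the ratio must fall below the threshold, in the south-west
        quadrant the savings per QALY forgone must exceed it.
        """
        if self.dominance == "comparator_dominant":
            return True
        if self.dominance in ("reference_dominant", "undefined"):
            return False
        if abs(self.delta_qaly) <= DELTA_QALY_TOL:
            return False  # equivalent strategies: no gain to pay for
        return self.nmb(wtp) > 0

    def nmb(self, wtp: float) -> float:
        """Net monetary benefit of the comparator at willingness-to-pay ``wtp``."""
        return wtp * self.delta_qaly - self.delta_cost

    @property
    def label(self) -> str:
        return f"{self.comparator.strategy} vs {self.reference.strategy}"


def icur(comparator: StrategyResult, reference: StrategyResult, wtp_1x: float) -> CeaComparison:
    """Incremental comparison of two strategy results from the same setting."""
    if comparator.setting != reference.setting:
        raise ValueError(
            f"cannot compare settings {comparator.setting!r} and {reference.setting!r}"
        )
    dc = comparator.cost_per_person - reference.cost_per_person
    dq = comparator.qalys_per_person - reference.qalys_per_person
    dominance = None
    if dc < 0 and dq > DELTA_QALY_TOL:
        dominance = "comparator_dominant"
    elif dc > 0 and dq < -DELTA_QALY_TOL:
        dominance = "reference_dominant"
    elif abs(dq) <= DELTA_QALY_TOL:
        dominance = None if abs(dc) <= 1e-12 else "undefined"
    ratio = dc / dq if abs(dq) > DELTA_QALY_TOL else float("nan")
    return CeaComparison(
        comparator=comparator,
        reference=reference,
        delta_cost=dc,
        delta_qaly=dq,
        icur=ratio,
        dominance=dominance,
        wtp_1x=wtp_1x,
        wtp_3x=3.0 * wtp_1x,
    )


def interval_recommendation(
    results: list[StrategyResult], wtp: float
) -> StrategyResult:
    """Recommended screening interval by stepwise shortening.

    ``results`` must be ordered by decreasing interval (longest first), all
    from the same setting and strategy.  Walking toward shorter intervals,
    each shortening is accepted when its pairwise ICUR against the last
    accepted interval falls below ``wtp`` (or when it dominates outright);
    the shortest accepted interval is returned.
    """
    if len(results) < 2:
        raise ValueError("need at least two interval results to compare")
    settings = {r.setting for r in results}
    strategies = {r.strategy for r in results}
    if len(settings) > 1 or len(strategies) > 1:
        raise ValueError("interval results must share one setting and one strategy")
    intervals = [float("inf") if r.interval is None else r.interval for r in results]
    # one-off is the least intensive option and therefore sorts first
    order = sorted(range(len(results)), key=lambda i: -intervals[i])
    if order != list(range(len(results))):
        raise ValueError("results must be ordered from longest to shortest interval")
    accepted = results[0]
    for candidate in results[1:]:
        cmp = icur(candidate, accepted, wtp_1x=wtp)
        if cmp.dominance == "comparator_dominant" or (
            cmp.delta_qaly > DELTA_QALY_TOL and not isnan(cmp.icur) and cmp.icur < wtp
        ):
            accepted = candidate
    return accepted


def comparison_table(comparisons: list[CeaComparison]) -> pd.DataFrame:
    """Delimited-export form of a list of comparisons."""
    rows = []
    for c in comparisons:
        rows.append(
            {
                "setting": c.comparator.setting,
                "comparator": c.comparator.strategy,
                "comparator_interval": c.comparator.interval_label,
                "reference": c.reference.strategy,
                "reference_interval": c.reference.interval_label,
                "delta_cost": c.delta_cost,
                "delta_qaly": c.delta_qaly,
                "icur": c.icur,
                "dominance": c.dominance or "",
                "significantly_cost_effective": c.significantly_cost_effective,
                "cost_effective": c.cost_effective,
            }
        )
    return pd.DataFrame(rows)
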