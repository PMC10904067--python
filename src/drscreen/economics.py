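"""Closed-form economic and epidemiologic conversions.

Capital-cost annualization (annuity method), per-person programme costing,
currency conversion, and the standard rate/probability conversion used to
turn multi-year cumulative incidence into an annual probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

#: CNY per USD, People's Bank of China 2020 reference rate.
DEFAULT_EXCHANGE_RATE = 6.9762

#: annual discount rate used for costs, utilities, and capital annualization
DEFAULT_DISCOUNT_RATE = 0.035

#: useful life (years) assumed for screening-programme capital items
DEFAULT_CAPITAL_LIFE_YEARS = 5


@dataclass(frozen=True)
class AnnualizationSpec:
    """A capital item to be converted to an equivalent annual cost."""

    replacement_cost: float
    r: float = DEFAULT_DISCOUNT_RATE
    n: int = DEFAULT_CAPITAL_LIFE_YEARS


@dataclass(frozen=True)
class IncidenceInterval:
    """Cumulative incidence ``p`` observed over ``t`` years."""

    p: float
    t: float


def annualization_factor(r: float, n: int) -> float:
    """Annuity factor ((1+r)^n - 1) / (r (1+r)^n).

    Dividing a purchase price by this factor spreads it over ``n`` years of
    useful life at discount rate ``r``.  Equal to the sum of the discount
    factors (1+r)^-k for k = 1..n; continuous at r -> 0 where it equals n.
    """
    if n < 1:
        raise ValueError(f"useful life n must be >= 1 year, got {n}")
    if r < 0:
        raise ValueError(f"discount rate must be >= 0, got {r}")
    if r == 0:
        return float(n)
    # algebraically ((1+r)^n - 1)/(r (1+r)^n); this form stays stable as r -> 0
    return -math.expm1(-n * math.log1p(r)) / r


def annualize_capital(spec: AnnualizationSpec, rounding: str = "published") -> float:
    """Equivalent annual cost of a capital item.

    ``rounding="published"`` first truncates the annuity factor to two decimals
    (4.5150... -> 4.51 at r=0.035, n=5), which is the convention the
    packaged cost tables were produced under; ``rounding="exact"`` uses the
    full-precision factor.
    """
    if spec.replacement_cost < 0:
        raise ValueError("replacement cost must be >= 0")
    factor = annualization_factor(spec.r, spec.n)
    if rounding == "published":
        factor = math.floor(factor * 100.0) / 100.0
    elif rounding != "exact":
        raise ValueError(f"rounding must be 'published' or 'exact', got {rounding!r}")
    return spec.replacement_cost / factor


def annualize_line_items(
    items: pd.DataFrame,
    r: float = DEFAULT_DISCOUNT_RATE,
    life_years: int = DEFAULT_CAPITAL_LIFE_YEARS,
    rounding: str = "published",
) -> pd.DataFrame:
    """Return ``items`` with an ``annual_cost_usd`` column filled in.

    Expected columns: ``item``, ``kind`` ("capital" or "recurring"),
    ``units``, ``unit_cost_usd``, ``annual_cost_usd``.  Capital rows are
    annualized from units x unit cost; recurring rows keep their stated
    annual cost (or units x unit cost when no annual figure is given).
    """
    out = items.copy()
    annual = []
    for row in out.itertuples(index=False):
        kind = row.kind
        if kind == "capital":
            total = float(row.units) * float(row.unit_cost_usd)
            annual.append(annualize_capital(AnnualizationSpec(total, r, life_years), rounding))
        elif kind == "recurring":
            if pd.notna(row.annual_cost_usd):
                annual.append(float(row.annual_cost_usd))
            else:
                annual.append(float(row.units) * float(row.unit_cost_usd))
        else:
            raise ValueError(f"unknown line-item kind {kind!r} for {row.item!r}")
    out["annual_cost_usd"] = annual
    return out


def per_person_screening_cost(
    items: pd.DataFrame,
    n_screened: int,
    r: float = DEFAULT_DISCOUNT_RATE,
    life_years: int = DEFAULT_CAPITAL_LIFE_YEARS,
    rounding: str = "published",
) -> float:
    """Annual programme cost per person screened.

    Sum of annualized capital and annual recurring line items divided by the
    number of people screened per year.
    """
    if n_screened <= 0:
        raise ValueError(f"n_screened must be > 0, got {n_screened}")
    if items.empty:
        return 0.0
    annual = annualize_line_items(items, r, life_years, rounding)
    return float(annual["annual_cost_usd"].sum()) / n_screened


def annual_incidence(p: float, t: float) -> float:
    """Annual event rate from cumulative incidence ``p`` over ``t`` years.

    r = -ln(1 - p) / t, the constant-hazard conversion.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError(f"cumulative incidence must be in [0, 1), got {p}")
    if t <= 0:
        raise ValueError(f"interval length must be > 0 years, got {t}")
    return -math.log1p(-p) / t


def prob_from_rate(r: float, t: float = 1.0) -> float:
    """Probability of at least one event in ``t`` years at constant rate ``r``."""
    if r < 0:
        raise ValueError(f"rate must be >= 0, got {r}")
    if t <= 0:
        raise ValueError(f"interval length must be > 0 years, got {t}")
    return -math.expm1(-r * t)


def cny_to_usd(amount: float, rate: float = DEFAULT_EXCHANGE_RATE) -> float:
    """Convert Chinese yuan to US dollars at ``rate`` CNY per USD."""
    if rate <= 0:
        raise ValueError(f"exchange rate must be > 0, got {rate}")
    return amount / rate
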