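"""Typed parameter containers, validation, and config I/O.

Every uncertain scalar is stored as a :class:`Value` (base, lo95, hi95).
Packaged fixtures ship a complete parameter set per setting (rural/urban):
disease prevalence, annual transition probabilities, health-state utilities,
screening-test characteristics for the community and telemedicine
modalities, itemized programme costs, mortality inputs, and economic
settings.  Compliance rates and the background life table are synthetic
assumptions (documented in the fixtures and methods note), not published
estimates.

Config files are YAML with the same structure as the packaged fixtures;
:func:`load_parameters` fills any missing section from the packaged fixture
for the requested setting and validates the result.
"""

from __future__ import annotations

import copy
import importlib.resources as resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator

import numpy as np
import pandas as pd
import yaml

from . import economics
from .states import HealthState

SETTINGS = ("rural", "urban")
MODALITIES = ("community", "telemedicine")


class ConfigurationError(ValueError):
    """A config file is missing a required key or cannot be interpreted."""


class ValidationError(ValueError):
    """A parameter value violates a model invariant."""


@dataclass
class Value:
    """An uncertain scalar: point estimate with a 95% interval."""

    base: float
    lo95: float | None = None
    hi95: float | None = None

    @property
    def lo(self) -> float:
        return self.base if self.lo95 is None else self.lo95

    @property
    def hi(self) -> float:
        return self.base if self.hi95 is None else self.hi95

    def as_list(self) -> list[float]:
        if self.lo95 is None and self.hi95 is None:
            return [self.base]
        return [self.base, self.lo, self.hi]


def _value(raw, key: str) -> Value:
    if isinstance(raw, Value):
        return raw
    if isinstance(raw, (int, float)):
        return Value(float(raw))
    if isinstance(raw, (list, tuple)):
        if len(raw) == 1:
            return Value(float(raw[0]))
        if len(raw) == 3:
            return Value(float(raw[0]), float(raw[1]), float(raw[2]))
    raise ConfigurationError(
        f"parameter {key!r} must be a number or [base, lo95, hi95], got {raw!r}"
    )


@dataclass
class PrevalenceSet:
    """Baseline prevalence of each retinopathy stage among diabetic patients."""

    setting: str
    npdr: Value
    pdr: Value
    dme: Value


@dataclass
class TransitionProbs:
    """Annual disease-progression probabilities."""

    normal_to_npdr: Value
    normal_to_pdr: Value
    npdr_to_pdr: Value
    npdr_to_dme: Value
    pdr_to_dme: Value
    pdr_to_svi: Value
    dme_to_svi: Value
    treated_pdr_to_svi: Value
    treated_dme_to_svi: Value


@dataclass
class UtilitySet:
    """QALY weights per health state (death is 0 by convention)."""

    no_dr: Value
    npdr: Value
    pdr: Value
    dme: Value
    svi: Value

    def weight(self, health: HealthState) -> float:
        if health is HealthState.DEATH:
            return 0.0
        return getattr(self, health.value).base


@dataclass
class TestCharacteristics:
    """Misclassification profile of one screening modality.

    Grade calling is expressed as the probability of each called grade given
    the true state; DME detection is a separate sensitivity/specificity pair
    layered on top of grade calling.
    """

    modality: str
    normal_called_npdr: Value
    normal_called_normal: Value
    npdr_called_normal: Value
    pdr_called_npdr: Value
    pdr_called_normal: Value
    dme_sensitivity: Value
    dme_specificity: Value


@dataclass
class CostSet:
    """All monetary inputs, in 2020 USD.

    ``screening_per_person`` is derived at load time from the itemized
    programme tables (annualized capital plus recurring costs divided by the
    annual screening volume).
    """

    screening_per_person: dict[str, Value]
    screening_items: dict[str, pd.DataFrame]
    hospital_exam_total: Value
    hospital_exam_items: pd.DataFrame
    photocoagulation: Value
    anti_vegf: Value
    followup_maintain: Value
    svi_first_year: Value
    svi_subsequent_year: Value
    uncertainty_fraction: dict[str, float] = field(default_factory=dict)


@dataclass
class MortalityModel:
    """Background mortality schedule and disease hazard multipliers.

    ``svi_multiplier_mode``: 'replace' applies rr_svi instead of rr_diabetes
    for visually impaired patients; 'multiply' stacks the two multipliers.
    """

    ages: np.ndarray
    q: np.ndarray
    rr_diabetes: Value
    rr_svi: Value
    svi_multiplier_mode: str = "replace"
    life_table_spec: dict | None = None

    def background_q(self, age: float) -> float:
        if age < self.ages[0]:
            raise ValueError(
                f"age {age} below the mortality schedule (starts at {self.ages[0]})"
            )
        idx = min(int(age - self.ages[0]), len(self.q) - 1)
        return float(self.q[idx])


@dataclass
class Compliance:
    """Screening uptake and referral acceptance (synthetic assumptions)."""

    uptake: Value
    referral_acceptance: Value


@dataclass
class EconomicSettings:
    discount_rate: float = 0.035
    n_cycles: int = 30
    cycle_length_years: float = 1.0
    start_age: int = 50
    persons_screened_per_year: int = 20000
    exchange_rate_cny_per_usd: float = economics.DEFAULT_EXCHANGE_RATE
    wtp_1x: float = 7000.0
    compliance: Compliance | None = None

    @property
    def wtp_3x(self) -> float:
        return 3.0 * self.wtp_1x


@dataclass
class ModelOptions:
    """Structural switches for points the evidence base leaves open."""

    treated_pdr_to_dme: bool = False
    dme_false_positive_referrals: bool = False


@dataclass
class ModelParameters:
    """The complete, validated parameter set for one setting."""

    setting: str
    prevalence: PrevalenceSet
    transitions: TransitionProbs
    utilities: UtilitySet
    tests: dict[str, TestCharacteristics]
    costs: CostSet
    mortality: MortalityModel
    economics: EconomicSettings
    options: ModelOptions = field(default_factory=ModelOptions)

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# loading


def _data_path(name: str) -> Path:
    return Path(str(resources.files("drscreen").joinpath("data", name)))


def packaged_fixture_path(setting: str) -> Path:
    if setting not in SETTINGS:
        raise ConfigurationError(f"unknown setting {setting!r}; expected one of {SETTINGS}")
    return _data_path(f"{setting}.yaml")


def _load_life_table(spec: dict) -> tuple[np.ndarray, np.ndarray]:
    kind = spec.get("kind", "gompertz")
    if kind == "gompertz":
        # imported lazily: synthetic_data depends on this module
        from .synthetic_data import make_life_table

        table = make_life_table(
            a=float(spec.get("a", 0.004)),
            b=float(spec.get("b", 0.085)),
            age_min=int(spec.get("age_min", 50)),
            age_max=int(spec.get("age_max", 110)),
        )
        return table.ages, table.q
    if kind == "table":
        ages = np.asarray(spec["ages"], dtype=float)
        q = np.asarray(spec["q"], dtype=float)
        if len(ages) != len(q):
            raise ConfigurationError("life table 'ages' and 'q' must have equal length")
        return ages, q
    if kind == "file":
        df = pd.read_csv(spec["path"])
        return df["age"].to_numpy(dtype=float), df["q"].to_numpy(dtype=float)
    raise ConfigurationError(f"unknown life table kind {kind!r}")


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ConfigurationError(f"missing required key {key!r} in {context}")
    return mapping[key]


def _build_costs(raw: dict, econ: EconomicSettings) -> CostSet:
    items = {
        "community": pd.read_csv(_data_path("community_screening_items.csv")),
        "telemedicine": pd.read_csv(_data_path("telemedicine_screening_items.csv")),
    }
    frac = dict(raw.get("uncertainty_fraction", {}))
    f_screen = float(frac.get("screening", 0.20))
    per_person = {}
    for modality, table in items.items():
        override = raw.get(f"screening_per_person_{modality}")
        if override is not None:
            base = float(override)
        else:
            base = economics.per_person_screening_cost(
                table,
                econ.persons_screened_per_year,
                r=econ.discount_rate,
            )
        per_person[modality] = Value(base, base * (1 - f_screen), base * (1 + f_screen))

    def cost_value(key: str) -> Value:
        base = float(_require(raw, key, "costs"))
        f = float(frac.get(key, 0.50))
        return Value(base, base * (1 - f), base * (1 + f))

    return CostSet(
        screening_per_person=per_person,
        screening_items=items,
        hospital_exam_total=cost_value("hospital_exam_total"),
        hospital_exam_items=pd.read_csv(_data_path("hospital_exam_items.csv")),
        photocoagulation=cost_value("photocoagulation"),
        anti_vegf=cost_value("anti_vegf"),
        followup_maintain=cost_value("followup_maintain"),
        svi_first_year=cost_value("svi_first_year"),
        svi_subsequent_year=cost_value("svi_subsequent_year"),
        uncertainty_fraction=frac,
    )


def _from_mapping(doc: dict) -> ModelParameters:
    setting = _require(doc, "setting", "config root")
    if setting not in SETTINGS:
        raise ConfigurationError(f"unknown setting {setting!r}; expected one of {SETTINGS}")

    prev_raw = _require(doc, "prevalence", "config root")
    prevalence = PrevalenceSet(
        setting=setting,
        npdr=_value(_require(prev_raw, "npdr", "prevalence"), "prevalence.npdr"),
        pdr=_value(_require(prev_raw, "pdr", "prevalence"), "prevalence.pdr"),
        dme=_value(_require(prev_raw, "dme", "prevalence"), "prevalence.dme"),
    )

    trans_raw = _require(doc, "transitions", "config root")
    transitions = TransitionProbs(
        **{
            k: _value(_require(trans_raw, k, "transitions"), f"transitions.{k}")
            for k in TransitionProbs.__dataclass_fields__
        }
    )

    util_raw = _require(doc, "utilities", "config root")
    utilities = UtilitySet(
        **{
            k: _value(_require(util_raw, k, "utilities"), f"utilities.{k}")
            for k in UtilitySet.__dataclass_fields__
        }
    )

    tests_raw = _require(doc, "tests", "config root")
    tests = {}
    for modality in MODALITIES:
        t_raw = _require(tests_raw, modality, "tests")
        kwargs = {
            k: _value(_require(t_raw, k, f"tests.{modality}"), f"tests.{modality}.{k}")
            for k in TestCharacteristics.__dataclass_fields__
            if k != "modality"
        }
        tests[modality] = TestCharacteristics(modality=modality, **kwargs)

    econ_raw = _require(doc, "economics", "config root")
    comp_raw = _require(doc, "compliance", "config root")
    compliance = Compliance(
        uptake=_value(_require(comp_raw, "uptake", "compliance"), "compliance.uptake"),
        referral_acceptance=_value(
            _require(comp_raw, "referral_acceptance", "compliance"),
            "compliance.referral_acceptance",
        ),
    )
    econ = EconomicSettings(
        discount_rate=float(_require(econ_raw, "discount_rate", "economics")),
        n_cycles=int(_require(econ_raw, "n_cycles", "economics")),
        cycle_length_years=float(econ_raw.get("cycle_length_years", 1.0)),
        start_age=int(_require(econ_raw, "start_age", "economics")),
        persons_screened_per_year=int(
            econ_raw.get("persons_screened_per_year", 20000)
        ),
        exchange_rate_cny_per_usd=float(
            econ_raw.get("exchange_rate_cny_per_usd", economics.DEFAULT_EXCHANGE_RATE)
        ),
        wtp_1x=float(_require(econ_raw, "wtp_1x_usd_per_qaly", "economics")),
        compliance=compliance,
    )

    costs = _build_costs(_require(doc, "costs", "config root"), econ)

    mort_raw = _require(doc, "mortality", "config root")
    lt_spec = _require(mort_raw, "life_table", "mortality")
    ages, q = _load_life_table(lt_spec)
    mortality = MortalityModel(
        ages=ages,
        q=q,
        rr_diabetes=_value(_require(mort_raw, "rr_diabetes", "mortality"), "rr_diabetes"),
        rr_svi=_value(_require(mort_raw, "rr_svi", "mortality"), "rr_svi"),
        svi_multiplier_mode=mort_raw.get("svi_multiplier_mode", "replace"),
        life_table_spec=lt_spec,
    )

    opt_raw = doc.get("options", {})
    options = ModelOptions(
        treated_pdr_to_dme=bool(opt_raw.get("treated_pdr_to_dme", False)),
        dme_false_positive_referrals=bool(
            opt_raw.get("dme_false_positive_referrals", False)
        ),
    )

    return ModelParameters(
        setting=setting,
        prevalence=prevalence,
        transitions=transitions,
        utilities=utilities,
        tests=tests,
        costs=costs,
        mortality=mortality,
        economics=econ,
        options=options,
    )


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_parameters(path: str | Path | None = None, setting: str = "rural") -> ModelParameters:
    """Load and validate a parameter set.

    ``path=None`` loads the packaged fixture for ``setting``.  A user config
    only needs the keys it overrides; everything else is filled from the
    packaged fixture.  Raises :class:`ConfigurationError` for missing or
    malformed keys and :class:`ValidationError` when a value breaks a model
    invariant.
    """
    with open(packaged_fixture_path(setting)) as fh:
        doc = yaml.safe_load(fh)
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigurationError(f"config file not found: {p}")
        with open(p) as fh:
            user_doc = yaml.safe_load(fh)
        if user_doc is None:
            user_doc = {}
        if not isinstance(user_doc, dict):
            raise ConfigurationError(f"config root of {p} must be a mapping")
        doc = _deep_merge(doc, user_doc)
        doc.setdefault("setting", setting)
    params = _from_mapping(doc)
    violations = validate_parameters(params)
    if violations:
        raise ValidationError("invalid parameters:\n  " + "\n  ".join(violations))
    return params


def write_parameters(params: ModelParameters, path: str | Path) -> None:
    """Serialize a parameter set back to the YAML config dialect.

    Round-trips bit-identically through :func:`load_parameters` for every
    numeric field.
    """
    doc = {
        "setting": params.setting,
        "prevalence": {
            k: getattr(params.prevalence, k).as_list() for k in ("npdr", "pdr", "dme")
        },
        "transitions": {
            k: getattr(params.transitions, k).as_list()
            for k in TransitionProbs.__dataclass_fields__
        },
        "utilities": {
            k: getattr(params.utilities, k).as_list()
            for k in UtilitySet.__dataclass_fields__
        },
        "tests": {
            m: {
                k: getattr(t, k).as_list()
                for k in TestCharacteristics.__dataclass_fields__
                if k != "modality"
            }
            for m, t in params.tests.items()
        },
        "costs": {
            "hospital_exam_total": params.costs.hospital_exam_total.base,
            "photocoagulation": params.costs.photocoagulation.base,
            "anti_vegf": params.costs.anti_vegf.base,
            "followup_maintain": params.costs.followup_maintain.base,
            "svi_first_year": params.costs.svi_first_year.base,
            "svi_subsequent_year": params.costs.svi_subsequent_year.base,
            "uncertainty_fraction": dict(params.costs.uncertainty_fraction),
            "screening_per_person_community": params.costs.screening_per_person[
                "community"
            ].base,
            "screening_per_person_telemedicine": params.costs.screening_per_person[
                "telemedicine"
            ].base,
        },
        "mortality": {
            "rr_diabetes": params.mortality.rr_diabetes.as_list(),
            "rr_svi": params.mortality.rr_svi.as_list(),
            "svi_multiplier_mode": params.mortality.svi_multiplier_mode,
            "life_table": {
                "kind": "table",
                "ages": [float(a) for a in params.mortality.ages],
                "q": [float(x) for x in params.mortality.q],
            },
        },
        "economics": {
            "discount_rate": params.economics.discount_rate,
            "n_cycles": params.economics.n_cycles,
            "cycle_length_years": params.economics.cycle_length_years,
            "start_age": params.economics.start_age,
            "persons_screened_per_year": params.economics.persons_screened_per_year,
            "exchange_rate_cny_per_usd": params.economics.exchange_rate_cny_per_usd,
            "wtp_1x_usd_per_qaly": params.economics.wtp_1x,
        },
        "compliance": {
            "uptake": params.economics.compliance.uptake.as_list(),
            "referral_acceptance": params.economics.compliance.referral_acceptance.as_list(),
        },
        "options": {
            "treated_pdr_to_dme": params.options.treated_pdr_to_dme,
            "dme_false_positive_referrals": params.options.dme_false_positive_referrals,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# validation


def _check_prob(name: str, v: Value, out: list[str], interval_check: bool = True) -> None:
    for tag, x in (("base", v.base), ("lo95", v.lo), ("hi95", v.hi)):
        if not 0.0 <= x <= 1.0:
            out.append(f"{name}.{tag} = {x} outside [0, 1]")
    # base-within-interval is a transcription sanity check: randomly drawn
    # values legitimately land outside their own 95% interval
    if interval_check and not v.lo <= v.base <= v.hi:
        out.append(f"{name}: base {v.base} outside interval [{v.lo}, {v.hi}]")


def validate_parameters(params: ModelParameters, fixture_checks: bool = True) -> list[str]:
    """Return a list of invariant violations (empty iff the set is valid).

    ``fixture_checks=False`` skips the checks that only the transcribed
    point estimates are expected to satisfy — the utility severity ordering
    (PDR and DME share a distribution, so independent draws legitimately
    cross) and the agreement of the hospital-exam total with its printed
    line items — leaving the structural invariants that every runnable
    parameter set must satisfy.
    """
    out: list[str] = []
    p = params.prevalence
    for k in ("npdr", "pdr", "dme"):
        _check_prob(f"prevalence.{k}", getattr(p, k), out, fixture_checks)
    total = p.npdr.base + p.pdr.base + p.dme.base
    if total >= 1.0:
        out.append(f"prevalence sum {total} >= 1 leaves no mass for NO_DR")

    t = params.transitions
    for k in TransitionProbs.__dataclass_fields__:
        _check_prob(f"transitions.{k}", getattr(t, k), out, fixture_checks)
    for origin, keys in (
        ("NO_DR", ("normal_to_npdr", "normal_to_pdr")),
        ("NPDR", ("npdr_to_pdr", "npdr_to_dme")),
        ("PDR", ("pdr_to_dme", "pdr_to_svi")),
    ):
        s = sum(getattr(t, k).base for k in keys)
        if s > 1.0:
            out.append(f"outgoing transition probabilities from {origin} sum to {s} > 1")
    if t.treated_pdr_to_svi.base > t.pdr_to_svi.base:
        out.append(
            "transitions.treated_pdr_to_svi = "
            f"{t.treated_pdr_to_svi.base} > pdr_to_svi = {t.pdr_to_svi.base} "
            "(treatment must not accelerate progression)"
        )
    if t.treated_dme_to_svi.base > t.dme_to_svi.base:
        out.append(
            "transitions.treated_dme_to_svi = "
            f"{t.treated_dme_to_svi.base} > dme_to_svi = {t.dme_to_svi.base} "
            "(treatment must not accelerate progression)"
        )

    u = params.utilities
    for k in UtilitySet.__dataclass_fields__:
        _check_prob(f"utilities.{k}", getattr(u, k), out, fixture_checks)
    if fixture_checks:
        order = [("no_dr", "npdr"), ("npdr", "pdr"), ("pdr", "dme"), ("dme", "svi")]
        for a, b in order:
            ua, ub = getattr(u, a).base, getattr(u, b).base
            if ua < ub - 1e-12:
                out.append(f"utilities.{a} = {ua} < utilities.{b} = {ub} (severity ordering)")

    for modality, test in params.tests.items():
        for k in TestCharacteristics.__dataclass_fields__:
            if k == "modality":
                continue
            _check_prob(f"tests.{modality}.{k}", getattr(test, k), out, fixture_checks)
        if test.normal_called_npdr.base + test.normal_called_normal.base > 1.0 + 1e-12:
            out.append(
                f"tests.{modality}: normal_called_npdr + normal_called_normal = "
                f"{test.normal_called_npdr.base + test.normal_called_normal.base} > 1"
            )
        if test.pdr_called_npdr.base + test.pdr_called_normal.base > 1.0:
            out.append(
                f"tests.{modality}: pdr_called_npdr + pdr_called_normal > 1"
            )

    c = params.costs
    for k in (
        "hospital_exam_total",
        "photocoagulation",
        "anti_vegf",
        "followup_maintain",
        "svi_first_year",
        "svi_subsequent_year",
    ):
        v = getattr(c, k)
        if v.base < 0:
            out.append(f"costs.{k} = {v.base} < 0")
    for modality, v in c.screening_per_person.items():
        if v.base < 0:
            out.append(f"costs.screening_per_person.{modality} = {v.base} < 0")
    if fixture_checks:
        exam_item_sum = float(c.hospital_exam_items["cost_usd"].sum())
        if abs(exam_item_sum - c.hospital_exam_total.base) > 0.005:
            out.append(
                f"hospital exam line items sum to {exam_item_sum}, "
                f"not the stated total {c.hospital_exam_total.base}"
            )

    m = params.mortality
    if np.any(m.q < 0) or np.any(m.q > 1):
        out.append("mortality.q outside [0, 1]")
    if np.any(np.diff(m.q) < -1e-12):
        out.append("mortality.q not nondecreasing over the modelled age range")
    for k in ("rr_diabetes", "rr_svi"):
        if getattr(m, k).base < 1.0:
            out.append(f"mortality.{k} = {getattr(m, k).base} < 1 (protective multiplier)")
    if m.svi_multiplier_mode not in ("replace", "multiply"):
        out.append(f"mortality.svi_multiplier_mode {m.svi_multiplier_mode!r} unknown")

    e = params.economics
    if e.discount_rate < 0:
        out.append(f"economics.discount_rate = {e.discount_rate} < 0")
    if e.n_cycles < 1:
        out.append(f"economics.n_cycles = {e.n_cycles} < 1")
    if e.wtp_1x <= 0:
        out.append(f"economics.wtp_1x = {e.wtp_1x} <= 0")
    if e.compliance is None:
        out.append("economics.compliance missing")
    else:
        _check_prob("compliance.uptake", e.compliance.uptake, out, fixture_checks)
        _check_prob("compliance.referral_acceptance", e.compliance.referral_acceptance, out, fixture_checks)

    return out


# ---------------------------------------------------------------------------
# uncertain-parameter registry (drives one-way DSA and PSA sampling)


@dataclass
class ParamRef:
    """Named handle on one uncertain scalar inside a ModelParameters tree.

    ``family`` is the PSA sampling family ('beta', 'gamma', or 'fixed');
    ``kind`` selects the one-way DSA range class ('probability', 'utility',
    'accuracy', 'cost', 'multiplier').
    """

    name: str
    family: str
    kind: str
    get: Callable[[ModelParameters], Value]
    set_base: Callable[[ModelParameters, float], None]

    def dsa_fraction(self, params: ModelParameters) -> float:
        if self.kind in ("probability", "utility", "accuracy", "multiplier"):
            return 0.10
        frac = params.costs.uncertainty_fraction
        key = self.name.split(".")[-1]
        if self.name.startswith("costs.screening_per_person"):
            key = "screening"
        return float(frac.get(key, 0.50))

    def support(self) -> tuple[float, float]:
        if self.kind in ("probability", "utility", "accuracy"):
            return (0.0, 1.0)
        if self.kind == "multiplier":
            return (1.0, np.inf)
        return (0.0, np.inf)


def _attr_ref(name: str, family: str, kind: str, *path: str) -> ParamRef:
    def get(params: ModelParameters) -> Value:
        obj = params
        for part in path[:-1]:
            obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
        return getattr(obj, path[-1])

    def set_base(params: ModelParameters, x: float) -> None:
        get(params).base = x

    return ParamRef(name, family, kind, get, set_base)


def _screening_cost_ref(modality: str) -> ParamRef:
    name = f"costs.screening_per_person.{modality}"

    def get(params: ModelParameters) -> Value:
        return params.costs.screening_per_person[modality]

    def set_base(params: ModelParameters, x: float) -> None:
        params.costs.screening_per_person[modality].base = x

    return ParamRef(name, "gamma", "cost", get, set_base)


def iter_uncertain_parameters(params: ModelParameters) -> Iterator[ParamRef]:
    """Yield a handle for every uncertain scalar, in a fixed order.

    The order is part of the package contract: PSA draws consume the random
    stream in this order, so it must not depend on runtime state.
    """
    for k in ("npdr", "pdr", "dme"):
        yield _attr_ref(f"prevalence.{k}", "beta", "probability", "prevalence", k)
    for k in TransitionProbs.__dataclass_fields__:
        yield _attr_ref(f"transitions.{k}", "beta", "probability", "transitions", k)
    for k in UtilitySet.__dataclass_fields__:
        yield _attr_ref(f"utilities.{k}", "beta", "utility", "utilities", k)
    for modality in MODALITIES:
        for k in TestCharacteristics.__dataclass_fields__:
            # normal_called_normal is the complement of normal_called_npdr and
            # is recomputed after sampling rather than drawn independently
            if k in ("modality", "normal_called_normal"):
                continue
            yield _attr_ref(
                f"tests.{modality}.{k}", "beta", "accuracy", "tests", modality, k
            )
    yield _attr_ref("compliance.uptake", "beta", "probability",
                    "economics", "compliance", "uptake")
    yield _attr_ref("compliance.referral_acceptance", "beta", "probability",
                    "economics", "compliance", "referral_acceptance")
    for modality in MODALITIES:
        yield _screening_cost_ref(modality)
    for k in (
        "hospital_exam_total",
        "photocoagulation",
        "anti_vegf",
        "followup_maintain",
        "svi_first_year",
        "svi_subsequent_year",
    ):
        yield _attr_ref(f"costs.{k}", "gamma", "cost", "costs", k)
    yield _attr_ref("mortality.rr_diabetes", "fixed", "multiplier",
                    "mortality", "rr_diabetes")
    yield _attr_ref("mortality.rr_svi", "fixed", "multiplier", "mortality", "rr_svi")


def repair_parameters(params: ModelParameters) -> list[str]:
    """Clip dependent fields so the set satisfies its invariants; log actions.

    Used after one-way DSA perturbations: a bound that breaks a joint
    invariant (e.g. treated progression exceeding untreated) is clipped
    rather than aborting the analysis.
    """
    log: list[str] = []
    t = params.transitions
    if t.treated_pdr_to_svi.base > t.pdr_to_svi.base:
        log.append("clipped treated_pdr_to_svi to pdr_to_svi")
        t.treated_pdr_to_svi.base = t.pdr_to_svi.base
    if t.treated_dme_to_svi.base > t.dme_to_svi.base:
        log.append("clipped treated_dme_to_svi to dme_to_svi")
        t.treated_dme_to_svi.base = t.dme_to_svi.base
    p = params.prevalence
    total = p.npdr.base + p.pdr.base + p.dme.base
    if total >= 1.0:
        scale = 0.999 / total
        for k in ("npdr", "pdr", "dme"):
            getattr(p, k).base *= scale
        log.append(f"rescaled prevalence (sum was {total:.4f})")
    for modality, test in params.tests.items():
        # keep the complement row consistent with the drawn false-positive rate
        test.normal_called_normal.base = 1.0 - test.normal_called_npdr.base
        s = test.pdr_called_npdr.base + test.pdr_called_normal.base
        if s > 1.0:
            test.pdr_called_npdr.base /= s
            test.pdr_called_normal.base /= s
            log.append(f"renormalized tests.{modality} PDR calling row (sum was {s:.4f})")
    return log


def parameter_table(params: ModelParameters) -> pd.DataFrame:
    """Flat audit table: one row per uncertain parameter."""
    rows = []
    for ref in iter_uncertain_parameters(params):
        v = ref.get(params)
        rows.append(
            {
                "name": ref.name,
                "base": v.base,
                "lo95": v.lo,
                "hi95": v.hi,
                "family": ref.family,
                "kind": ref.kind,
            }
        )
    return pd.DataFrame(rows)
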