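"""Model parameters: domain types, loading, validation, provenance.

Every quantity the cost-utility model consumes lives in a :class:`ModelConfig`,
the single source of truth for a run.  Each numeric leaf carries a provenance
tag recording whether it comes from a published table, published text, a
figure that was deliberately not transcribed (placeholder), a synthetic
assumption of this package, or a derived complement.  Untagged parameters are
a validation error: the underlying evaluation mixes trial estimates, national
tariffs, expert opinion and pure assumptions, and reports must be able to say
which is which.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator, Optional

import yaml

from .lifetable import LifeTable, generate_gompertz_makeham

ARM_DUPILUMAB = "dupilumab"
ARM_BSC = "bsc"
ARMS = (ARM_DUPILUMAB, ARM_BSC)

#: Allowed provenance tags.  "user" marks values overridden in a user config
#: file without an explicit tag of their own.
PROVENANCE_TAGS = frozenset(
    {"paper-table", "paper-text", "figure-only-placeholder", "synthetic", "derived", "user"}
)

#: Tags that mark values NOT taken from the published evaluation; outputs that
#: depend on them are watermarked.
PLACEHOLDER_TAGS = frozenset({"figure-only-placeholder", "synthetic"})


class ConfigError(ValueError):
    """Raised by :func:`load_config` on parse/validation failure.

    Carries the full violation list, not only the first problem.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "invalid model configuration:\n" + "\n".join(f"  - {v}" for v in self.violations)
        )


@dataclass(frozen=True)
class Violation:
    """One validation failure: which parameter, its value, which rule broke."""

    parameter: str
    value: Any
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.parameter} = {self.value!r}: {self.rule}"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Demographics:
    start_age: float = 51.39
    male_fraction: float = 0.604


@dataclass
class ResponseProbabilities:
    """Arm-specific response probabilities at the two tree assessment points.

    Stored as (week-24 marginal, week-52 conditional on week-24 response)
    because only week-24 responders are re-assessed at week 52.  The published
    source prints these only in a figure, so packaged defaults are
    placeholders and must stay flagged as such.
    """

    p_resp_wk24_dup: float
    p_resp_wk24_bsc: float
    p_resp_wk52_given_wk24_dup: float
    p_resp_wk52_given_wk24_bsc: float
    provenance_note: str = (
        "response probabilities are figure-only placeholders; replace with trial estimates"
    )

    def p24(self, arm: str) -> float:
        _check_arm(arm)
        return self.p_resp_wk24_dup if arm == ARM_DUPILUMAB else self.p_resp_wk24_bsc

    def p52_given_24(self, arm: str) -> float:
        _check_arm(arm)
        return (
            self.p_resp_wk52_given_wk24_dup
            if arm == ARM_DUPILUMAB
            else self.p_resp_wk52_given_wk24_bsc
        )

    @staticmethod
    def conditional_from_marginal(p24: float, p52_marginal: float) -> float:
        """Convert a marginal week-52 response rate to the conditional
        convention used here, assuming all week-52 responders responded at
        week 24 (the tree re-assesses only week-24 responders)."""
        if p24 <= 0:
            raise ValueError("week-24 probability must be positive to condition on it")
        if p52_marginal > p24:
            raise ValueError("marginal week-52 rate cannot exceed the week-24 rate")
        return p52_marginal / p24


@dataclass
class SustainedResponse:
    #: Annual probability a controlled patient keeps responding (expert panel).
    annual_p_sustain: float = 0.98


@dataclass
class SurgeryAccess:
    p_ineligible: float = 0.151
    max_surgery_age: float = 70.0
    annual_p_surgery: float = 0.019
    p_postop_to_uncontrolled: float = 0.40
    p_surgery_to_postop_controlled: float = 1.0

    @property
    def annual_p_stay_eligible(self) -> float:
        # complement of the 1.9% surgery transition (printed as 98.1%)
        return 1.0 - self.annual_p_surgery

    @property
    def p_postop_stay_controlled(self) -> float:
        return 1.0 - self.p_postop_to_uncontrolled


@dataclass
class TreeUtilities:
    """Year-1 utility weights: baseline, treatment-specific weeks 12-24, and
    response-status utilities after the week-24 assessment."""

    u_baseline: float = 0.769
    u_wk12_24_dup: float = 0.875
    u_wk12_24_bsc: float = 0.810
    u_wk24plus_responder: float = 0.891
    u_wk24plus_nonresponder: float = 0.808

    def u_wk12_24(self, arm: str) -> float:
        _check_arm(arm)
        return self.u_wk12_24_dup if arm == ARM_DUPILUMAB else self.u_wk12_24_bsc


@dataclass
class MarkovUtilities:
    u_controlled: float = 0.913
    u_inadequate: float = 0.776
    u_surgery: float = 0.820
    u_postop_controlled: float = 0.827  # inadequate (0.776) + surgery gain 0.051
    u_postop_uncontrolled: float = 0.760
    u_death: float = 0.0


@dataclass
class TreeCosts:
    """Year-1 therapy and medical costs (EUR) by eventual response status and
    half-year (weeks 0-24 / weeks 25-52)."""

    therapy_responder_h1: float = 780.0
    therapy_responder_h2: float = 910.0
    medical_responder_h1: float = 3345.0
    medical_responder_h2: float = 3903.0
    therapy_nonresponder_h1: float = 842.0
    therapy_nonresponder_h2: float = 982.0
    medical_nonresponder_h1: float = 6790.0
    medical_nonresponder_h2: float = 7922.0

    def half_year(self, responder: bool, half: int) -> tuple[float, float]:
        """(therapy, medical) cost for one half-year, half in {1, 2}."""
        if half not in (1, 2):
            raise ValueError(f"half must be 1 or 2, got {half}")
        tag = "responder" if responder else "nonresponder"
        return (
            getattr(self, f"therapy_{tag}_h{half}"),
            getattr(self, f"medical_{tag}_h{half}"),
        )


@dataclass
class MarkovStateCosts:
    """Annual disease-management cost (EUR) per alive long-term health state."""

    controlled: float = 8937.0
    inadequate: float = 16536.0
    postop_controlled: float = 8937.0
    postop_uncontrolled: float = 16536.0
    death: float = 0.0


@dataclass
class DrugCostSpec:
    """Dupilumab acquisition: 300 mg every 2 weeks -> 26 administrations/year.

    The per-administration ex-factory price net of confidential discounts is
    not public, so there is no default: configs must state it explicitly.  The
    published lifetime discounted drug cost (EUR 76,383) can be used by a
    downstream user to back-solve a price under their own assumptions; this
    package never does that silently.
    """

    price_per_administration: Optional[float] = None
    administrations_per_year: int = 26
    compliance: float = 1.0
    bsc_acquisition_cost: float = 0.0
    administration_cost: float = 0.0

    def annual_cost(self, arm: str) -> float:
        _check_arm(arm)
        if arm == ARM_BSC:
            return self.bsc_acquisition_cost
        if self.price_per_administration is None:
            raise ValueError(
                "drug price_per_administration is required for the dupilumab arm "
                "(no default exists; the net price is not public)"
            )
        return (
            self.price_per_administration * self.administrations_per_year * self.compliance
            + self.administration_cost
        )


@dataclass
class AEItem:
    """One adverse-event row: annual incidence per arm and Italian unit cost."""

    name: str
    rate_dup: float
    rate_bsc: float
    unit_cost: float


def default_ae_items() -> list[AEItem]:
    """The five adverse events observed in the pivotal trials, with annual
    incidence rates per arm and Italian unit tariffs (EUR)."""
    return [
        AEItem("injection_site_reaction", 0.395, 0.000, 20.66),
        AEItem("nasopharyngitis", 0.275, 0.287, 16.31),
        AEItem("epistaxis", 0.106, 0.114, 16.31),
        AEItem("headache", 0.092, 0.181, 20.66),
        AEItem("asthma", 0.058, 0.173, 326.48),
    ]


@dataclass
class SurgeryCostSpec:
    ct_scan: float = 104.0
    procedure: float = 2009.0
    annual_followup: float = 103.0
    followup_visits_per_year: int = 5
    visit_tariff: float = 20.66

    @property
    def episode_cost(self) -> float:
        """One surgical episode: CT work-up plus the day-hospital procedure."""
        return self.ct_scan + self.procedure


@dataclass
class IndirectCostSpec:
    """Societal-perspective productivity losses: hours valued at the national
    hourly productivity figure, 8-hour workdays, state-specific days lost."""

    eur_per_hour: float = 29.80
    hours_per_day: float = 8.0
    workdays_lost_per_year_by_state: dict[str, float] = field(default_factory=dict)

    def annual_cost(self, state_name: str) -> float:
        days = self.workdays_lost_per_year_by_state.get(state_name, 0.0)
        return days * self.hours_per_day * self.eur_per_hour


PERSPECTIVE_NHS = "NHS"
PERSPECTIVE_SOCIETAL = "societal"


def default_wtp_grid() -> list[float]:
    """0 to 100,000 EUR/QALY in 500 steps; includes the Italian informal
    acceptability range endpoints (25,000 / 40,000) and midpoint (32,500)."""
    return [float(x) for x in range(0, 100_001, 500)]


@dataclass
class EconSettings:
    discount_rate_costs: float = 0.03
    discount_rate_effects: float = 0.03
    horizon_max_age: float = 110.0
    perspective: str = PERSPECTIVE_NHS
    wtp_grid: list[float] = field(default_factory=default_wtp_grid)


@dataclass
class ModelSwitches:
    """Structural conventions the source leaves open; each is overridable."""

    #: week-52 non-responders accrue responder utility over weeks 24-52 (they
    #: respond until the week-52 assessment) but non-responder costs.
    nr52_responder_utility: bool = True
    #: apply one year of background mortality during the decision tree.
    tree_mortality: bool = False
    #: half-cycle correction in the Markov valuation.
    half_cycle_correction: bool = False
    #: adverse-event costs accrue over the whole alive lifetime (arm-specific
    #: rates); if False they accrue only in year 1.
    ae_costs_lifetime: bool = True
    #: the EUR 103/year surgical follow-up is added on top of the
    #: post-operative state management costs.
    postop_followup_separate: bool = True


@dataclass
class LifeTableSpec:
    """Where background mortality comes from: a CSV (age,qx) or a synthetic
    Gompertz-Makeham schedule."""

    kind: str = "gompertz_makeham"  # or "csv"
    path: Optional[str] = None
    makeham_a: float = 5e-4
    gompertz_b: float = 2e-5
    gompertz_c: float = 0.095
    min_age: int = 0
    max_age: int = 110

    def build(self) -> LifeTable:
        if self.kind == "csv":
            if not self.path:
                raise ValueError("life_table.kind = 'csv' requires life_table.path")
            return LifeTable.from_csv(self.path)
        if self.kind == "gompertz_makeham":
            return generate_gompertz_makeham(
                self.makeham_a, self.gompertz_b, self.gompertz_c, self.min_age, self.max_age
            )
        raise ValueError(f"unknown life_table.kind {self.kind!r}")


@dataclass
class ModelConfig:
    """The complete parameter set for one model run."""

    demographics: Demographics = field(default_factory=Demographics)
    # placeholder response probabilities (figure-only in the source); the
    # packaged fixture re-applies and flags the same values
    response: ResponseProbabilities = field(
        default_factory=lambda: ResponseProbabilities(0.60, 0.25, 0.90, 0.70)
    )
    sustained: SustainedResponse = field(default_factory=SustainedResponse)
    surgery_access: SurgeryAccess = field(default_factory=SurgeryAccess)
    tree_utilities: TreeUtilities = field(default_factory=TreeUtilities)
    markov_utilities: MarkovUtilities = field(default_factory=MarkovUtilities)
    tree_costs: TreeCosts = field(default_factory=TreeCosts)
    markov_state_costs: MarkovStateCosts = field(default_factory=MarkovStateCosts)
    drug: DrugCostSpec = field(default_factory=DrugCostSpec)
    ae_items: list[AEItem] = field(default_factory=default_ae_items)
    surgery_costs: SurgeryCostSpec = field(default_factory=SurgeryCostSpec)
    indirect: IndirectCostSpec = field(default_factory=IndirectCostSpec)
    econ: EconSettings = field(default_factory=EconSettings)
    switches: ModelSwitches = field(default_factory=ModelSwitches)
    life_table: LifeTableSpec = field(default_factory=LifeTableSpec)
    seed: int = 0
    provenance: dict[str, str] = field(default_factory=dict)

    _life_table_cache: Optional[LifeTable] = field(
        default=None, repr=False, compare=False
    )

    def resolve_life_table(self) -> LifeTable:
        if self._life_table_cache is None:
            self._life_table_cache = self.life_table.build()
        return self._life_table_cache

    def copy(self) -> "ModelConfig":
        new = copy.deepcopy(self)
        new._life_table_cache = self._life_table_cache  # tables are immutable
        return new

    # -- provenance helpers -------------------------------------------------

    def placeholder_parameters(self) -> list[tuple[str, str]]:
        """(path, tag) for every parameter not taken from the published
        evaluation; these drive report watermarks."""
        return sorted(
            (p, t) for p, t in self.provenance.items() if t in PLACEHOLDER_TAGS
        )

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("_life_table_cache", None)
        return d


# ---------------------------------------------------------------------------
# Parameter paths (used by validation, OWSA and PSA)
# ---------------------------------------------------------------------------


def iter_numeric_leaves(cfg: ModelConfig) -> Iterator[tuple[str, float]]:
    """Yield (dotted path, value) for every numeric scalar parameter."""

    def walk(prefix: str, obj: Any) -> Iterator[tuple[str, float]]:
        if isinstance(obj, bool):
            return
        if isinstance(obj, (int, float)):
            yield prefix, float(obj)
        elif isinstance(obj, dict):
            for k, v in obj.items():
                yield from walk(f"{prefix}.{k}", v)
        elif isinstance(obj, list):
            for i, v in enumerate(obj):
                yield from walk(f"{prefix}[{i}]", v)

    d = cfg.to_dict()
    for section in (
        "demographics",
        "response",
        "sustained",
        "surgery_access",
        "tree_utilities",
        "markov_utilities",
        "tree_costs",
        "markov_state_costs",
        "drug",
        "ae_items",
        "surgery_costs",
        "indirect",
        "econ",
    ):
        obj = d[section]
        if section == "econ":
            obj = {k: v for k, v in obj.items() if k != "wtp_grid"}
        if section == "drug" and obj.get("price_per_administration") is None:
            obj = dict(obj)
            obj["price_per_administration"] = 0.0  # still enumerated as a path
        yield from walk(section, obj)


def _resolve_parent(cfg: ModelConfig, path: str):
    """Resolve a dotted path with optional [i] indexing to (parent, key)."""
    parts: list[Any] = []
    for token in path.split("."):
        while "[" in token:
            head, rest = token.split("[", 1)
            idx, token = rest.split("]", 1)
            if head:
                parts.append(head)
            parts.append(int(idx))
            token = token.lstrip(".")
        if token:
            parts.append(token)
    obj: Any = cfg
    for p in parts[:-1]:
        if isinstance(p, int):
            obj = obj[p]
        elif isinstance(obj, dict):
            obj = obj[p]
        else:
            obj = getattr(obj, p)
    return obj, parts[-1]


def get_param(cfg: ModelConfig, path: str) -> Any:
    """Fetch a parameter by dotted path, e.g. ``markov_utilities.u_controlled``
    or ``ae_items[0].rate_dup``."""
    try:
        parent, key = _resolve_parent(cfg, path)
        if isinstance(key, int):
            return parent[key]
        if isinstance(parent, dict):
            return parent[key]
        return getattr(parent, key)
    except (AttributeError, KeyError, IndexError, ValueError) as exc:
        raise KeyError(f"parameter path not found: {path!r}") from exc


def set_param(cfg: ModelConfig, path: str, value: Any) -> None:
    try:
        parent, key = _resolve_parent(cfg, path)
        if isinstance(key, int):
            parent[key] = value
        elif isinstance(parent, dict):
            parent[key] = value
        else:
            getattr(parent, key)  # raise if absent
            setattr(parent, key, value)
    except (AttributeError, KeyError, IndexError, ValueError) as exc:
        raise KeyError(f"parameter path not found: {path!r}") from exc


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

_PROBABILITY_FIELDS = [
    "response.p_resp_wk24_dup",
    "response.p_resp_wk24_bsc",
    "response.p_resp_wk52_given_wk24_dup",
    "response.p_resp_wk52_given_wk24_bsc",
    "sustained.annual_p_sustain",
    "surgery_access.p_ineligible",
    "surgery_access.annual_p_surgery",
    "surgery_access.p_postop_to_uncontrolled",
    "surgery_access.p_surgery_to_postop_controlled",
    "drug.compliance",
    "demographics.male_fraction",
]

_UTILITY_FIELDS = [
    f"tree_utilities.{f.name}" for f in dataclasses.fields(TreeUtilities)
] + [f"markov_utilities.{f.name}" for f in dataclasses.fields(MarkovUtilities)]


def validate_config(cfg: ModelConfig) -> list[Violation]:
    """Check every type invariant; violations are returned as data, never
    raised.  An empty list means the configuration is runnable."""
    out: list[Violation] = []

    def check(cond: bool, path: str, value: Any, rule: str) -> None:
        if not cond:
            out.append(Violation(path, value, rule))

    for path in _PROBABILITY_FIELDS:
        v = get_param(cfg, path)
        check(0.0 <= v <= 1.0, path, v, "probability must lie in [0, 1]")
    for path in _UTILITY_FIELDS:
        v = get_param(cfg, path)
        check(0.0 <= v <= 1.0, path, v, "utility weight must lie in [0, 1]")

    lt_spec = cfg.life_table
    check(
        cfg.demographics.start_age > 18,
        "demographics.start_age",
        cfg.demographics.start_age,
        "start age must exceed 18",
    )
    check(
        cfg.demographics.start_age < lt_spec.max_age,
        "demographics.start_age",
        cfg.demographics.start_age,
        "start age must be below the life-table maximum age",
    )

    for path in (
        "tree_costs.therapy_responder_h1",
        "tree_costs.therapy_responder_h2",
        "tree_costs.medical_responder_h1",
        "tree_costs.medical_responder_h2",
        "tree_costs.therapy_nonresponder_h1",
        "tree_costs.therapy_nonresponder_h2",
        "tree_costs.medical_nonresponder_h1",
        "tree_costs.medical_nonresponder_h2",
        "markov_state_costs.controlled",
        "markov_state_costs.inadequate",
        "markov_state_costs.postop_controlled",
        "markov_state_costs.postop_uncontrolled",
        "markov_state_costs.death",
        "surgery_costs.ct_scan",
        "surgery_costs.procedure",
        "surgery_costs.annual_followup",
        "surgery_costs.visit_tariff",
        "drug.bsc_acquisition_cost",
        "drug.administration_cost",
        "indirect.eur_per_hour",
        "indirect.hours_per_day",
    ):
        v = get_param(cfg, path)
        check(v >= 0, path, v, "cost must be non-negative")

    for i, item in enumerate(cfg.ae_items):
        check(item.rate_dup >= 0, f"ae_items[{i}].rate_dup", item.rate_dup, "rate must be >= 0")
        check(item.rate_bsc >= 0, f"ae_items[{i}].rate_bsc", item.rate_bsc, "rate must be >= 0")
        check(
            item.unit_cost >= 0, f"ae_items[{i}].unit_cost", item.unit_cost, "cost must be >= 0"
        )

    price = cfg.drug.price_per_administration
    if price is None:
        out.append(
            Violation(
                "drug.price_per_administration",
                None,
                "required and has no default (the net price is not public)",
            )
        )
    else:
        check(price >= 0, "drug.price_per_administration", price, "price must be >= 0")
    check(
        cfg.drug.administrations_per_year > 0,
        "drug.administrations_per_year",
        cfg.drug.administrations_per_year,
        "administrations per year must be positive",
    )

    sc = cfg.surgery_costs
    expected_followup = round(sc.followup_visits_per_year * sc.visit_tariff)
    check(
        abs(sc.annual_followup - expected_followup) < 0.5 + 1e-9,
        "surgery_costs.annual_followup",
        sc.annual_followup,
        f"must equal round(visits x tariff) = {expected_followup}",
    )

    econ = cfg.econ
    for path in ("econ.discount_rate_costs", "econ.discount_rate_effects"):
        v = get_param(cfg, path)
        check(0.0 <= v < 1.0, path, v, "annual discount rate must lie in [0, 1)")
    check(
        econ.horizon_max_age > cfg.demographics.start_age,
        "econ.horizon_max_age",
        econ.horizon_max_age,
        "horizon must exceed the cohort start age",
    )
    check(
        econ.perspective in (PERSPECTIVE_NHS, PERSPECTIVE_SOCIETAL),
        "econ.perspective",
        econ.perspective,
        "perspective must be 'NHS' or 'societal'",
    )
    if econ.perspective == PERSPECTIVE_SOCIETAL:
        check(
            bool(cfg.indirect.workdays_lost_per_year_by_state),
            "indirect.workdays_lost_per_year_by_state",
            cfg.indirect.workdays_lost_per_year_by_state,
            "societal perspective requires workdays-lost inputs per state",
        )
    for state, days in cfg.indirect.workdays_lost_per_year_by_state.items():
        check(
            days >= 0,
            f"indirect.workdays_lost_per_year_by_state.{state}",
            days,
            "workdays lost must be >= 0",
        )

    # provenance completeness
    for path, _value in iter_numeric_leaves(cfg):
        tag = cfg.provenance.get(path)
        if tag is None:
            out.append(Violation(path, None, "parameter has no provenance tag"))
        elif tag not in PROVENANCE_TAGS:
            out.append(
                Violation(path, tag, f"unknown provenance tag (allowed: {sorted(PROVENANCE_TAGS)})")
            )

    return out


# ---------------------------------------------------------------------------
# Load / save
# ---------------------------------------------------------------------------

_SECTION_TYPES = {
    "demographics": Demographics,
    "response": ResponseProbabilities,
    "sustained": SustainedResponse,
    "surgery_access": SurgeryAccess,
    "tree_utilities": TreeUtilities,
    "markov_utilities": MarkovUtilities,
    "tree_costs": TreeCosts,
    "markov_state_costs": MarkovStateCosts,
    "drug": DrugCostSpec,
    "surgery_costs": SurgeryCostSpec,
    "indirect": IndirectCostSpec,
    "econ": EconSettings,
    "switches": ModelSwitches,
    "life_table": LifeTableSpec,
}

_MONEY_SECTIONS = {"tree_costs", "markov_state_costs", "surgery_costs"}


def _round_money(x: float) -> float:
    return round(float(x), 2)


def config_from_dict(data: dict) -> ModelConfig:
    """Build a ModelConfig from a nested plain dict (already merged with
    defaults where the caller wants them); unknown keys are errors."""
    errors: list[Violation] = []
    kwargs: dict[str, Any] = {}
    known = set(_SECTION_TYPES) | {"ae_items", "seed", "provenance"}
    for key in data:
        if key not in known:
            errors.append(Violation(key, data[key], "unknown configuration section"))
    for section, typ in _SECTION_TYPES.items():
        sub = data.get(section, {})
        if sub is None:
            sub = {}
        if not isinstance(sub, dict):
            errors.append(Violation(section, sub, "section must be a mapping"))
            continue
        names = {f.name for f in dataclasses.fields(typ)}
        bad = set(sub) - names
        for k in bad:
            errors.append(Violation(f"{section}.{k}", sub[k], "unknown configuration key"))
        clean = {k: v for k, v in sub.items() if k in names}
        if section in _MONEY_SECTIONS:
            clean = {
                k: _round_money(v) if isinstance(v, (int, float)) and not isinstance(v, bool) else v
                for k, v in clean.items()
            }
        try:
            kwargs[section] = typ(**clean)
        except (TypeError, ValueError) as exc:
            errors.append(Violation(section, sub, f"cannot construct section: {exc}"))
    ae_raw = data.get("ae_items")
    if ae_raw is None:
        kwargs["ae_items"] = default_ae_items()
    else:
        items = []
        for i, row in enumerate(ae_raw):
            try:
                items.append(AEItem(**row))
            except (TypeError, ValueError) as exc:
                errors.append(Violation(f"ae_items[{i}]", row, f"cannot construct AE item: {exc}"))
        kwargs["ae_items"] = items
    if errors:
        raise ConfigError(errors)
    cfg = ModelConfig(**kwargs)
    cfg.seed = int(data.get("seed", 0))
    cfg.provenance = dict(data.get("provenance") or {})
    return cfg


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path, defaults: Optional[ModelConfig] = None) -> ModelConfig:
    """Load a YAML/JSON configuration file.

    Missing fields are filled from ``defaults`` (the packaged default fixture
    unless another base is given).  Values the file overrides without an
    explicit provenance entry are re-tagged ``user``.  Raises
    :class:`ConfigError` listing *all* schema and invariant violations.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" near line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(
            [Violation(str(path), None, f"cannot parse configuration{where}: {exc}")]
        ) from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError([Violation(str(path), raw, "top level must be a mapping")])

    if defaults is None:
        from .synthetic import default_fixture  # circular at import time only

        defaults = default_fixture().config
    base = defaults.to_dict()
    merged = _deep_merge(base, raw)
    cfg = config_from_dict(merged)

    # retag user-overridden leaves that came without their own provenance
    user_prov = (raw.get("provenance") or {}) if isinstance(raw, dict) else {}
    base_cfg = config_from_dict(base)
    base_vals = dict(iter_numeric_leaves(base_cfg))
    for p, v in iter_numeric_leaves(cfg):
        if p in user_prov:
            continue
        if p not in base_vals or base_vals[p] != v:
            cfg.provenance[p] = "user"

    violations = validate_config(cfg)
    if violations:
        raise ConfigError(violations)
    return cfg


def write_config(cfg: ModelConfig, path: str | Path) -> None:
    """Serialise a configuration to YAML; round-trips exactly through
    :func:`load_config`."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Small parameter operations
# ---------------------------------------------------------------------------


def ppp_convert(amount: float, coefficient: float = 0.648) -> float:
    """Convert a USD amount to Italian EUR by a purchasing-power-parity
    coefficient (2021 value 0.648)."""
    if amount < 0:
        raise ValueError(f"amount must be non-negative, got {amount}")
    if coefficient <= 0:
        raise ValueError(f"coefficient must be positive, got {coefficient}")
    return amount * coefficient


def annual_ae_cost(ae_profile: list[AEItem], arm: str) -> float:
    """Expected annual adverse-event cost for one arm: sum of incidence-rate
    times unit cost over the profile."""
    if not ae_profile:
        raise ValueError("adverse-event profile must be non-empty")
    _check_arm(arm)
    attr = "rate_dup" if arm == ARM_DUPILUMAB else "rate_bsc"
    return float(sum(getattr(item, attr) * item.unit_cost for item in ae_profile))


def _check_arm(arm: str) -> None:
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
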