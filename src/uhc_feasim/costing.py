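"""Bottom-up costing of the MCH benefit package.

Facility ledgers (capital inventories, salary totals, overhead totals, drug
line items, visit registers) are aggregated into annual MCH-attributable
costs by component, converted to per-visit unit costs, and combined with a
drug price list and service-utilization mixes into per-beneficiary package
unit costs.

Cost components
---------------
capital
    Replacement costs annualized with the standard annuity factor
    ``C * r / (1 - (1+r)^-L)`` at discount rate ``r`` over useful life ``L``.
personnel, overhead
    Annual expenditure totals taken from the ledger.
drugs
    Quantity x unit price over dispensing line items.

Shared (non-drug) costs are attributed to MCH by the facility utilization
weight — the share of all outpatient visits that were for MCH services.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from .errors import ConfigurationError, DegenerateInputError, InvalidInputError
from .money import MoneyLike, as_rational, round_half_up

__all__ = [
    "MATERNAL_SERVICES",
    "CHILD_SERVICES",
    "MATERNAL_CORE_SERVICES",
    "MATERNAL_OPTIONAL_SERVICES",
    "CapitalItem",
    "CostingParams",
    "ServicePriceList",
    "FacilityCostLedger",
    "PackageUnitCost",
    "annualize_capital",
    "allocate_to_mch",
    "compute_mch_weight",
    "unit_component_cost",
    "maternal_package_cost",
    "child_package_cost",
    "combined_unit_cost",
    "scale_to_state",
    "to_usd",
    "facility_component_costs",
    "state_unit_component_costs",
    "read_facility_ledger",
    "write_facility_ledger",
]

CAPITAL_CATEGORIES = ("building", "transport", "medical_equipment", "other")

# Benefit-package services. The maternal pathway always includes the core
# pregnancy services; family planning and the complication services enter
# weighted by their utilization proportions.
MATERNAL_CORE_SERVICES = ("anc", "normal_delivery", "pnc")
MATERNAL_OPTIONAL_SERVICES = (
    "family_planning",
    "malaria_in_pregnancy",
    "hypertension_in_pregnancy",
    "postpartum_hemorrhage",
)
MATERNAL_SERVICES = MATERNAL_CORE_SERVICES + MATERNAL_OPTIONAL_SERVICES
CHILD_SERVICES = (
    "child_malaria",
    "pneumonia",
    "diarrhea",
    "routine_immunization",
    "measles",
)
KNOWN_SERVICES = MATERNAL_SERVICES + CHILD_SERVICES


@dataclass(frozen=True)
class CapitalItem:
    """One capital asset at replacement cost."""

    category: str
    replacement_cost: Fraction
    useful_life: int
    acquisition_year: int = 0

    def __post_init__(self) -> None:
        if self.category not in CAPITAL_CATEGORIES:
            raise InvalidInputError(
                f"unknown capital category {self.category!r}; expected one of {CAPITAL_CATEGORIES}"
            )
        object.__setattr__(self, "replacement_cost", as_rational(self.replacement_cost))
        if self.replacement_cost < 0:
            raise InvalidInputError("replacement_cost must be nonnegative")
        if self.useful_life < 1:
            raise InvalidInputError("useful_life must be at least 1 year")


#: Default useful lives by capital category, in years.
DEFAULT_USEFUL_LIVES: Mapping[str, int] = {
    "building": 30,
    "transport": 10,
    "medical_equipment": 5,
    "other": 5,
}


@dataclass(frozen=True)
class CostingParams:
    """Tunable costing assumptions.

    discount_rate
        Annual rate for capital annualization (default 3%).
    exchange_rate
        Naira per US$ for display conversion (default 305.5 ₦/$).
    anc_visits, child_visits_per_year
        Contact counts of the benefit package: four antenatal visits per
        pregnancy; three facility visits per child-year.
    p_mother, p_child
        Mixing probabilities for the combined per-beneficiary cost
        (0.2 / 0.8, from the demographic composition of the target group).
    """

    discount_rate: Fraction = Fraction(3, 100)
    useful_life_defaults: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_USEFUL_LIVES)
    )
    exchange_rate: Fraction = Fraction(3055, 10)
    anc_visits: int = 4
    child_visits_per_year: int = 3
    p_mother: Fraction = Fraction(2, 10)
    p_child: Fraction = Fraction(8, 10)

    def __post_init__(self) -> None:
        for name in ("discount_rate", "exchange_rate", "p_mother", "p_child"):
            object.__setattr__(self, name, as_rational(getattr(self, name)))
        if self.p_mother + self.p_child != 1:
            raise InvalidInputError("p_mother + p_child must equal 1")
        if self.anc_visits < 1:
            raise InvalidInputError("anc_visits must be at least 1")
        if self.exchange_rate <= 0:
            raise InvalidInputError("exchange_rate must be positive")

    @property
    def maternal_contacts(self) -> int:
        """Facility contacts per pregnancy attracting per-visit shared costs:
        the ANC visits plus one delivery and one postnatal visit."""
        return self.anc_visits + 2


@dataclass(frozen=True)
class ServicePriceList:
    """Drug-and-consumable unit cost per service episode, in Naira."""

    prices: Mapping[str, Fraction]

    def __post_init__(self) -> None:
        clean = {}
        for service, price in dict(self.prices).items():
            if service not in KNOWN_SERVICES:
                raise ConfigurationError(
                    f"unknown service {service!r}; expected one of {sorted(KNOWN_SERVICES)}"
                )
            p = as_rational(price)
            if p < 0:
                raise InvalidInputError(f"price for {service!r} must be nonnegative")
            clean[service] = p
        object.__setattr__(self, "prices", clean)

    def __getitem__(self, service: str) -> Fraction:
        try:
            return self.prices[service]
        except KeyError:
            raise ConfigurationError(f"no price configured for service {service!r}") from None

    def __contains__(self, service: str) -> bool:
        return service in self.prices

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "ServicePriceList":
        import pandas as pd

        df = pd.read_csv(path, sep=None, engine="python")
        if not {"service", "naira_cost"} <= set(df.columns):
            raise ConfigurationError(f"price list {path} must have columns service, naira_cost")
        return cls({str(r.service): as_rational(str(r.naira_cost)) for r in df.itertuples()})

    def to_csv(self, path: Union[str, Path]) -> None:
        import pandas as pd

        pd.DataFrame(
            {"service": list(self.prices), "naira_cost": [float(v) for v in self.prices.values()]}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class FacilityCostLedger:
    """One facility-year of cost and utilization records."""

    facility_id: str
    capital_items: tuple[CapitalItem, ...]
    personnel_annual: Fraction
    overhead_annual: Fraction
    drug_line_items: tuple[tuple[str, Fraction, Fraction], ...]  # (service, qty, unit price)
    visits_total: int
    visits_mch: int
    maternal_service_mix: Mapping[str, Fraction] = field(default_factory=dict)
    child_service_mix: Mapping[str, Fraction] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "capital_items", tuple(self.capital_items))
        object.__setattr__(self, "personnel_annual", as_rational(self.personnel_annual))
        object.__setattr__(self, "overhead_annual", as_rational(self.overhead_annual))
        object.__setattr__(
            self,
            "drug_line_items",
            tuple((s, as_rational(q), as_rational(p)) for s, q, p in self.drug_line_items),
        )
        if self.personnel_annual < 0 or self.overhead_annual < 0:
            raise InvalidInputError("monetary fields must be nonnegative")
        if self.visits_mch > self.visits_total:
            raise InvalidInputError("visits_mch cannot exceed visits_total")
        for s, q, p in self.drug_line_items:
            if q < 0 or p < 0:
                raise InvalidInputError(f"drug line item {s!r} has negative quantity or price")


@dataclass(frozen=True)
class PackageUnitCost:
    """Per-beneficiary annual package cost for one cost-component set."""

    component_set: str  # drugs_only | drugs_overheads | all_components
    maternal: Fraction
    child: Fraction
    combined: Fraction

    def __post_init__(self) -> None:
        for name in ("maternal", "child", "combined"):
            object.__setattr__(self, name, as_rational(getattr(self, name)))
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} unit cost must be nonnegative")
        lo, hi = min(self.maternal, self.child), max(self.maternal, self.child)
        if not lo <= self.combined <= hi:
            raise InvalidInputError("combined unit cost must lie between maternal and child")


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def annualize_capital(item: CapitalItem, discount_rate: MoneyLike) -> Fraction:
    """Equivalent annual cost of a capital item (annuity factor).

    ``C * r / (1 - (1+r)^-L)`` for ``r > 0``; the straight-line ``C / L``
    in the ``r = 0`` limit.
    """
    r = as_rational(discount_rate)
    if r < 0:
        raise InvalidInputError("discount_rate must be nonnegative")
    if r == 0:
        return item.replacement_cost / item.useful_life
    return item.replacement_cost * r / (1 - (1 + r) ** -item.useful_life)


def allocate_to_mch(total_cost: MoneyLike, mch_weight: MoneyLike) -> Fraction:
    """Attribute a shared annual cost to MCH by the utilization weight."""
    w = as_rational(mch_weight)
    if not 0 <= w <= 1:
        raise InvalidInputError(f"mch_weight must lie in [0, 1], got {w}")
    return as_rational(total_cost) * w


def compute_mch_weight(visits_mch: int, visits_total: int) -> Fraction:
    """Share of all outpatient visits that were for MCH services."""
    if visits_total <= 0:
        raise DegenerateInputError("visits_total must be positive to form a weight")
    if visits_mch > visits_total:
        raise InvalidInputError("visits_mch cannot exceed visits_total")
    return Fraction(visits_mch, visits_total)


def unit_component_cost(mch_cost: MoneyLike, mch_visits: int) -> Fraction:
    """Per-MCH-visit cost of one component, unrounded."""
    if mch_visits <= 0:
        raise DegenerateInputError("mch_visits must be positive")
    return as_rational(mch_cost) / mch_visits


def _per_visit_total(per_visit_components: Union[Mapping[str, MoneyLike], MoneyLike, None]) -> Fraction:
    if per_visit_components is None:
        return Fraction(0)
    if isinstance(per_visit_components, Mapping):
        return sum((as_rational(v) for v in per_visit_components.values()), Fraction(0))
    return as_rational(per_visit_components)


def maternal_package_cost(
    prices: ServicePriceList,
    mix: Mapping[str, MoneyLike],
    params: CostingParams = CostingParams(),
    per_visit_components: Union[Mapping[str, MoneyLike], MoneyLike, None] = None,
) -> Fraction:
    """Annual package cost per pregnant woman.

    Drug part: the full ANC drug course, facility delivery and postnatal
    consumables, plus family planning and each complication service weighted
    by its utilization proportion in ``mix`` (keys restricted to the optional
    maternal services). Non-drug components, when supplied as per-visit
    amounts, accrue over the pregnancy's facility contacts (ANC visits +
    delivery + PNC).
    """
    unknown = set(mix) - set(MATERNAL_OPTIONAL_SERVICES)
    if unknown:
        raise ConfigurationError(
            f"maternal mix may only weight optional maternal services; got {sorted(unknown)}"
        )
    drug = prices["anc"] + prices["normal_delivery"] + prices["pnc"]
    for service in MATERNAL_OPTIONAL_SERVICES:
        w = as_rational(mix.get(service, 0))
        if w < 0:
            raise InvalidInputError(f"mix weight for {service!r} must be nonnegative")
        if w:
            drug += w * prices[service]
    return drug + params.maternal_contacts * _per_visit_total(per_visit_components)


def child_package_cost(
    prices: ServicePriceList,
    mix: Mapping[str, MoneyLike],
    params: CostingParams = CostingParams(),
    per_visit_components: Union[Mapping[str, MoneyLike], MoneyLike, None] = None,
) -> Fraction:
    """Annual package cost per under-five child.

    ``child_visits_per_year`` visits, each costing the mix-weighted average
    drug price plus any per-visit non-drug components.
    """
    unknown = set(mix) - set(CHILD_SERVICES)
    if unknown:
        raise ConfigurationError(f"child mix may only weight child services; got {sorted(unknown)}")
    per_visit_drug = Fraction(0)
    for service, weight in mix.items():
        w = as_rational(weight)
        if w < 0:
            raise InvalidInputError(f"mix weight for {service!r} must be nonnegative")
        per_visit_drug += w * prices[service]
    return params.child_visits_per_year * (per_visit_drug + _per_visit_total(per_visit_components))


def combined_unit_cost(
    maternal: MoneyLike, child: MoneyLike, params: CostingParams = CostingParams()
) -> Fraction:
    """Per-beneficiary cost for 'either mother or child':
    ``p_mother * maternal + p_child * child``."""
    m, c = as_rational(maternal), as_rational(child)
    if m < 0 or c < 0:
        raise InvalidInputError("unit costs must be nonnegative")
    return params.p_mother * m + params.p_child * c


def scale_to_state(avg_facility_cost: MoneyLike, n_standard_facilities: int) -> Fraction:
    """Average per-facility cost times the state's standard facility count."""
    if n_standard_facilities < 0:
        raise InvalidInputError("n_standard_facilities must be nonnegative")
    return as_rational(avg_facility_cost) * n_standard_facilities


def to_usd(amount: MoneyLike, exchange_rate: MoneyLike = Fraction(3055, 10)) -> Fraction:
    """Convert Naira to US$ (display to one decimal)."""
    rate = as_rational(exchange_rate)
    if rate <= 0:
        raise InvalidInputError("exchange_rate must be positive")
    return as_rational(amount) / rate


# ---------------------------------------------------------------------------
# Ledger aggregation
# ---------------------------------------------------------------------------


def facility_component_costs(
    ledger: FacilityCostLedger, params: CostingParams = CostingParams()
) -> dict[str, Fraction]:
    """Annual MCH-attributable cost per component for one facility.

    Capital, personnel and overheads are shared costs weighted by the
    facility's MCH utilization weight; drug line items are MCH-specific and
    enter at full value.
    """
    weight = compute_mch_weight(ledger.visits_mch, ledger.visits_total)
    capital_total = sum(
        (annualize_capital(item, params.discount_rate) for item in ledger.capital_items),
        Fraction(0),
    )
    drugs = sum((q * p for _, q, p in ledger.drug_line_items), Fraction(0))
    return {
        "capital": allocate_to_mch(capital_total, weight),
        "personnel": allocate_to_mch(ledger.personnel_annual, weight),
        "overhead": allocate_to_mch(ledger.overhead_annual, weight),
        "drugs": drugs,
    }


def state_unit_component_costs(
    ledgers: Sequence[FacilityCostLedger], params: CostingParams = CostingParams()
) -> dict[str, Fraction]:
    """Pooled per-MCH-visit unit cost by component across facilities.

    Ratio-of-sums estimator: total MCH-attributable component cost across
    facilities divided by total MCH visits.
    """
    if not ledgers:
        raise DegenerateInputError("at least one facility ledger is required")
    totals = {"capital": Fraction(0), "personnel": Fraction(0), "overhead": Fraction(0), "drugs": Fraction(0)}
    visits = 0
    for ledger in ledgers:
        for k, v in facility_component_costs(ledger, params).items():
            totals[k] += v
        visits += ledger.visits_mch
    if visits == 0:
        raise DegenerateInputError("no MCH visits across ledgers")
    return {k: v / visits for k, v in totals.items()}


# ---------------------------------------------------------------------------
# Sectioned plain-text ledger files
# ---------------------------------------------------------------------------

_SECTION_RE = re.compile(r"^\[(?P<name>[a-z_]+)\]$")
_LEDGER_SECTIONS = ("capital", "personnel", "overhead", "drugs", "visits")


def write_facility_ledger(ledger: FacilityCostLedger, path: Union[str, Path]) -> None:
    """Write one facility ledger in the sectioned delimited format."""
    lines = [f"# facility: {ledger.facility_id}"]
    lines.append("[capital]")
    lines.append("category,replacement_cost,useful_life,acquisition_year")
    for item in ledger.capital_items:
        lines.append(
            f"{item.category},{float(item.replacement_cost):.4f},{item.useful_life},{item.acquisition_year}"
        )
    lines.append("[personnel]")
    lines.append(f"{float(ledger.personnel_annual):.4f}")
    lines.append("[overhead]")
    lines.append(f"{float(ledger.overhead_annual):.4f}")
    lines.append("[drugs]")
    lines.append("service,quantity,unit_price")
    for s, q, p in ledger.drug_line_items:
        lines.append(f"{s},{float(q):.4f},{float(p):.4f}")
    lines.append("[visits]")
    lines.append("visits_total,visits_mch")
    lines.append(f"{ledger.visits_total},{ledger.visits_mch}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_facility_ledger(path: Union[str, Path]) -> FacilityCostLedger:
    """Parse a sectioned ledger file with line-numbered validation errors."""
    path = Path(path)
    facility_id = path.stem
    sections: dict[str, list[tuple[int, str]]] = {}
    current: Union[str, None] = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"^#\s*facility:\s*(.+)$", line)
            if m:
                facility_id = m.group(1).strip()
            continue
        m = _SECTION_RE.match(line)
        if m:
            current = m.group("name")
            if current not in _LEDGER_SECTIONS:
                raise ConfigurationError(f"{path}:{lineno}: unknown section [{current}]")
            sections[current] = []
            continue
        if current is None:
            raise ConfigurationError(f"{path}:{lineno}: data before any section header")
        sections[current].append((lineno, line))

    missing = [s for s in _LEDGER_SECTIONS if s not in sections]
    if missing:
        raise ConfigurationError(f"{path}: missing sections {missing}")

    def _fields(lineno: int, line: str, n: int, what: str) -> list[str]:
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != n:
            raise ConfigurationError(f"{path}:{lineno}: expected {n} {what} fields, got {len(parts)}")
        return parts

    capital = []
    for lineno, line in sections["capital"]:
        parts = _fields(lineno, line, 4, "capital")
        if parts[0] == "category":
            continue
        try:
            capital.append(
                CapitalItem(parts[0], as_rational(parts[1]), int(parts[2]), int(parts[3]))
            )
        except (ValueError, InvalidInputError) as exc:
            raise ConfigurationError(f"{path}:{lineno}: {exc}") from exc

    def _scalar(name: str) -> Fraction:
        rows = sections[name]
        if len(rows) != 1:
            raise ConfigurationError(f"{path}: section [{name}] must hold exactly one total")
        lineno, line = rows[0]
        try:
            return as_rational(line)
        except Exception as exc:
            raise ConfigurationError(f"{path}:{lineno}: bad {name} total {line!r}") from exc

    drugs = []
    for lineno, line in sections["drugs"]:
        parts = _fields(lineno, line, 3, "drug")
        if parts[0] == "service":
            continue
        if parts[0] not in KNOWN_SERVICES:
            raise ConfigurationError(f"{path}:{lineno}: unknown service {parts[0]!r}")
        drugs.append((parts[0], as_rational(parts[1]), as_rational(parts[2])))

    visit_rows = [r for r in sections["visits"] if not r[1].startswith("visits_total")]
    if len(visit_rows) != 1:
        raise ConfigurationError(f"{path}: section [visits] must hold one data row")
    lineno, line = visit_rows[0]
    parts = _fields(lineno, line, 2, "visits")
    try:
        visits_total, visits_mch = int(parts[0]), int(parts[1])
    except ValueError as exc:
        raise ConfigurationError(f"{path}:{lineno}: visit counts must be integers") from exc

    try:
        return FacilityCostLedger(
            facility_id=facility_id,
            capital_items=tuple(capital),
            personnel_annual=_scalar("personnel"),
            overhead_annual=_scalar("overhead"),
            drug_line_items=tuple(drugs),
            visits_total=visits_total,
            visits_mch=visits_mch,
        )
    except InvalidInputError as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc
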