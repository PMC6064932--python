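"""Coverage and funding-gap analysis.

Combines per-beneficiary unit costs, target head counts and scenario revenue
into feasibility rows: amount required per year, lives covered by the
available funds, the gap or surplus, and the additional aggregate funding
needed as a percent of the available amount. Also solves for the minimum
CRF percentage whose allocated share covers a given requirement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Union

from .costing import PackageUnitCost
from .demography import StateProfile, TargetBeneficiaries, vulnerable_subset
from .errors import ConfigurationError, DegenerateInputError, InvalidInputError
from .money import MoneyLike, as_rational, round_half_up
from .revenue import (
    CounterpartBase,
    FundAllocation,
    ScenarioSpec,
    StateRevenueInputs,
    get_scenario,
)

__all__ = [
    "GROUPS",
    "FeasibilityRow",
    "StateAnalysisInputs",
    "required_amount",
    "funding_gap",
    "additional_pct",
    "lives_covered",
    "run_scenario",
    "minimum_crf_percent",
]

GROUPS = ("maternal", "child", "all_mch", "all_mch_vulnerable")


@dataclass(frozen=True)
class FeasibilityRow:
    """One (state x beneficiary group x scenario) result.

    Monetary fields are exact rationals; ``gap == available - required``
    holds identically. Display rounding is applied by the reporting layer.
    """

    state: str
    group: str
    scenario_id: str
    unit_cost: Fraction
    targets: int
    required: Fraction
    available: Fraction
    lives_covered: int
    gap: Fraction
    additional_pct_value: Fraction

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise InvalidInputError(f"unknown group {self.group!r}")
        if self.gap != self.available - self.required:
            raise InvalidInputError("row identity violated: gap != available - required")
        if self.lives_covered < 0:
            raise InvalidInputError("lives_covered must be nonnegative")

    @property
    def additional_pct_display(self) -> int:
        """Half-up integer percent, negative for surpluses."""
        return round_half_up(self.additional_pct_value)


def required_amount(unit_cost: MoneyLike, targets: int) -> Fraction:
    """Annual amount required: unrounded unit cost times target head count."""
    if targets < 0:
        raise InvalidInputError("targets must be nonnegative")
    return as_rational(unit_cost) * targets


def funding_gap(available: MoneyLike, required: MoneyLike) -> Fraction:
    """``available - required``; negative values signal infeasibility."""
    return as_rational(available) - as_rational(required)


def additional_pct(gap: MoneyLike, available: MoneyLike) -> Fraction:
    """Additional aggregate funds needed as a percent of the available amount.

    ``-100 * gap / available``: a shortfall yields a positive percentage, a
    surplus a negative one. Display rounds half-up to an integer.
    """
    a = as_rational(available)
    if a <= 0:
        raise DegenerateInputError("available must be positive")
    return -100 * as_rational(gap) / a


def lives_covered(available: MoneyLike, unit_cost: MoneyLike) -> int:
    """Beneficiaries fully payable from the available amount.

    Floor of the exact ratio — a fractional person cannot be covered. The
    unit cost should be the unrounded value (required / targets).
    """
    u = as_rational(unit_cost)
    if u <= 0:
        raise DegenerateInputError("unit_cost must be positive")
    a = as_rational(available)
    if a <= 0:
        return 0
    return int(a / u)


@dataclass(frozen=True)
class StateAnalysisInputs:
    """Everything one state contributes to a scenario run.

    unit_costs
        Per-beneficiary package cost for each component set the scenarios
        need, keyed by component-set value (``"drugs_only"``, ...).
    """

    targets: TargetBeneficiaries
    unit_costs: Mapping[str, PackageUnitCost]
    revenue_inputs: StateRevenueInputs = StateRevenueInputs()
    allocation: FundAllocation = FundAllocation()
    vulnerable_fraction: Fraction = Fraction(63, 100)

    def __post_init__(self) -> None:
        object.__setattr__(self, "vulnerable_fraction", as_rational(self.vulnerable_fraction))


def run_scenario(
    scenario_id: Union[str, ScenarioSpec],
    state: StateProfile,
    group: str,
    inputs: StateAnalysisInputs,
    counterpart_base: CounterpartBase = CounterpartBase.SCENARIO_REVENUE,
) -> FeasibilityRow:
    """Compose demography, costing and revenue into one feasibility row."""
    from .revenue import scenario_revenue

    spec = get_scenario(scenario_id) if isinstance(scenario_id, str) else scenario_id
    if group not in GROUPS:
        raise ConfigurationError(f"unknown group {group!r}; expected one of {GROUPS}")
    component_set = spec.component_set.value
    if component_set not in inputs.unit_costs:
        raise ConfigurationError(
            f"missing upstream data for state {state.state_name!r}: no unit costs for "
            f"component set {component_set!r} (have {sorted(inputs.unit_costs)})"
        )
    pkg = inputs.unit_costs[component_set]

    if group == "maternal":
        unit, targets = pkg.maternal, inputs.targets.pregnant_women
    elif group == "child":
        unit, targets = pkg.child, inputs.targets.under_five
    elif group == "all_mch":
        unit, targets = pkg.combined, inputs.targets.all_mch
    else:  # all_mch_vulnerable
        unit = pkg.combined
        targets = vulnerable_subset(inputs.targets, inputs.vulnerable_fraction).all_mch

    required = required_amount(unit, targets)
    available = scenario_revenue(spec, inputs.allocation, inputs.revenue_inputs, counterpart_base)
    gap = funding_gap(available, required)
    return FeasibilityRow(
        state=state.state_name,
        group=group,
        scenario_id=spec.scenario_id,
        unit_cost=unit,
        targets=targets,
        required=required,
        available=available,
        lives_covered=lives_covered(available, unit) if unit > 0 else 0,
        gap=gap,
        additional_pct_value=additional_pct(gap, available),
    )


def minimum_crf_percent(
    max_required: MoneyLike,
    alloc: FundAllocation = FundAllocation(),
    allocation_fraction: MoneyLike = Fraction(50, 100),
) -> tuple[Fraction, int]:
    """Smallest CRF percentage whose allocated state share covers a requirement.

    Solves ``allocation_fraction * (x * crf_one_percent) / n_sharing_units
    >= max_required`` for continuous ``x`` (closed form
    ``x = max_required * n / (fraction * crf_one_percent)``) and returns
    ``(continuous_minimum, ceiling)``.
    """
    req = as_rational(max_required)
    f = as_rational(allocation_fraction)
    if f <= 0:
        raise DegenerateInputError("allocation_fraction must be positive")
    if req < 0:
        raise InvalidInputError("max_required must be nonnegative")
    x = req * alloc.n_sharing_units / (f * alloc.crf_one_percent)
    return x, math.ceil(x)
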