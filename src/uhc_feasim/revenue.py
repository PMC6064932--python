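"""Scenario revenue construction from BHCPF allocation rules.

The BHCPF equals 1% of the Consolidated Revenue Fund (CRF) and is split
between the NHIS (50%), the NPHCDA (45%) and the FMOH (5%); each recipient's
portion is shared equally across the 36 states and the FCT. A scenario's
revenue is the state share of a chosen BHCPF fraction, optionally grossed up
by a counterpart-funding rate and topped up with state/LGA budget lines and
facility internally generated revenue (IGR).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from fractions import Fraction
from typing import Mapping, Union

from .errors import ConfigurationError, InvalidInputError
from .money import MoneyLike, as_rational

__all__ = [
    "FundAllocation",
    "ScenarioSpec",
    "StateRevenueInputs",
    "ComponentSet",
    "CounterpartBase",
    "SCENARIO_PRESETS",
    "get_scenario",
    "state_share",
    "apply_counterpart",
    "scenario_revenue",
]


class ComponentSet(str, Enum):
    """Which cost components the programme funds under a scenario family."""

    DRUGS_ONLY = "drugs_only"
    DRUGS_OVERHEADS = "drugs_overheads"
    ALL_COMPONENTS = "all_components"


class CounterpartBase(str, Enum):
    """Base on which the counterpart rate is applied.

    SCENARIO_REVENUE (default) matches the scenario definitions: the rate
    grosses up the scenario's own BHCPF revenue. NPHCDA_COMPONENT is the
    alternative reading (rate applied to the NPHCDA 45% state share).
    """

    SCENARIO_REVENUE = "scenario_revenue"
    NPHCDA_COMPONENT = "nphcda_component"


@dataclass(frozen=True)
class FundAllocation:
    """The BHCPF envelope and its statutory split."""

    crf_one_percent: Fraction = Fraction(38_555_000_000)
    nhis_fraction: Fraction = Fraction(50, 100)
    nphcda_fraction: Fraction = Fraction(45, 100)
    fmoh_fraction: Fraction = Fraction(5, 100)
    n_sharing_units: int = 37

    def __post_init__(self) -> None:
        for name in ("crf_one_percent", "nhis_fraction", "nphcda_fraction", "fmoh_fraction"):
            object.__setattr__(self, name, as_rational(getattr(self, name)))
        if self.nhis_fraction + self.nphcda_fraction + self.fmoh_fraction != 1:
            raise InvalidInputError("NHIS + NPHCDA + FMOH fractions must sum to 1")
        if self.n_sharing_units < 1:
            raise InvalidInputError("n_sharing_units must be at least 1")


@dataclass(frozen=True)
class StateRevenueInputs:
    """Optional state-level revenue components, already scaled to state level."""

    state_phc_budget: Fraction = Fraction(0)
    lga_phc_budget_scaled: Fraction = Fraction(0)
    igr_scaled: Fraction = Fraction(0)

    def __post_init__(self) -> None:
        for name in ("state_phc_budget", "lga_phc_budget_scaled", "igr_scaled"):
            object.__setattr__(self, name, as_rational(getattr(self, name)))
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class ScenarioSpec:
    """One revenue recipe paired with a cost-component set."""

    scenario_id: str
    bhcpf_fraction: Fraction
    counterpart_rate: Fraction = Fraction(0)
    include_state_budget: bool = False
    include_lga_budget: bool = False
    include_igr: bool = False
    component_set: ComponentSet = ComponentSet.DRUGS_ONLY

    def __post_init__(self) -> None:
        object.__setattr__(self, "bhcpf_fraction", as_rational(self.bhcpf_fraction))
        object.__setattr__(self, "counterpart_rate", as_rational(self.counterpart_rate))
        object.__setattr__(self, "component_set", ComponentSet(self.component_set))
        if not 0 < self.bhcpf_fraction <= 1:
            raise InvalidInputError("bhcpf_fraction must lie in (0, 1]")
        if self.counterpart_rate < 0:
            raise InvalidInputError("counterpart_rate must be nonnegative")


def _presets() -> dict[str, ScenarioSpec]:
    # Sub-scenario letters a-f fix the BHCPF fraction and counterpart rate;
    # scenario families 1/2/3 fix the funded component set, with family 3
    # also drawing on state/LGA budgets and IGR.
    fractions = {
        "a": (Fraction(50, 100), Fraction(0)),
        "b": (Fraction(70, 100), Fraction(0)),
        "c": (Fraction(95, 100), Fraction(0)),
        "d": (Fraction(50, 100), Fraction(25, 100)),
        "e": (Fraction(70, 100), Fraction(25, 100)),
        "f": (Fraction(95, 100), Fraction(25, 100)),
    }
    families = {
        "1": (ComponentSet.DRUGS_ONLY, False),
        "2": (ComponentSet.DRUGS_OVERHEADS, False),
        "3": (ComponentSet.ALL_COMPONENTS, True),
    }
    presets = {}
    for fam, (components, extra_sources) in families.items():
        for letter, (bhcpf, cp) in fractions.items():
            sid = fam + letter
            presets[sid] = ScenarioSpec(
                scenario_id=sid,
                bhcpf_fraction=bhcpf,
                counterpart_rate=cp,
                include_state_budget=extra_sources,
                include_lga_budget=extra_sources,
                include_igr=extra_sources,
                component_set=components,
            )
    return presets


#: The eighteen preset scenarios (families 1-3 x sub-scenarios a-f).
SCENARIO_PRESETS: Mapping[str, ScenarioSpec] = _presets()


def get_scenario(scenario_id: str) -> ScenarioSpec:
    """Look up a preset scenario by id (e.g. ``"1c"``)."""
    try:
        return SCENARIO_PRESETS[scenario_id]
    except KeyError:
        raise ConfigurationError(
            f"unknown scenario_id {scenario_id!r}; expected one of {sorted(SCENARIO_PRESETS)}"
        ) from None


def state_share(alloc: FundAllocation, fraction: MoneyLike) -> Fraction:
    """One state's share of a BHCPF fraction, unrounded.

    ``crf_one_percent * fraction / n_sharing_units`` — kept rational; the
    division by 37 is the step that produces a repeating decimal.
    """
    f = as_rational(fraction)
    if not 0 <= f <= 1:
        raise InvalidInputError("fraction must lie in [0, 1]")
    return alloc.crf_one_percent * f / alloc.n_sharing_units


def apply_counterpart(base: MoneyLike, rate: MoneyLike) -> Fraction:
    """Gross up a revenue base by the counterpart-funding rate: ``base * (1 + rate)``."""
    r = as_rational(rate)
    if r < 0:
        raise InvalidInputError("counterpart rate must be nonnegative")
    return as_rational(base) * (1 + r)


def scenario_revenue(
    spec: Union[ScenarioSpec, str],
    alloc: FundAllocation = FundAllocation(),
    state_inputs: StateRevenueInputs = StateRevenueInputs(),
    counterpart_base: CounterpartBase = CounterpartBase.SCENARIO_REVENUE,
) -> Fraction:
    """Total available revenue for one state under a scenario, unrounded."""
    if isinstance(spec, str):
        spec = get_scenario(spec)
    bhcpf = state_share(alloc, spec.bhcpf_fraction)
    if counterpart_base is CounterpartBase.SCENARIO_REVENUE:
        total = apply_counterpart(bhcpf, spec.counterpart_rate)
    else:
        total = bhcpf + spec.counterpart_rate * state_share(alloc, alloc.nphcda_fraction)
    if spec.include_state_budget:
        total += state_inputs.state_phc_budget
    if spec.include_lga_budget:
        total += state_inputs.lga_phc_budget_scaled
    if spec.include_igr:
        total += state_inputs.igr_scaled
    return total
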