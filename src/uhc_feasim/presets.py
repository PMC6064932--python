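"""State presets for Imo-, Kaduna- and Niger-like analyses.

Each preset bundles the demographic profile, utilization weight, per-visit
component unit costs and calibrated service mixes needed to run the full
pipeline for one of the three study states.

Census base populations are back-derived: the integer census whose
nine-year compounded projection reproduces the published pregnant and
under-five targets exactly under independent half-up rounding. LGA counts
are the states' administrative counts; nothing numeric depends on them.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Mapping

from .calibration import calibrate_child_mix, calibrate_maternal_mix
from .costing import (
    CostingParams,
    PackageUnitCost,
    ServicePriceList,
    child_package_cost,
    combined_unit_cost,
    maternal_package_cost,
)
from .demography import StateProfile
from .errors import ConfigurationError
from .money import as_rational
from .reference import (
    AVG_UTILIZATION,
    COMPONENT_UNIT_COSTS,
    FACILITY_COUNTS,
    GROWTH_RATES,
    STATES,
    UTILIZATION_WEIGHTS,
    price_list,
    unrounded_unit_cost,
)
from .revenue import ComponentSet

__all__ = ["StatePreset", "get_state_preset", "preset_unit_costs", "STATES"]

_CENSUS = {"Imo": 3_934_899, "Kaduna": 6_113_502, "Niger": 3_950_248}
_N_LGAS = {"Imo": 27, "Kaduna": 23, "Niger": 25}


@dataclass(frozen=True)
class StatePreset:
    """Everything needed to run one study-state analysis."""

    profile: StateProfile
    mch_weight: Fraction
    component_unit_costs: Mapping[str, Fraction]  # per-MCH-visit: capital/personnel/overhead
    maternal_mix: Mapping[str, Fraction]
    child_mix: Mapping[str, Fraction]
    price_list: ServicePriceList
    avg_maternal_visits: int  # annual per facility
    avg_child_visits: int


@lru_cache(maxsize=None)
def get_state_preset(state_name: str) -> StatePreset:
    """Preset for one of the three study states (case-sensitive name)."""
    if state_name not in STATES:
        raise ConfigurationError(f"unknown state preset {state_name!r}; expected one of {STATES}")
    prices = price_list()
    profile = StateProfile(
        state_name=state_name,
        census_population=_CENSUS[state_name],
        growth_rate=as_rational(GROWTH_RATES[state_name]),
        n_standard_facilities=FACILITY_COUNTS[state_name],
        n_lgas=_N_LGAS[state_name],
    )
    return StatePreset(
        profile=profile,
        mch_weight=as_rational(UTILIZATION_WEIGHTS[state_name]),
        component_unit_costs={
            k: as_rational(v) for k, v in COMPONENT_UNIT_COSTS[state_name].items()
        },
        maternal_mix=calibrate_maternal_mix(unrounded_unit_cost(state_name, "maternal"), prices),
        child_mix=calibrate_child_mix(unrounded_unit_cost(state_name, "child"), prices),
        price_list=prices,
        avg_maternal_visits=AVG_UTILIZATION[state_name]["maternal"],
        avg_child_visits=AVG_UTILIZATION[state_name]["child"],
    )


def preset_unit_costs(
    state_name: str, params: CostingParams = CostingParams()
) -> dict[str, PackageUnitCost]:
    """Package unit costs per component set, composed from the preset.

    Drug parts come from the price list and calibrated mixes; overheads,
    personnel and capital accrue per facility contact at the state's
    per-visit component unit costs.
    """
    preset = get_state_preset(state_name)
    comp = preset.component_unit_costs
    per_visit = {
        ComponentSet.DRUGS_ONLY.value: {},
        ComponentSet.DRUGS_OVERHEADS.value: {"overhead": comp["overhead"]},
        ComponentSet.ALL_COMPONENTS.value: comp,
    }
    out = {}
    for cset, extras in per_visit.items():
        maternal = maternal_package_cost(preset.price_list, preset.maternal_mix, params, extras)
        child = child_package_cost(preset.price_list, preset.child_mix, params, extras)
        out[cset] = PackageUnitCost(
            component_set=cset,
            maternal=maternal,
            child=child,
            combined=combined_unit_cost(maternal, child, params),
        )
    return out
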