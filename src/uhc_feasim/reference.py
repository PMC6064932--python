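"""Published reference figures for the three-state BHCPF feasibility study.

Immutable transcriptions of the published 2015 figures for Imo, Kaduna and
Niger states — drug price list, per-visit component unit costs, scenario
result tables and in-text scalars — used as regression fixtures and as the
"printed inputs" path of the pipeline. Values are stored verbatim as
printed, including two internal inconsistencies flagged in
:data:`KNOWN_ERRATA`.

All monetary values are Naira; scalars are exact (ints, or Fractions keyed
by decimal strings).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from fractions import Fraction
from types import MappingProxyType
from typing import Mapping

from .money import as_rational

__all__ = [
    "STATES",
    "SCENARIO_TABLE_IDS",
    "ReferenceRow",
    "reference_values",
    "reference_checksum",
    "KNOWN_ERRATA",
]

STATES = ("Imo", "Kaduna", "Niger")

#: Scenario ids for which full published result tables exist.
SCENARIO_TABLE_IDS = ("1a", "1c", "1d", "1f")

#: Table 5-style drug-and-consumable price list (Naira per service episode).
PRICES: Mapping[str, str] = MappingProxyType({
    "anc": "2837.6",
    "normal_delivery": "1503.2",
    "pnc": "339.8",
    "malaria_in_pregnancy": "423.5",
    "hypertension_in_pregnancy": "1620.8",
    "postpartum_hemorrhage": "507.8",
    "family_planning": "365.7",
    "child_malaria": "472.4",
    "pneumonia": "875.5",
    "diarrhea": "443.1",
    "routine_immunization": "71.2",
    "measles": "100.0",
})

#: Per-MCH-visit unit costs by component (Naira), by state.
COMPONENT_UNIT_COSTS: Mapping[str, Mapping[str, str]] = MappingProxyType({
    "Imo": MappingProxyType({"capital": "133.1", "personnel": "2506.6", "overhead": "80.1"}),
    "Kaduna": MappingProxyType({"capital": "43.9", "personnel": "676.5", "overhead": "9.7"}),
    "Niger": MappingProxyType({"capital": "81.3", "personnel": "1748.0", "overhead": "19.9"}),
})

#: MCH utilization weights, growth rates (%/yr), standard facility counts.
UTILIZATION_WEIGHTS = MappingProxyType({"Imo": "0.83", "Kaduna": "0.85", "Niger": "0.9"})
GROWTH_RATES = MappingProxyType({"Imo": "3.2", "Kaduna": "3.0", "Niger": "3.4"})
FACILITY_COUNTS = MappingProxyType({"Imo": 418, "Kaduna": 255, "Niger": 274})

#: Average annual MCH service utilization per facility (visits, 2015).
AVG_UTILIZATION = MappingProxyType({
    "Imo": MappingProxyType({"maternal": 817, "child": 3658}),
    "Kaduna": MappingProxyType({"maternal": 4690, "child": 8671}),
    "Niger": MappingProxyType({"maternal": 2623, "child": 5555}),
})

#: Published target beneficiary counts (persons, 2015).
TARGETS = MappingProxyType({
    "Imo": MappingProxyType({"maternal": 261_229, "child": 1_044_915, "all_mch": 1_306_143,
                             "all_mch_vulnerable": 822_870}),
    "Kaduna": MappingProxyType({"maternal": 398_837, "child": 1_595_347, "all_mch": 1_994_184,
                                "all_mch_vulnerable": 1_256_336}),
    "Niger": MappingProxyType({"maternal": 266_857, "child": 1_067_430, "all_mch": 1_334_287,
                               "all_mch_vulnerable": 840_601}),
})

#: Amount required per year (Naira) by state and group — constant across
#: the drugs-only scenario tables.
REQUIRED = MappingProxyType({
    "Imo": MappingProxyType({"maternal": 1_260_836_278, "child": 402_574_841,
                             "all_mch": 1_663_411_119, "all_mch_vulnerable": 1_048_336_495}),
    "Kaduna": MappingProxyType({"maternal": 1_903_905_766, "child": 548_852_075,
                                "all_mch": 2_452_757_841, "all_mch_vulnerable": 1_545_293_182}),
    "Niger": MappingProxyType({"maternal": 1_269_963_038, "child": 900_339_922,
                               "all_mch": 2_170_302_960, "all_mch_vulnerable": 1_367_657_518}),
})

#: Rounded package unit costs (Naira) as displayed in the scenario tables.
UNIT_COSTS_DISPLAY = MappingProxyType({
    "Imo": MappingProxyType({"maternal": 4827, "child": 385, "all_mch": 1274,
                             "all_mch_vulnerable": 1274}),
    "Kaduna": MappingProxyType({"maternal": 4774, "child": 344, "all_mch": 1230,
                                "all_mch_vulnerable": 1230}),
    "Niger": MappingProxyType({"maternal": 4759, "child": 843, "all_mch": 1627,
                               "all_mch_vulnerable": 1627}),
})

#: Full-package (all components) per-beneficiary costs (Naira).
FULL_PACKAGE_UNITS = MappingProxyType({
    "Imo": MappingProxyType({"maternal": "21145.5", "child": "8544.8"}),
    "Kaduna": MappingProxyType({"maternal": "9153.6", "child": "2534.0"}),
    "Niger": MappingProxyType({"maternal": "8729.6", "child": "4709.0"}),
})

#: In-text revenue scalars (Naira).
REVENUE_SCALARS = MappingProxyType({
    "crf_one_percent": 38_555_000_000,
    "nhis_state_share": 521_013_514,
    "nphcda_state_share": 468_912_162,
    "counterpart_in_text": 24_481_419,  # matches neither convention; unused
    "total_revenue": MappingProxyType(
        {"Imo": 7_013_884_907, "Kaduna": 9_968_254_995, "Niger": 5_202_936_421}
    ),
})

#: State-level annual cost totals (Naira) as printed in the results text.
STATE_COST_TOTALS = MappingProxyType({
    "drugs": MappingProxyType(
        {"Imo": 454_991_616, "Kaduna": 913_922_222, "Niger": 925_283_827}
    ),
    "capital": MappingProxyType(
        {"Imo": 248_852_530, "Kaduna": 149_420_695, "Niger": 182_132_833}
    ),
    "personnel": MappingProxyType(
        {"Imo": 149_889_054, "Kaduna": 2_304_646_474, "Niger": 3_916_955_570}
    ),
    "overhead": MappingProxyType(
        {"Imo": 149_889_054, "Kaduna": 32_910_644, "Niger": 44_514_106}
    ),
})


@dataclass(frozen=True)
class ReferenceRow:
    """One published scenario-table row (displayed values, verbatim)."""

    available: int
    lives_covered: int
    gap: int
    additional_pct: int


def _rows(avail: int, cells: dict[tuple[str, str], tuple[int, int, int]]):
    return {
        key: ReferenceRow(avail, lives, gap, pct)
        for key, (lives, gap, pct) in cells.items()
    }


#: Published scenario tables: (state, group) -> displayed row.
SCENARIO_TABLES: Mapping[str, Mapping[tuple[str, str], ReferenceRow]] = {
    "1a": _rows(521_013_514, {
        ("Imo", "maternal"): (107_937, -739_822_765, 142),
        ("Kaduna", "maternal"): (109_144, -1_382_892_252, 265),
        ("Niger", "maternal"): (109_481, -748_949_524, 144),
        ("Imo", "child"): (1_352_332, 118_438_672, -23),
        ("Kaduna", "child"): (1_514_429, -27_838_562, 5),
        ("Niger", "child"): (617_706, -379_326_408, 73),
        ("Imo", "all_mch"): (409_110, -1_142_397_606, 219),
        ("Kaduna", "all_mch"): (423_603, -1_931_744_328, 371),
        ("Niger", "all_mch"): (320_315, -1_649_289_446, 317),
        ("Imo", "all_mch_vulnerable"): (408_959, -527_322_981, 101),
        ("Kaduna", "all_mch_vulnerable"): (423_588, -1_024_279_668, 197),
        ("Niger", "all_mch_vulnerable"): (320_230, -846_644_044, 162),
    }),
    "1c": _rows(989_925_676, {
        ("Imo", "maternal"): (205_100, -270_910_603, 27),
        ("Kaduna", "maternal"): (207_373, -913_980_090, 92),
        ("Niger", "maternal"): (208_013, -280_037_362, 28),
        ("Imo", "child"): (2_569_430, 587_350_835, -59),
        ("Kaduna", "child"): (2_877_414, 441_073_601, -45),
        ("Niger", "child"): (1_173_641, 89_585_754, -9),
        ("Imo", "all_mch"): (777_309, -673_485_444, 68),
        ("Kaduna", "all_mch"): (804_847, -1_462_832_165, 148),
        ("Niger", "all_mch"): (608_599, -1_180_377_284, 119),
        ("Imo", "all_mch_vulnerable"): (777_022, -58_410_819, 6),
        ("Kaduna", "all_mch_vulnerable"): (804_818, -555_367_506, 56),
        ("Niger", "all_mch_vulnerable"): (608_436, -377_731_842, 38),
    }),
    "1d": _rows(651_266_892, {
        ("Imo", "maternal"): (134_934, -609_569_386, 94),
        ("Kaduna", "maternal"): (136_430, -1_252_638_874, 192),
        ("Niger", "maternal"): (136_851, -618_696_146, 95),
        ("Imo", "child"): (1_690_415, 248_692_051, -38),
        ("Kaduna", "child"): (1_893_036, 102_414_817, -16),
        ("Niger", "child"): (772_132, -249_073_030, 38),
        ("Imo", "all_mch"): (511_388, -1_012_144_227, 155),
        ("Kaduna", "all_mch"): (529_504, -1_801_490_949, 277),
        ("Niger", "all_mch"): (400_394, -1_519_036_068, 233),
        ("Imo", "all_mch_vulnerable"): (511_198, -397_069_603, 61),
        ("Kaduna", "all_mch_vulnerable"): (529_485, -894_026_290, 137),
        ("Niger", "all_mch_vulnerable"): (400_287, -716_390_626, 110),
    }),
    "1f": _rows(1_237_407_095, {
        ("Imo", "maternal"): (256_374, -23_429_184, 2),
        ("Kaduna", "maternal"): (259_216, -666_498_671, 54),
        ("Niger", "maternal"): (260_016, -32_555_943, 3),
        ("Imo", "child"): (3_211_788, 834_832_254, -67),
        ("Kaduna", "child"): (3_596_768, 688_555_020, -56),
        ("Niger", "child"): (1_467_052, 337_067_173, -27),
        ("Imo", "all_mch"): (971_637, -426_004_025, 34),
        ("Kaduna", "all_mch"): (1_006_058, -1_215_350_746, 98),
        ("Niger", "all_mch"): (760_749, -932_895_865, 75),
        ("Imo", "all_mch_vulnerable"): (971_277, 189_070_600, -15),
        ("Kaduna", "all_mch_vulnerable"): (1_006_022, -307_886_087, 25),
        ("Niger", "all_mch_vulnerable"): (760_545, -130_250_423, 11),
    }),
}

#: Cells whose printed value is internally inconsistent with the source's
#: own arithmetic (verified by recomputation), keyed by
#: (scenario_id, state, group, column).
KNOWN_ERRATA = frozenset({
    # gap prints -846,644,044 but available - required = -846,644,004
    ("1a", "Niger", "all_mch_vulnerable", "gap"),
    # Imo personnel total prints identical to the overhead total, which is
    # inconsistent with the Imo per-visit personnel unit cost
    ("text", "Imo", "personnel", "state_total"),
    # Niger full-package units do not equal drug cost + per-visit components,
    # while Imo and Kaduna reproduce to within 1 Naira
    ("text", "Niger", "maternal", "full_package_unit"),
    ("text", "Niger", "child", "full_package_unit"),
})


def reference_values() -> dict:
    """All embedded reference figures as one nested dict (fresh copy).

    Monetary strings are decimal literals; convert with
    :func:`uhc_feasim.money.as_rational` for exact arithmetic.
    """

    def thaw(obj):
        if isinstance(obj, (MappingProxyType, dict)):
            return {k: thaw(v) for k, v in obj.items()}
        return obj

    return {
        "prices": thaw(PRICES),
        "component_unit_costs": thaw(COMPONENT_UNIT_COSTS),
        "utilization_weights": thaw(UTILIZATION_WEIGHTS),
        "growth_rates": thaw(GROWTH_RATES),
        "facility_counts": thaw(FACILITY_COUNTS),
        "avg_utilization": thaw(AVG_UTILIZATION),
        "targets": thaw(TARGETS),
        "required": thaw(REQUIRED),
        "unit_costs_display": thaw(UNIT_COSTS_DISPLAY),
        "full_package_units": thaw(FULL_PACKAGE_UNITS),
        "revenue_scalars": thaw(REVENUE_SCALARS),
        "state_cost_totals": thaw(STATE_COST_TOTALS),
        "scenario_tables": {
            sid: {
                f"{state}/{group}": {
                    "available": row.available,
                    "lives_covered": row.lives_covered,
                    "gap": row.gap,
                    "additional_pct": row.additional_pct,
                }
                for (state, group), row in table.items()
            }
            for sid, table in SCENARIO_TABLES.items()
        },
        "known_errata": sorted("/".join(e) for e in KNOWN_ERRATA),
    }


def reference_checksum() -> str:
    """SHA-256 over the canonical JSON form of the reference figures."""
    blob = json.dumps(reference_values(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()


def unrounded_unit_cost(state: str, group: str) -> Fraction:
    """Exact package unit cost implied by the published required / targets."""
    return Fraction(REQUIRED[state][group], TARGETS[state][group])


def price_list():
    """The reference drug price list as a :class:`ServicePriceList`."""
    from .costing import ServicePriceList

    return ServicePriceList({k: as_rational(v) for k, v in PRICES.items()})
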