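"""State population projection and target-beneficiary derivation.

The beneficiary model is deliberately simple, mirroring how Nigerian PHC
planning documents size an MCH programme: a single geometric growth rate per
state applied to a census base, with pregnant women taken as 5% and
under-five children as 20% of the projected population, and the vulnerable
(below-poverty-line) subset as 63% of any beneficiary group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Union

import pandas as pd

from .errors import InvalidInputError
from .money import MoneyLike, as_rational, round_half_up

__all__ = [
    "DemographyParams",
    "StateProfile",
    "TargetBeneficiaries",
    "project_population",
    "derive_targets",
    "vulnerable_subset",
    "read_state_profiles",
    "write_state_profiles",
]

STATE_PROFILE_COLUMNS = [
    "state_name",
    "census_population",
    "growth_rate",
    "n_standard_facilities",
    "n_lgas",
]


@dataclass(frozen=True)
class DemographyParams:
    """Fractions and horizon used to size the beneficiary population.

    pregnant_fraction
        Share of the projected population who are pregnant in the target
        year (default 0.05).
    under5_fraction
        Share who are under-five children (default 0.20).
    vulnerable_fraction
        Below-poverty-line share used for the vulnerable-group analysis
        (default 0.63, the national poverty headcount ratio).
    base_year, target_year
        Census base year and programme year; the projection horizon is
        ``target_year - base_year`` with annual compounding.
    """

    pregnant_fraction: Fraction = Fraction(5, 100)
    under5_fraction: Fraction = Fraction(20, 100)
    vulnerable_fraction: Fraction = Fraction(63, 100)
    base_year: int = 2006
    target_year: int = 2015

    def __post_init__(self) -> None:
        object.__setattr__(self, "pregnant_fraction", as_rational(self.pregnant_fraction))
        object.__setattr__(self, "under5_fraction", as_rational(self.under5_fraction))
        object.__setattr__(self, "vulnerable_fraction", as_rational(self.vulnerable_fraction))
        for name in ("pregnant_fraction", "under5_fraction", "vulnerable_fraction"):
            f = getattr(self, name)
            if not 0 <= f <= 1:
                raise InvalidInputError(f"{name} must lie in [0, 1], got {f}")
        if self.pregnant_fraction + self.under5_fraction > 1:
            raise InvalidInputError("pregnant_fraction + under5_fraction must not exceed 1")
        if self.target_year < self.base_year:
            raise InvalidInputError("target_year must be >= base_year")

    @property
    def n_years(self) -> int:
        return self.target_year - self.base_year


@dataclass(frozen=True)
class StateProfile:
    """One state's demographic and infrastructure parameters."""

    state_name: str
    census_population: int
    growth_rate: Fraction  # percent per annum
    n_standard_facilities: int
    n_lgas: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "growth_rate", as_rational(self.growth_rate))
        if self.census_population <= 0:
            raise InvalidInputError("census_population must be positive")
        if self.growth_rate < 0:
            raise InvalidInputError("growth_rate must be nonnegative")
        if self.n_standard_facilities <= 0:
            raise InvalidInputError("n_standard_facilities must be positive")


@dataclass(frozen=True)
class TargetBeneficiaries:
    """Beneficiary head counts for one state and year.

    ``all_mch`` is normally the exact sum of the two parts; a one-person
    discrepancy is tolerated on construction because independently rounded
    published figures can differ from the sum of their rounded parts by one.
    """

    pregnant_women: int
    under_five: int
    all_mch: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.all_mch < 0:
            object.__setattr__(self, "all_mch", self.pregnant_women + self.under_five)
        if self.pregnant_women < 0 or self.under_five < 0:
            raise InvalidInputError("beneficiary counts must be nonnegative")
        if abs(self.all_mch - (self.pregnant_women + self.under_five)) > 1:
            raise InvalidInputError(
                "all_mch must equal pregnant_women + under_five (±1 for "
                "independently rounded published figures)"
            )


def project_population(
    census_population: MoneyLike, growth_rate: MoneyLike, n_years: int
) -> Fraction:
    """Project a census population forward with annual compounding.

    Returns the exact ``census_population * (1 + growth_rate/100) ** n_years``
    as a Fraction; round half-up only for display.
    """
    pop = as_rational(census_population)
    rate = as_rational(growth_rate)
    if pop <= 0:
        raise InvalidInputError("census_population must be positive")
    if n_years < 0:
        raise InvalidInputError("n_years must be nonnegative")
    if rate < 0:
        raise InvalidInputError("growth_rate must be nonnegative")
    return pop * (1 + rate / 100) ** n_years


def derive_targets(
    population: MoneyLike, params: DemographyParams = DemographyParams()
) -> TargetBeneficiaries:
    """Derive beneficiary counts from an (unrounded) projected population.

    Each fraction is applied to the unrounded population and rounded half-up
    independently; ``all_mch`` is the sum of the rounded parts.
    """
    pop = as_rational(population)
    if pop <= 0:
        raise InvalidInputError("population must be positive")
    pregnant = round_half_up(params.pregnant_fraction * pop)
    under5 = round_half_up(params.under5_fraction * pop)
    return TargetBeneficiaries(pregnant, under5, pregnant + under5)


def vulnerable_subset(
    targets: TargetBeneficiaries, fraction: MoneyLike = Fraction(63, 100)
) -> TargetBeneficiaries:
    """Scale every beneficiary count by the below-poverty-line fraction.

    Each count is scaled and rounded half-up independently, including
    ``all_mch`` — matching how published vulnerable-group rows are derived
    from the printed ALL-MCH totals.
    """
    f = as_rational(fraction)
    if not 0 <= f <= 1:
        raise InvalidInputError(f"fraction must lie in [0, 1], got {f}")
    return TargetBeneficiaries(
        round_half_up(f * targets.pregnant_women),
        round_half_up(f * targets.under_five),
        round_half_up(f * targets.all_mch),
    )


def read_state_profiles(path: Union[str, Path]) -> list[StateProfile]:
    """Read state profiles from a delimited file with the documented columns.

    Expected columns: ``state_name, census_population, growth_rate,
    n_standard_facilities, n_lgas`` (comma- or tab-delimited, sniffed).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in STATE_PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"state profile file {path} missing columns: {missing}")
    return [
        StateProfile(
            state_name=str(row.state_name),
            census_population=int(row.census_population),
            growth_rate=as_rational(str(row.growth_rate)),
            n_standard_facilities=int(row.n_standard_facilities),
            n_lgas=int(row.n_lgas),
        )
        for row in df.itertuples(index=False)
    ]


def write_state_profiles(profiles: list[StateProfile], path: Union[str, Path]) -> None:
    """Write profiles back to the same delimited schema (CSV)."""
    pd.DataFrame(
        [
            {
                "state_name": p.state_name,
                "census_population": p.census_population,
                "growth_rate": float(p.growth_rate),
                "n_standard_facilities": p.n_standard_facilities,
                "n_lgas": p.n_lgas,
            }
            for p in profiles
        ],
        columns=STATE_PROFILE_COLUMNS,
    ).to_csv(path, index=False)
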