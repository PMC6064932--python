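"""Synthetic facility registers and cost ledgers.

Generates facility-year ledgers with the statistical structure the costing
pipeline assumes — monthly attendance by service, drug dispensing priced
from a price list, salary and overhead totals, capital inventories — so
that the end-to-end pipeline recovers configured per-component unit costs.

Construction guarantees the identity at zero noise: annual shared-cost
totals are set to ``target_unit_cost x visits_total`` so that after
weighting by the realized MCH utilization weight and dividing by MCH
visits, the pipeline returns the configured target exactly. Noise enters
as multiplicative lognormal jitter (mean one, coefficient of variation
``noise_cv``) on cost totals and prices, and gamma-Poisson dispersion on
visit counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np

from .costing import (
    CHILD_SERVICES,
    MATERNAL_SERVICES,
    CapitalItem,
    CostingParams,
    FacilityCostLedger,
    ServicePriceList,
    annualize_capital,
)
from .demography import StateProfile, write_state_profiles
from .errors import ConfigurationError
from .money import as_rational, round_half_up
from .presets import get_state_preset
from .reference import STATES

__all__ = ["SyntheticConfig", "StateBundle", "generate_facility_ledgers", "generate_state_bundle", "write_bundle"]

# shares of the capital requirement assigned to each asset category
_CAPITAL_SHARES = {"building": 0.5, "medical_equipment": 0.3, "transport": 0.15, "other": 0.05}


@dataclass(frozen=True)
class SyntheticConfig:
    """Recipe for a batch of synthetic facility ledgers.

    target_unit_costs
        Per-MCH-visit cost targets by component
        (``{"capital": ..., "personnel": ..., "overhead": ...}``) that the
        costing pipeline should recover.
    visit_volume_means
        Mean annual visits per service per facility.
    mch_weight
        Facility MCH utilization weight used to back out total outpatient
        volume.
    noise_cv
        Coefficient of variation for visit counts, cost totals and price
        jitter; zero gives deterministic, exactly-recoverable ledgers.
    """

    seed: int
    n_facilities: int
    target_unit_costs: Mapping[str, float]
    visit_volume_means: Mapping[str, float]
    price_list: ServicePriceList
    mch_weight: float = 0.85
    noise_cv: float = 0.0
    costing: CostingParams = field(default_factory=CostingParams)

    def __post_init__(self) -> None:
        if self.n_facilities < 1:
            raise ConfigurationError("n_facilities must be at least 1")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be nonnegative")
        if not 0 < self.mch_weight <= 1:
            raise ConfigurationError("mch_weight must lie in (0, 1]")
        unknown = set(self.target_unit_costs) - {"capital", "personnel", "overhead"}
        if unknown:
            raise ConfigurationError(f"unknown cost components {sorted(unknown)}")
        if any(v < 0 for v in self.target_unit_costs.values()):
            raise ConfigurationError("target unit costs must be nonnegative")
        bad = set(self.visit_volume_means) - set(MATERNAL_SERVICES) - set(CHILD_SERVICES)
        if bad:
            raise ConfigurationError(f"unknown services in visit_volume_means: {sorted(bad)}")
        if sum(self.visit_volume_means.values()) <= 0 and any(
            v > 0 for v in self.target_unit_costs.values()
        ):
            raise ConfigurationError("nonzero cost targets require nonzero visit volumes")


def _draw_count(rng: np.random.Generator, mean: float, cv: float) -> int:
    """Nonnegative count with the given mean and CV (gamma-Poisson)."""
    if mean <= 0:
        return 0
    if cv == 0:
        return int(round(mean))
    shape = 1.0 / cv**2
    lam = rng.gamma(shape, mean / shape)
    return int(rng.poisson(lam))


def _jitter(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative lognormal factor with mean 1 and CV ``cv``."""
    if cv == 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return float(rng.lognormal(-(sigma**2) / 2, sigma))


def generate_facility_ledgers(config: SyntheticConfig) -> list[FacilityCostLedger]:
    """Deterministically generate ``n_facilities`` ledgers for a config."""
    rng = np.random.default_rng(config.seed)
    params = config.costing
    af = {  # capital recovery: replacement cost per Naira of annual cost
        cat: 1 / annualize_capital(CapitalItem(cat, 1, life), params.discount_rate)
        for cat, life in params.useful_life_defaults.items()
    }
    ledgers = []
    for i in range(config.n_facilities):
        monthly = {
            s: [_draw_count(rng, m / 12, config.noise_cv) for _ in range(12)]
            for s, m in config.visit_volume_means.items()
        }
        annual = {s: sum(months) for s, months in monthly.items()}
        visits_mch = sum(annual.values())
        if visits_mch == 0:
            if any(v > 0 for v in config.target_unit_costs.values()):
                raise ConfigurationError(
                    "drew zero MCH visits against nonzero cost targets; "
                    "raise visit_volume_means or lower noise_cv"
                )
            visits_total = 0
        else:
            visits_total = max(visits_mch, round(visits_mch / config.mch_weight))

        targets = {k: as_rational(v) for k, v in config.target_unit_costs.items()}
        personnel = targets.get("personnel", Fraction(0)) * visits_total * as_rational(
            _jitter(rng, config.noise_cv)
        )
        overhead = targets.get("overhead", Fraction(0)) * visits_total * as_rational(
            _jitter(rng, config.noise_cv)
        )
        capital_requirement = targets.get("capital", Fraction(0)) * visits_total * as_rational(
            _jitter(rng, config.noise_cv)
        )
        capital_items = tuple(
            CapitalItem(
                category=cat,
                replacement_cost=capital_requirement * as_rational(share) * af[cat],
                useful_life=params.useful_life_defaults[cat],
                acquisition_year=2015,
            )
            for cat, share in _CAPITAL_SHARES.items()
            if capital_requirement > 0
        )
        drug_lines = tuple(
            (s, Fraction(annual[s]), config.price_list[s] * as_rational(_jitter(rng, config.noise_cv)))
            for s in sorted(annual)
            if annual[s] > 0 and s in config.price_list
        )
        ledgers.append(
            FacilityCostLedger(
                facility_id=f"facility_{i:03d}",
                capital_items=capital_items,
                personnel_annual=personnel,
                overhead_annual=overhead,
                drug_line_items=drug_lines,
                visits_total=visits_total,
                visits_mch=visits_mch,
            )
        )
    return ledgers


@dataclass(frozen=True)
class StateBundle:
    """Full synthetic input set for one state-like analysis."""

    profile: StateProfile
    ledgers: tuple[FacilityCostLedger, ...]
    price_list: ServicePriceList
    maternal_mix: Mapping[str, Fraction]
    child_mix: Mapping[str, Fraction]
    mch_weight: Fraction


def generate_state_bundle(
    state_like: str,
    seed: int,
    n_facilities: int = 12,
    noise_cv: float = 0.1,
) -> StateBundle:
    """Synthetic register bundle calibrated to one of the study states.

    Visit volumes follow the state's average annual maternal/child service
    utilization, distributed across services by the calibrated mixes;
    component cost targets are the state's published per-visit unit costs,
    so the end-to-end pipeline reproduces the state's unit-cost structure.
    """
    if state_like not in STATES:
        raise ConfigurationError(f"unknown state preset {state_like!r}; expected one of {STATES}")
    preset = get_state_preset(state_like)
    # distribute average annual utilization over services proportionally to
    # the package pathway: core maternal services once per pregnancy episode,
    # optional ones by mix weight; child services by mix share.
    m_weights = {s: 1.0 for s in ("anc", "normal_delivery", "pnc")}
    m_weights.update({s: float(w) for s, w in preset.maternal_mix.items() if w > 0})
    m_total = sum(m_weights.values())
    c_total = sum(float(w) for w in preset.child_mix.values())
    volumes: dict[str, float] = {
        s: preset.avg_maternal_visits * w / m_total for s, w in m_weights.items()
    }
    volumes.update(
        {
            s: preset.avg_child_visits * float(w) / c_total
            for s, w in preset.child_mix.items()
            if w > 0
        }
    )
    config = SyntheticConfig(
        seed=seed,
        n_facilities=n_facilities,
        target_unit_costs={k: float(v) for k, v in preset.component_unit_costs.items()},
        visit_volume_means=volumes,
        price_list=preset.price_list,
        mch_weight=float(preset.mch_weight),
        noise_cv=noise_cv,
    )
    return StateBundle(
        profile=preset.profile,
        ledgers=tuple(generate_facility_ledgers(config)),
        price_list=preset.price_list,
        maternal_mix=preset.maternal_mix,
        child_mix=preset.child_mix,
        mch_weight=preset.mch_weight,
    )


def write_bundle(bundle: StateBundle, outdir: Union[str, Path]) -> list[Path]:
    """Emit a bundle as the delimited files the costing module reads."""
    from .costing import write_facility_ledger

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    profile_path = outdir / "state_profiles.csv"
    write_state_profiles([bundle.profile], profile_path)
    written.append(profile_path)
    prices_path = outdir / "price_list.csv"
    bundle.price_list.to_csv(prices_path)
    written.append(prices_path)
    for ledger in bundle.ledgers:
        path = outdir / f"{ledger.facility_id}.ledger"
        write_facility_ledger(ledger, path)
        written.append(path)
    return written
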