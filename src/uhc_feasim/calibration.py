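"""Service-mix calibration against state package unit costs.

The utilization proportions with which optional maternal services and child
services enter the benefit package are not observable from aggregate
figures alone; they are identified here by constrained least squares
against per-state package unit costs, and the resulting mixes are shipped
as state presets.

Maternal: the core pregnancy pathway (ANC course, delivery, PNC) is fixed;
the weights of family planning and the three complication services absorb
the residual ``target - core`` via the minimum-norm solution
``w = residual * p / (p . p)``, which is automatically nonnegative for a
nonnegative residual.

Child: weights over the five child services must sum to one and be
nonnegative while reproducing the per-visit drug cost; solved as the
minimum-distance-from-uniform point of that affine slice, with a clamp-and-
resolve active set for nonnegativity.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

from .costing import (
    CHILD_SERVICES,
    MATERNAL_CORE_SERVICES,
    MATERNAL_OPTIONAL_SERVICES,
    CostingParams,
    ServicePriceList,
)
from .errors import ConfigurationError, InvalidInputError
from .money import MoneyLike, as_rational

__all__ = ["calibrate_maternal_mix", "calibrate_child_mix"]


def calibrate_maternal_mix(
    target_unit_cost: MoneyLike, prices: ServicePriceList
) -> dict[str, Fraction]:
    """Optional-service weights reproducing a maternal drugs-only unit cost."""
    target = as_rational(target_unit_cost)
    core = sum((prices[s] for s in MATERNAL_CORE_SERVICES), Fraction(0))
    residual = target - core
    if residual < 0:
        raise ConfigurationError(
            f"maternal target {float(target):.1f} is below the core pathway cost "
            f"{float(core):.1f}; no nonnegative mix exists"
        )
    p = [prices[s] for s in MATERNAL_OPTIONAL_SERVICES]
    denom = sum(x * x for x in p)
    if denom == 0:
        if residual != 0:
            raise ConfigurationError("all optional prices are zero but residual is nonzero")
        return {s: Fraction(0) for s in MATERNAL_OPTIONAL_SERVICES}
    weights = {s: residual * prices[s] / denom for s in MATERNAL_OPTIONAL_SERVICES}
    if any(w > 1 for w in weights.values()):
        raise ConfigurationError("calibrated maternal weight exceeds 1; target implausible")
    return weights


def calibrate_child_mix(
    target_unit_cost: MoneyLike,
    prices: ServicePriceList,
    params: CostingParams = CostingParams(),
) -> dict[str, Fraction]:
    """Sum-to-one service proportions reproducing a child drugs-only unit cost.

    Minimizes the distance from the uniform mix subject to
    ``sum w = 1``, ``3 * (p . w) = target``, ``w >= 0``.
    """
    target = as_rational(target_unit_cost)
    per_visit = float(target) / params.child_visits_per_year
    p_all = np.array([float(prices[s]) for s in CHILD_SERVICES])
    if not p_all.min() <= per_visit <= p_all.max():
        raise ConfigurationError(
            f"per-visit target {per_visit:.2f} outside the price range "
            f"[{p_all.min():.2f}, {p_all.max():.2f}]; no convex mix exists"
        )
    active = list(range(len(CHILD_SERVICES)))
    for _ in range(len(CHILD_SERVICES)):
        p = p_all[active]
        a_mat = np.vstack([p, np.ones_like(p)])
        b = np.array([per_visit, 1.0])
        center = np.full(len(active), 1.0 / len(active))
        w = center + a_mat.T @ np.linalg.solve(a_mat @ a_mat.T, b - a_mat @ center)
        if (w >= -1e-12).all():
            weights = {s: Fraction(0) for s in CHILD_SERVICES}
            for idx, val in zip(active, w):
                weights[CHILD_SERVICES[idx]] = Fraction(max(val, 0.0)).limit_denominator(10**9)
            # exact re-fit of one interior weight so the mix reproduces the
            # rational target identically despite float intermediates
            return _exact_refit(weights, target, prices, params)
        active = [idx for idx, val in zip(active, w) if val > 1e-12]
        if len(active) < 2:
            raise ConfigurationError("active-set collapsed; target not representable")
    raise ConfigurationError("child mix calibration did not converge")


def _exact_refit(
    weights: dict[str, Fraction],
    target: Fraction,
    prices: ServicePriceList,
    params: CostingParams,
) -> dict[str, Fraction]:
    """Nudge two nonzero weights so price and sum constraints hold exactly."""
    nz = [s for s, w in weights.items() if w > 0]
    if len(nz) < 2:
        raise ConfigurationError("need at least two nonzero weights for exact refit")
    # pick the two nonzero services with the largest price separation
    lo = min(nz, key=lambda s: prices[s])
    hi = max(nz, key=lambda s: prices[s])
    if prices[lo] == prices[hi]:
        raise InvalidInputError("degenerate prices; cannot refit exactly")
    per_visit = target / params.child_visits_per_year
    others = sum((weights[s] * prices[s] for s in weights if s not in (lo, hi)), Fraction(0))
    mass = 1 - sum((weights[s] for s in weights if s not in (lo, hi)), Fraction(0))
    # solve w_lo + w_hi = mass, w_lo*p_lo + w_hi*p_hi = per_visit - others
    w_hi = (per_visit - others - mass * prices[lo]) / (prices[hi] - prices[lo])
    w_lo = mass - w_hi
    if w_lo < 0 or w_hi < 0:
        raise ConfigurationError("exact refit produced negative weight")
    out = dict(weights)
    out[lo], out[hi] = w_lo, w_hi
    return out
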