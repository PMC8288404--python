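"""Wood/crop product-pool bookkeeping.

Harvested products enter per-class pools (short/medium/long-lived by
default), decay exponentially, and return CO2 (plus landfill CH4-carbon,
counted in carbon units here) to the atmosphere.  The pool stock change feeds
the budget's delta1/delta2 terms; the decay flux feeds the crop/wood product
oxidation sources of the residual-respiration equation.

The decay law is a single exponential per class (e-folding times and inflow
split are configurable), with inflow spread uniformly through the year, so
one annual step of a pool with stock ``s``, e-folding time ``tau`` and inflow
``I`` gives::

    s' = s * exp(-1/tau) + I * tau * (1 - exp(-1/tau))

and the released flux is whatever mass balance demands, exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .budget_core import FluxEstimate

#: Default relative 1-sigma uncertainty for product oxidation fluxes.
PRODUCT_FLUX_REL_SIGMA = 0.20


@dataclass(frozen=True)
class ProductPoolConfig:
    pool_classes: tuple[str, ...] = ("short", "medium", "long")
    efold_years: tuple[float, ...] = (2.0, 25.0, 35.0)
    class_split: tuple[float, ...] = (0.4, 0.3, 0.3)

    def __post_init__(self) -> None:
        if not (len(self.pool_classes) == len(self.efold_years) == len(self.class_split)):
            raise ValueError("pool_classes, efold_years and class_split must align")
        if any(t <= 0 for t in self.efold_years):
            raise ValueError("e-folding times must be > 0")
        if any(f < 0 for f in self.class_split):
            raise ValueError("class-split fractions must be >= 0")
        if abs(sum(self.class_split) - 1.0) > 1e-9:
            raise ValueError("class-split fractions must sum to 1")


@dataclass(frozen=True)
class PoolState:
    stocks: tuple[float, ...]
    year: int = 0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.stocks):
            raise ValueError("pool stocks must be >= 0")

    @property
    def total(self) -> float:
        return sum(self.stocks)

    @classmethod
    def empty(cls, config: ProductPoolConfig, year: int = 0) -> "PoolState":
        return cls(stocks=(0.0,) * len(config.pool_classes), year=year)


def step_pools(
    state: PoolState, inflow: float, config: ProductPoolConfig
) -> tuple[PoolState, float]:
    """Advance the pools one year; return (new state, decay flux PgC yr^-1).

    Mass balance ``inflow - decay_flux == delta stocks`` holds exactly (the
    flux is computed as the balance residual, so conservation is by
    construction at machine precision).
    """
    if inflow < 0:
        raise ValueError(f"inflow must be >= 0, got {inflow!r}")
    if len(state.stocks) != len(config.pool_classes):
        raise ValueError("state/config pool-class mismatch")
    new_stocks = []
    for s, tau, frac in zip(state.stocks, config.efold_years, config.class_split):
        decay = math.exp(-1.0 / tau)
        retained_inflow = inflow * frac * tau * (1.0 - decay)
        new_stocks.append(s * decay + retained_inflow)
    new_state = PoolState(stocks=tuple(new_stocks), year=state.year + 1)
    decay_flux = inflow - (new_state.total - state.total)
    return new_state, decay_flux


def run_pools(
    inflows: Sequence[float],
    config: ProductPoolConfig | None = None,
    initial: PoolState | None = None,
) -> tuple[PoolState, list[float]]:
    """Run a whole inflow series; return the final state and yearly fluxes."""
    config = config or ProductPoolConfig()
    state = initial or PoolState.empty(config)
    fluxes = []
    for inflow in inflows:
        state, flux = step_pools(state, inflow, config)
        fluxes.append(flux)
    return state, fluxes


def product_pool_delta(before: PoolState, after: PoolState) -> float:
    """Stock-change term under the atmospheric sign convention.

    Pool growth stores carbon, so it is negative (like delta2 in the budget).
    """
    return -(after.total - before.total)


def crop_consumption(
    harvest: float,
    net_export: float,
    storage_delta1: float = 0.0,
    rel_sigma: float = PRODUCT_FLUX_REL_SIGMA,
) -> FluxEstimate:
    """CO2 (plus digestive CH4-carbon) from consuming harvested crop products.

    consumption = harvest - net export - storage increase.  ``storage_delta1``
    uses the atmospheric convention (negative = pool growth), so a growing
    product pool reduces the flux and a drawdown adds to it.
    """
    if harvest < 0:
        raise ValueError("harvest must be >= 0")
    value = harvest - net_export + storage_delta1
    if value < -1e-12:
        raise ValueError(
            f"crop consumption cannot be negative (got {value:.4f}); "
            "check harvest/trade/storage inputs"
        )
    value = max(value, 0.0)
    return FluxEstimate(value=value, sigma=rel_sigma * value)


def wood_emission(
    decay_flux: float,
    fuelwood: float,
    burn_emission_factor: float = 0.9,
    rel_sigma: float = PRODUCT_FLUX_REL_SIGMA,
) -> FluxEstimate:
    """Carbon emission from wood-product decay plus fuelwood burning."""
    if decay_flux < 0 or fuelwood < 0:
        raise ValueError("decay flux and fuelwood use must be >= 0")
    if not (0.0 < burn_emission_factor <= 1.0):
        raise ValueError("burn emission factor must lie in (0, 1]")
    value = decay_flux + fuelwood * burn_emission_factor
    return FluxEstimate(value=value, sigma=rel_sigma * value)
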