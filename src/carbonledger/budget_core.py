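"""Regional carbon-budget arithmetic: bottom-up net ecosystem exchange (NEE).

Everything here works in PgC yr^-1 under the atmospheric sign convention:

* NEE < 0 means the region is a net sink of atmospheric CO2;
* carbon-stock-change components (the deltas) are < 0 when storage increases;
* river export components and gross trade flows are >= 0.

A region's NEE is the stock change corrected for carbon that crossed the
region's boundary without touching the regional atmosphere::

    NEE = dC - F_rivers - F_trade

Carbon fixed from the atmosphere and then exported (by rivers, or as traded
crop/wood products) does not appear in the stock inventories, so lateral
exports make NEE a larger sink than dC alone; net imports, which are oxidized
in-region, make it a smaller one.  Only the biogenic share of riverine DIC
counts: carbonate weathering takes half of each mole of exported DIC from the
rock reservoir, not the atmosphere, and that lithogenic half is excluded
(as is the matching stock term delta5).

Uncertainties are 1-sigma and are propagated in quadrature, assuming
independent Gaussian errors for each term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

#: The nine RECCAP land regions used throughout.
REGIONS: tuple[str, ...] = (
    "North America",
    "South America",
    "Europe",
    "Africa",
    "Russia",
    "East Asia",
    "South Asia",
    "Southeast Asia",
    "Australia",
)

TROPICAL_REGIONS: tuple[str, ...] = (
    "South America",
    "Africa",
    "South Asia",
    "Southeast Asia",
)

NORTHERN_REGIONS: tuple[str, ...] = ("Europe", "East Asia", "North America", "Russia")

#: Named non-SHR atmospheric source fluxes entering the residual equation.
SOURCE_NAMES: tuple[str, ...] = (
    "crop",
    "wood",
    "grazing",
    "fires_residue",
    "fires_other",
    "luc",
    "reduced",
    "outgas_rivers_lakes",
    "outgas_estuaries",
)

#: Sources carrying more than one alternative data product.
MULTI_PRODUCT_SOURCES: tuple[str, ...] = ("fires_other", "luc", "outgas_rivers_lakes")

#: Default NEE of land areas outside the nine regions (PgC yr^-1).
DEFAULT_NON_RECCAP_SINK = -0.4

#: Default background (pre-anthropogenic) natural land sink (PgC yr^-1),
#: derived from the printed -2.8 total and -2.2 anthropogenic values.
DEFAULT_BACKGROUND_SINK = -0.6

#: Tropical soil-stock bias bound: inventories that ignore tropical soil
#: carbon may understate dC3 by ~26%.  Off by default (a bound, not a fix).
TROPICAL_SOIL_BIAS_FACTOR = 1.26


def round_printed(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, matching printed-table conventions."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _check_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"{name}: non-finite value {v!r}")


@dataclass(frozen=True)
class FluxEstimate:
    """A single flux term: central value, 1-sigma error, optional products.

    ``products`` holds alternative (value, sigma) estimates from independent
    data products; when present, the headline ``value`` is their unweighted
    mean (enforced) and the Monte-Carlo engine samples among them.
    """

    value: float
    sigma: float = 0.0
    products: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        _check_finite("FluxEstimate.value", self.value)
        if not math.isfinite(self.sigma) or self.sigma < 0:
            raise ValueError(f"sigma must be finite and >= 0, got {self.sigma!r}")
        if self.products is not None:
            if len(self.products) == 0:
                raise ValueError("products, if given, must be non-empty")
            for v, s in self.products:
                _check_finite("product value", v)
                if s < 0:
                    raise ValueError("product sigma must be >= 0")
            mean = sum(v for v, _ in self.products) / len(self.products)
            if abs(mean - self.value) > 1e-9:
                raise ValueError(
                    f"headline value {self.value} is not the product mean {mean}"
                )

    @classmethod
    def from_products(cls, products: Sequence[tuple[float, float]]) -> "FluxEstimate":
        """Build an estimate whose value is the unweighted product mean."""
        prods = tuple((float(v), float(s)) for v, s in products)
        mean = sum(v for v, _ in prods) / len(prods)
        sigma = math.sqrt(sum(s * s for _, s in prods)) / len(prods)
        return cls(value=mean, sigma=sigma, products=prods)

    def scaled(self, factor: float) -> "FluxEstimate":
        prods = (
            tuple((v * factor, s * abs(factor)) for v, s in self.products)
            if self.products is not None
            else None
        )
        return FluxEstimate(self.value * factor, self.sigma * abs(factor), prods)


@dataclass(frozen=True)
class StockChange:
    """Inventory stock-change components (negative = storage increase).

    delta5 (lithogenic loss of carbonate rock to weathering) is carried for
    completeness but never enters dC: it is not an atmospheric exchange.
    """

    delta1_crop_products: FluxEstimate
    delta2_wood_products: FluxEstimate
    delta3_biomass_litter_soil: FluxEstimate
    delta4_inland_water_burial: FluxEstimate
    delta5_lithogenic_weathering: FluxEstimate


@dataclass(frozen=True)
class RiverExport:
    """Riverine carbon export to the ocean, split by species and origin."""

    doc: FluxEstimate
    poc: FluxEstimate
    dic_carbonate: FluxEstimate
    dic_silicate: FluxEstimate


@dataclass(frozen=True)
class TradeFlux:
    """Gross trade flows of crop and wood products (all >= 0)."""

    crop_export: FluxEstimate
    crop_import: FluxEstimate
    wood_export: FluxEstimate
    wood_import: FluxEstimate


@dataclass(frozen=True)
class RegionalBudget:
    """One region's complete budget: stocks, lateral fluxes, NPP, sources."""

    region: str
    stock: StockChange
    rivers: RiverExport
    trade: TradeFlux
    #: Alternative regional NPP products as (value, sigma); value < 0 = uptake.
    npp_products: tuple[tuple[float, float], ...]
    non_shr_sources: Mapping[str, FluxEstimate] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [n for n in SOURCE_NAMES if n not in self.non_shr_sources]
        if missing:
            raise ValueError(
                f"region {self.region!r}: missing non-SHR sources {missing}"
            )
        if len(self.npp_products) < 1:
            raise ValueError(f"region {self.region!r}: needs >= 1 NPP product")

    @property
    def npp_central(self) -> float:
        """Unweighted mean of the NPP products (PgC yr^-1, negative)."""
        return sum(v for v, _ in self.npp_products) / len(self.npp_products)


@dataclass(frozen=True)
class BudgetTable:
    """The regional collection plus global scalar adjustments."""

    regions: Mapping[str, RegionalBudget]
    non_reccap_sink: float = DEFAULT_NON_RECCAP_SINK
    background_sink: float = DEFAULT_BACKGROUND_SINK

    def __post_init__(self) -> None:
        for name, budget in self.regions.items():
            if budget.region != name:
                raise ValueError(f"region key {name!r} != budget.region {budget.region!r}")

    def require_complete(self) -> None:
        missing = [r for r in REGIONS if r not in self.regions]
        if missing:
            raise ValueError(f"budget table missing regions: {missing}")


# ---------------------------------------------------------------------------
# operations

def aggregate(estimates: Sequence[FluxEstimate]) -> FluxEstimate:
    """Sum of flux estimates with root-sum-of-squares uncertainty."""
    if len(estimates) == 0:
        raise ValueError("cannot aggregate an empty list of estimates")
    value = sum(e.value for e in estimates)
    sigma = math.sqrt(sum(e.sigma**2 for e in estimates))
    return FluxEstimate(value=value, sigma=sigma)


def delta_c(stock: StockChange) -> FluxEstimate:
    """Total stock change dC = d1 + d2 + d3 + d4 (d5 excluded)."""
    return aggregate(
        [
            stock.delta1_crop_products,
            stock.delta2_wood_products,
            stock.delta3_biomass_litter_soil,
            stock.delta4_inland_water_burial,
        ]
    )


def biogenic_river_flux(rivers: RiverExport) -> FluxEstimate:
    """Atmosphere-derived share of river export.

    DOC, POC and silicate-weathering DIC are fully biogenic (silicate
    weathering consumes one mole of atmospheric CO2 per mole of DIC).
    Carbonate weathering consumes only half a mole from the atmosphere per
    mole of DIC, so half of the carbonate DIC is lithogenic and excluded.
    """
    comps = {
        "doc": rivers.doc,
        "poc": rivers.poc,
        "dic_carbonate": rivers.dic_carbonate,
        "dic_silicate": rivers.dic_silicate,
    }
    for name, c in comps.items():
        _check_finite(f"rivers.{name}", c.value)
        if c.value < 0:
            raise ValueError(f"river component {name} has negative central value")
    return aggregate(
        [rivers.doc, rivers.poc, rivers.dic_silicate, rivers.dic_carbonate.scaled(0.5)]
    )


def net_trade(trade: TradeFlux) -> FluxEstimate:
    """Net trade flux: exports minus imports (positive = net exporter)."""
    comps = {
        "crop_export": trade.crop_export,
        "crop_import": trade.crop_import,
        "wood_export": trade.wood_export,
        "wood_import": trade.wood_import,
    }
    for name, c in comps.items():
        if c.value < 0:
            raise ValueError(f"gross trade flow {name} must be >= 0")
    return aggregate(
        [
            trade.crop_export,
            trade.wood_export,
            trade.crop_import.scaled(-1.0),
            trade.wood_import.scaled(-1.0),
        ]
    )


def regional_nee(
    budget: RegionalBudget,
    *,
    tropical_soil_bias: bool = False,
    bias_factor: float = TROPICAL_SOIL_BIAS_FACTOR,
) -> FluxEstimate:
    """Bottom-up regional NEE = dC - F_rivers - F_trade.

    With ``tropical_soil_bias`` the biomass/litter/soil stock term of the four
    tropical regions is inflated by ``bias_factor`` to probe the effect of
    soil-carbon changes being ignored in tropical inventories.
    """
    stock = budget.stock
    if tropical_soil_bias and budget.region in TROPICAL_REGIONS:
        stock = replace(
            stock,
            delta3_biomass_litter_soil=stock.delta3_biomass_litter_soil.scaled(bias_factor),
        )
    dc = delta_c(stock)
    rivers = biogenic_river_flux(budget.rivers)
    trade = net_trade(budget.trade)
    value = dc.value - rivers.value - trade.value
    sigma = math.sqrt(dc.sigma**2 + rivers.sigma**2 + trade.sigma**2)
    return FluxEstimate(value=value, sigma=sigma)


def source_total(budget: RegionalBudget) -> FluxEstimate:
    """Sum of the region's non-SHR atmospheric sources."""
    return aggregate([budget.non_shr_sources[n] for n in SOURCE_NAMES])


def global_nee(
    table: BudgetTable,
    non_reccap_sink: float | None = None,
    background_sink: float | None = None,
    **nee_kwargs,
) -> tuple[FluxEstimate, FluxEstimate]:
    """Global total and anthropogenic NEE.

    total = sum of the nine regional NEE values plus the scalar sink of land
    outside the regions; anthropogenic = total minus the scalar background
    natural sink.  Both scalars default to the table's stored adjustments and
    carry no uncertainty of their own.
    """
    table.require_complete()
    nrs = table.non_reccap_sink if non_reccap_sink is None else non_reccap_sink
    bgs = table.background_sink if background_sink is None else background_sink
    regional = aggregate([regional_nee(table.regions[r], **nee_kwargs) for r in REGIONS])
    total = FluxEstimate(value=regional.value + nrs, sigma=regional.sigma)
    anthropogenic = FluxEstimate(value=total.value - bgs, sigma=total.sigma)
    return total, anthropogenic
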