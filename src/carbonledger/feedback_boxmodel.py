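"""Reduced-form coupled carbon-climate box model (SIM-1 vs SIM-2).

A deliberately small structural analogue of the emulator experiment: one
well-mixed atmosphere, one soil box, an inert ocean/export sink, log-CO2
fertilization of NPP, Q10 respiration, and temperature proportional to log
radiative forcing.  The experiment contrasts

* SIM-1: all NPP reaches the soil as litterfall (the configuration of
  current-generation land-carbon models), and
* SIM-2: a fraction of NPP is removed laterally before litterfall (harvest,
  grazing, fires, riverine leaching), oxidized back to the atmosphere within
  the year except for a river share partly exported to the ocean.  The
  fraction is calibrated so the present-day modeled SHR/NPP ratio matches
  the budget-derived estimate.

Diagnostics are the concentration-carbon and climate-carbon feedback
parameters of the soil box (beta_soil in PgC per ppm, gamma_soil in PgC per
K) from biogeochemically- and radiatively-coupled runs, plus end-of-century
CO2 and temperature.  Only sign and ordering claims are meaningful at this
level of reduction; nothing here emulates specific Earth System Models.

Units: carbon in PgC, fluxes in PgC yr^-1, CO2 in ppm (2.124 PgC per ppm),
temperature anomaly in K.  Integration is annual explicit Euler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

PGC_PER_PPM = 2.124


def rcp85_like_emissions(years: np.ndarray) -> np.ndarray:
    """High-end fossil-fuel emissions path (PgC yr^-1).

    Exponential growth (~2.5%/yr) up to 8 PgC yr^-1 in 2000, then a linear
    ramp to 28 PgC yr^-1 by 2100 - the shape, not the digits, of the
    high-emissions scenario family.
    """
    years = np.asarray(years, dtype=float)
    e = np.where(
        years <= 2000.0,
        8.0 * np.exp(0.025 * (years - 2000.0)),
        8.0 + 0.2 * (years - 2000.0),
    )
    return e


@dataclass(frozen=True)
class BoxModelConfig:
    npp0: float = 50.0  # preindustrial NPP magnitude, PgC yr^-1
    tau_soil: float = 30.0  # baseline soil turnover, yr
    csoil0: float | None = None  # PgC; None = equilibrated start
    beta_fert: float = 0.6  # log-CO2 fertilization factor
    q10: float = 2.0  # respiration temperature sensitivity
    lateral_fraction: float = 0.0  # share of NPP removed before litterfall
    river_fraction: float = 0.075  # share of lateral flux routed to rivers
    river_outgas_fraction: float = 0.5  # share of river flux outgassed
    river_T_sens: float = 0.06  # river-flux sensitivity per K
    river_npp_sens: float = 0.3  # river-flux sensitivity per unit rel. NPP
    climate_sensitivity: float = 3.0  # K per CO2 doubling
    ocean_uptake_fraction: float = 0.45  # share of annual emissions to ocean
    co2_0_ppm: float = 285.0
    t_start: int = 1850
    t_end: int = 2100
    emissions: Callable[[np.ndarray], np.ndarray] | Sequence[float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.lateral_fraction < 1.0:
            raise ValueError("lateral_fraction must lie in [0, 1)")
        if self.q10 <= 0 or self.tau_soil <= 0 or self.npp0 <= 0:
            raise ValueError("q10, tau_soil and npp0 must be > 0")
        for name in ("river_fraction", "river_outgas_fraction", "ocean_uptake_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def emissions_series(self, years: np.ndarray) -> np.ndarray:
        if self.emissions is None:
            return rcp85_like_emissions(years)
        if callable(self.emissions):
            return np.asarray(self.emissions(years), dtype=float)
        e = np.asarray(self.emissions, dtype=float)
        if e.size != years.size:
            raise ValueError(
                f"emissions path covers {e.size} years, simulation needs {years.size}"
            )
        return e


@dataclass
class Trajectory:
    """Yearly state and flux series of one run."""

    year: np.ndarray
    co2_ppm: np.ndarray
    temp_K: np.ndarray
    csoil: np.ndarray
    npp: np.ndarray  # magnitude, PgC yr^-1
    shr: np.ndarray
    lateral: np.ndarray
    river_outgas: np.ndarray
    ocean: np.ndarray  # cumulative ocean + export sink, PgC
    max_drift: float = 0.0  # worst per-step carbon-conservation residual, PgC

    def at_year(self, y: int) -> int:
        idx = np.nonzero(self.year == y)[0]
        if idx.size == 0:
            raise KeyError(f"year {y} not in trajectory")
        return int(idx[0])

    def river_outgas_change_pct(
        self, ref: tuple[int, int] = (2000, 2009), year: int = 2100
    ) -> float:
        """% change of river outgassing at ``year`` vs the ``ref`` mean."""
        lo, hi = (self.at_year(y) for y in ref)
        base = float(self.river_outgas[lo : hi + 1].mean())
        if base == 0.0:
            raise ZeroDivisionError("no river outgassing in the reference window")
        return (float(self.river_outgas[self.at_year(year)]) / base - 1.0) * 100.0


def run(
    config: BoxModelConfig,
    mode: str = "sim1",
    *,
    co2_coupling: bool = True,
    climate_coupling: bool = True,
) -> Trajectory:
    """Integrate the coupled model.

    ``mode="sim1"`` forces the lateral fraction to zero; ``"sim2"`` uses the
    configured value.  The coupling switches support the feedback
    diagnostics: ``climate_coupling=False`` pins the temperature anomaly at
    zero (biogeochemical run); ``co2_coupling=False`` pins NPP at its
    preindustrial value (radiative run).
    """
    if mode not in ("sim1", "sim2"):
        raise ValueError(f"mode must be 'sim1' or 'sim2', got {mode!r}")
    f = 0.0 if mode == "sim1" else config.lateral_fraction

    years = np.arange(config.t_start, config.t_end + 1)
    emis = config.emissions_series(years)
    nyr = years.size

    atm = config.co2_0_ppm * PGC_PER_PPM
    soil = config.csoil0 if config.csoil0 is not None else (1.0 - f) * config.npp0 * config.tau_soil
    ocean = 0.0
    total0 = atm + soil + ocean

    # Preindustrial river export to the ocean is part of the closed natural
    # cycle (returned to the atmosphere by the ocean elsewhere), so a
    # constant compensation flux keeps the unforced state in equilibrium;
    # only export anomalies act as a net sink.
    river0 = config.river_fraction * f * config.npp0
    export0 = (1.0 - config.river_outgas_fraction) * river0

    out = {k: np.empty(nyr) for k in ("co2_ppm", "temp_K", "csoil", "npp", "shr", "lateral", "river_outgas", "ocean")}
    max_drift = 0.0
    cum_e = 0.0

    for i in range(nyr):
        co2 = atm / PGC_PER_PPM
        if co2 <= 0:
            raise ValueError(f"non-physical state: CO2 {co2:.2f} ppm in {years[i]}")
        logr = math.log(co2 / config.co2_0_ppm)
        temp = config.climate_sensitivity * logr / math.log(2.0) if climate_coupling else 0.0
        npp = (
            config.npp0 * (1.0 + config.beta_fert * logr)
            if co2_coupling
            else config.npp0
        )
        if npp < 0:
            npp = 0.0
        shr = soil / config.tau_soil * config.q10 ** (temp / 10.0)

        lateral = f * npp
        river = config.river_fraction * lateral * (
            1.0
            + config.river_T_sens * temp
            + config.river_npp_sens * (npp / config.npp0 - 1.0)
        )
        river = min(max(river, 0.0), lateral)
        outgas = config.river_outgas_fraction * river
        export = river - outgas
        oxidized = lateral - river

        e = float(emis[i])
        uptake = config.ocean_uptake_fraction * e

        d_atm = e - uptake - npp + shr + oxidized + outgas + export0
        d_soil = (1.0 - f) * npp - shr
        d_ocean = uptake + export - export0

        atm += d_atm
        soil += d_soil
        ocean += d_ocean
        cum_e += e
        if soil < 0 or atm < 0:
            raise ValueError(
                f"non-physical state in {years[i]}: atm={atm:.1f} PgC, soil={soil:.1f} PgC"
            )
        drift = abs((atm + soil + ocean) - total0 - cum_e)
        max_drift = max(max_drift, drift)

        out["co2_ppm"][i] = atm / PGC_PER_PPM
        out["temp_K"][i] = temp
        out["csoil"][i] = soil
        out["npp"][i] = npp
        out["shr"][i] = shr
        out["lateral"][i] = lateral
        out["river_outgas"][i] = outgas
        out["ocean"][i] = ocean

    return Trajectory(year=years, max_drift=max_drift, **out)


def diagnose_beta_gamma(config: BoxModelConfig, mode: str = "sim1") -> tuple[float, float]:
    """Soil feedback parameters from two partially-coupled runs.

    beta_soil: soil-carbon change per ppm CO2 rise in a run with temperature
    held at zero.  gamma_soil: soil-carbon change per K warming in a run with
    the CO2 effect on NPP disabled.
    """
    bgc = run(config, mode, climate_coupling=False)
    d_co2 = bgc.co2_ppm[-1] - bgc.co2_ppm[0]
    if abs(d_co2) < 1e-9:
        raise ZeroDivisionError("no CO2 forcing applied; beta_soil undefined")
    beta = (bgc.csoil[-1] - bgc.csoil[0]) / d_co2

    rad = run(config, mode, co2_coupling=False)
    d_t = rad.temp_K[-1] - rad.temp_K[0]
    if abs(d_t) < 1e-9:
        raise ZeroDivisionError("no warming realized; gamma_soil undefined")
    gamma = (rad.csoil[-1] - rad.csoil[0]) / d_t
    return beta, gamma


def present_day_shr_npp_ratio(
    config: BoxModelConfig, mode: str = "sim2", window: tuple[int, int] = (2000, 2009)
) -> float:
    """Modeled SHR/NPP over the present-day window of a fully coupled run."""
    traj = run(config, mode)
    lo, hi = (traj.at_year(y) for y in window)
    return float(traj.shr[lo : hi + 1].mean() / traj.npp[lo : hi + 1].mean())


def calibrate_lateral_fraction(
    target_shr_npp_ratio: float,
    config: BoxModelConfig,
    tol: float = 1e-3,
    f_max: float = 0.98,
) -> float:
    """Lateral fraction whose present-day SHR/NPP ratio matches the target.

    The ratio decreases monotonically with the removed fraction, so a simple
    bracketing root search converges; the fitted fraction is verified to
    reproduce the target within ``tol``.
    """
    if not 0.0 < target_shr_npp_ratio < 1.0:
        raise ValueError("target ratio must lie in (0, 1)")

    def ratio_at(f: float) -> float:
        return present_day_shr_npp_ratio(replace(config, lateral_fraction=f), "sim2")

    r0 = ratio_at(0.0)
    if target_shr_npp_ratio > r0:
        if abs(target_shr_npp_ratio - r0) <= tol:
            return 0.0
        raise ValueError(
            f"target ratio {target_shr_npp_ratio:.3f} exceeds the zero-removal "
            f"ratio {r0:.3f}; unattainable in [0, 1)"
        )
    if target_shr_npp_ratio < ratio_at(f_max):
        raise ValueError(
            f"target ratio {target_shr_npp_ratio:.3f} below the ratio at "
            f"lateral_fraction={f_max}; unattainable"
        )
    f = brentq(
        lambda x: ratio_at(x) - target_shr_npp_ratio, 0.0, f_max, xtol=1e-6
    )
    achieved = ratio_at(f)
    if abs(achieved - target_shr_npp_ratio) > tol:
        raise RuntimeError(
            f"calibration failed: achieved ratio {achieved:.4f} vs target "
            f"{target_shr_npp_ratio:.4f}"
        )
    return float(f)
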