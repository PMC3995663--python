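"""Autotroph stock updates: growth from NPP forcing and leaf mortality.

Marine cells hold one phytoplankton stock whose biomass is incremented
directly from the monthly NPP forcing (standing biomass is assumed able to
generate the observed productivity each step; its only loss is grazing).
Terrestrial cells hold deciduous and evergreen leaf pools: monthly NPP is
converted to wet matter, the structural allocation is discarded (only
leaves are edible), the remainder is split between the leaf strategies by a
climate-driven evergreen fraction, and leaves die at climate-modulated
annual rates.  Stock updates obey ``delta B = gain - loss`` exactly each
step; herbivory losses are applied separately by the feeding processes.
"""

from __future__ import annotations

import math

import numpy as np

from .core_state import Stock
from .forcing import ForcingSeries
from .params import AutotrophParams, NumericsParams

__all__ = [
    "npp_to_wet_matter_kg",
    "grow_phytoplankton",
    "structural_fraction",
    "evergreen_fraction",
    "grow_terrestrial_leaves",
    "leaf_mortality",
]

_G_PER_M2_TO_KG_PER_KM2 = 1.0e3  # g C m^-2  ->  kg C km^-2


def npp_to_wet_matter_kg(
    npp_gC_m2_month: float,
    area_km2: float,
    carbon_to_wet: float,
    months_per_step: float,
) -> float:
    """Convert areal monthly NPP to wet-matter kg produced in one step."""
    if npp_gC_m2_month < 0:
        raise ValueError("NPP must be >= 0")
    return (
        npp_gC_m2_month * _G_PER_M2_TO_KG_PER_KM2 * area_km2
        * carbon_to_wet * months_per_step
    )


def grow_phytoplankton(
    stock: Stock,
    npp_gC_m2_month: float,
    area_km2: float,
    params: AutotrophParams,
    numerics: NumericsParams,
) -> float:
    """Increment the phytoplankton stock from NPP forcing; returns the gain."""
    if stock.leaf_strategy != "n/a":
        raise ValueError("grow_phytoplankton expects the marine phytoplankton stock")
    gain = npp_to_wet_matter_kg(
        npp_gC_m2_month, area_km2, params.carbon_to_wet_marine,
        numerics.months_per_step,
    )
    stock.total_biomass_kg += gain
    return gain


def _logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def structural_fraction(forcing: ForcingSeries, params: AutotrophParams) -> float:
    """Fraction of NPP allocated to inedible structural tissue.

    A logistic response to annual NPP: productive (forest-forming) climates
    allocate more to wood and other structure.
    """
    annual_npp = float(np.sum(forcing.npp_gC_m2_month))
    f = params.f_struct_min + (params.f_struct_max - params.f_struct_min) * _logistic(
        (annual_npp - params.f_struct_npp0_gC_m2_yr) / params.f_struct_npp_scale
    )
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"structural fraction outside [0, 1]: {f}")
    return f


def evergreen_fraction(forcing: ForcingSeries, params: AutotrophParams) -> float:
    """Proportion of leaf production carried by evergreen canopies.

    A logistic response to the coldest monthly temperature: mild winters
    favour evergreen leaves, cold-seasonal climates favour deciduous ones.
    """
    coldest = float(np.min(forcing.temperature_C))
    f = _logistic((coldest - params.f_ever_temp0_C) / params.f_ever_temp_scale)
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"evergreen fraction outside [0, 1]: {f}")
    return f


def grow_terrestrial_leaves(
    stocks: list[Stock],
    forcing: ForcingSeries,
    month: int,
    area_km2: float,
    params: AutotrophParams,
    numerics: NumericsParams,
) -> dict[str, float]:
    """Add this month's leaf production to the deciduous/evergreen stocks.

    Total edible gain is ``NPP * A * psi * dt * (1 - f_struct)``, split
    ``f_ever`` to the evergreen stock and ``1 - f_ever`` to the deciduous
    one.  Returns the per-strategy gains.
    """
    by_strategy = {s.leaf_strategy: s for s in stocks}
    if set(by_strategy) != {"deciduous", "evergreen"}:
        raise ValueError("terrestrial growth expects one deciduous and one evergreen stock")
    total = npp_to_wet_matter_kg(
        float(forcing.npp_gC_m2_month[month]), area_km2,
        params.carbon_to_wet_terrestrial, numerics.months_per_step,
    ) * (1.0 - structural_fraction(forcing, params))
    f_ever = evergreen_fraction(forcing, params)
    gains = {"evergreen": total * f_ever, "deciduous": total * (1.0 - f_ever)}
    for strategy, gain in gains.items():
        by_strategy[strategy].total_biomass_kg += gain
    return gains


def _deciduous_seasonal_weights(forcing: ForcingSeries, params: AutotrophParams) -> np.ndarray:
    """Monthly weights concentrating deciduous leaf fall in cold months.

    Weights are a logistic function of monthly temperature, normalised to
    average 1 over the year so the annual mortality rate is preserved; an
    aseasonal climate yields uniform weights.
    """
    t = forcing.temperature_C
    w = 1.0 / (
        1.0 + np.exp((t - params.deciduous_fall_temp0_C) / params.deciduous_fall_temp_scale)
    )
    total = float(np.sum(w))
    if total <= 0.0:
        return np.ones(12)
    return w * (12.0 / total)


def leaf_mortality(
    stock: Stock,
    forcing: ForcingSeries,
    month: int,
    params: AutotrophParams,
    numerics: NumericsParams,
) -> float:
    """Remove this step's leaf mortality from a terrestrial stock.

    Annual rates are converted to the time step with the engine's
    exponential-decay discretisation, ``loss = B * (1 - exp(-mu * dt))``,
    which keeps the stock non-negative for any rate.  Deciduous mortality is
    seasonally concentrated in cold months through the same climate
    responses as growth; evergreen mortality is spread evenly.
    """
    if stock.leaf_strategy == "n/a":
        raise ValueError("leaf_mortality applies to terrestrial leaf stocks only")
    if stock.leaf_strategy == "evergreen":
        mu_annual = params.mu_evergreen_per_year
        weight = 1.0
    else:
        mu_annual = params.mu_deciduous_per_year
        weight = float(_deciduous_seasonal_weights(forcing, params)[month])
    mu_annual *= params.leaf_fraction_of_mortality
    # a monthly step is exactly 1/12 year for annual-rate conversion
    dt_years = numerics.months_per_step / 12.0
    loss = stock.total_biomass_kg * (1.0 - math.exp(-mu_annual * weight * dt_years))
    stock.total_biomass_kg -= loss
    return loss
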