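"""Emergent community diagnostics: trophic pyramids, mass-abundance
spectra, and life-history summaries.

Trophic levels are assigned by functional-group feeding mode (autotroph,
herbivore, omnivore, carnivore).  All metrics are emitted as tidy tables
(one row per level, bin, or cohort record) suitable for external plotting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_state import Cohort
from .params import NumericsParams

__all__ = [
    "TrophicSummary",
    "trophic_pyramid",
    "mass_abundance_spectrum",
    "life_history_summaries",
    "MORTALITY_RATE_CAP_PER_YEAR",
]

TROPHIC_LEVELS = ("autotroph", "herbivore", "omnivore", "carnivore")

#: the minimum resolvable lifespan is one monthly time step, so
#: lifespan-inverse mortality estimates are bounded at 12 per year
MORTALITY_RATE_CAP_PER_YEAR = 12.0


@dataclass
class TrophicSummary:
    """Annual-mean standing stocks and inter-level fluxes for one cell."""

    biomass_density_kg_km2: dict = field(default_factory=dict)
    abundance_density_km2: dict = field(default_factory=dict)
    #: flux as percent of the source level's standing stock per year,
    #: keyed (source level, destination level)
    flux_percent_of_source: dict = field(default_factory=dict)
    #: NPP as percent of autotroph standing stock per year
    npp_percent_of_autotroph: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "trophic_level": tl,
                "biomass_density_kg_km2": self.biomass_density_kg_km2.get(tl, 0.0),
                "abundance_density_km2": self.abundance_density_km2.get(tl, float("nan")),
            }
            for tl in TROPHIC_LEVELS
        ]
        return pd.DataFrame(rows)


def trophic_pyramid(
    history: pd.DataFrame,
    fluxes: pd.DataFrame,
    area_km2: float,
    steps_per_year: int = 12,
    window_steps: int | None = None,
) -> TrophicSummary:
    """Aggregate a run's final window into a trophic biomass pyramid.

    ``history`` and ``fluxes`` are the tables produced by the engine.  The
    window defaults to the final year.  Standing stocks are annual means of
    biomass/abundance density by trophic level; flux percentages are the
    window's summed inter-level transfers divided by the source level's
    standing stock.
    """
    if history.empty:
        raise ValueError("empty history: need at least one recorded step")
    window_steps = window_steps or steps_per_year
    last = int(history["step"].max())
    lo = last - window_steps + 1
    h = history[history["step"] >= lo]
    fx = fluxes[fluxes["step"] >= lo]

    summary = TrophicSummary()
    grouped = h.groupby(["step", "trophic_level"])["biomass_density_kg_km2"].sum()
    mean_biomass = grouped.groupby("trophic_level").mean()
    ab = h.dropna(subset=["abundance_density_km2"]).groupby(
        ["step", "trophic_level"]
    )["abundance_density_km2"].sum().groupby("trophic_level").mean()
    for tl in TROPHIC_LEVELS:
        summary.biomass_density_kg_km2[tl] = float(mean_biomass.get(tl, 0.0))
        if tl != "autotroph":
            summary.abundance_density_km2[tl] = float(ab.get(tl, 0.0))

    per_year = steps_per_year / window_steps  # rescale window totals to a year
    transfers = {
        ("autotroph", "herbivore"): fx["herbivory_by_herbivores"].sum(),
        ("autotroph", "omnivore"): fx["herbivory_by_omnivores"].sum(),
    }
    for consumer, dest in (("omnivores", "omnivore"), ("carnivores", "carnivore")):
        for prey in ("herbivore", "omnivore", "carnivore"):
            transfers[(prey, dest)] = transfers.get((prey, dest), 0.0) + float(
                fx[f"predation_by_{consumer}_on_{prey}s"].sum()
            )
    for (src, dst), total_kg in transfers.items():
        stock = summary.biomass_density_kg_km2.get(src, 0.0)
        if stock > 0.0:
            summary.flux_percent_of_source[(src, dst)] = (
                100.0 * per_year * (total_kg / area_km2) / stock
            )
    autotroph_stock = summary.biomass_density_kg_km2.get("autotroph", 0.0)
    if autotroph_stock > 0.0:
        summary.npp_percent_of_autotroph = (
            100.0 * per_year * (fx["stock_growth"].sum() / area_km2) / autotroph_stock
        )
    return summary


def mass_abundance_spectrum(
    cohorts: list[Cohort],
    area_km2: float,
    edges_log10: np.ndarray | None = None,
    n_bins: int = 20,
    kind: str = "abundance",
) -> pd.DataFrame:
    """Least-squares slope of log density against log body mass per level.

    Abundance density is summed into logarithmic body-mass bins (20 bins
    spanning the community's mass range by default, or explicit
    ``edges_log10``); the slope of ``log10(density)`` vs ``log10(bin-centre
    mass)`` is fitted per trophic level.  ``kind='nbs'`` fits the
    normalised biomass spectrum instead (binned biomass density divided by
    linear bin width).  Levels occupying fewer than 3 bins are dropped; if
    no level remains the regression is undefined and a ``ValueError`` is
    raised.
    """
    if kind not in {"abundance", "nbs"}:
        raise ValueError("kind must be 'abundance' or 'nbs'")
    live = [c for c in cohorts if c.abundance > 0]
    if not live:
        raise ValueError("no live cohorts to bin")
    if edges_log10 is None:
        masses = np.log10([c.body_mass_kg for c in live])
        lo, hi = float(np.min(masses)), float(np.max(masses))
        hi = hi + 1e-9 if hi > lo else lo + 1.0
        edges_log10 = np.linspace(lo, hi, n_bins + 1)
    edges_log10 = np.asarray(edges_log10, dtype=float)
    n = len(edges_log10) - 1
    centres = 0.5 * (edges_log10[:-1] + edges_log10[1:])
    widths_linear = 10.0 ** edges_log10[1:] - 10.0 ** edges_log10[:-1]

    rows = []
    for tl in ("herbivore", "omnivore", "carnivore"):
        values = np.zeros(n)
        for c in live:
            if c.group.feeding_mode != tl:
                continue
            b = int(np.clip(
                np.searchsorted(edges_log10, math.log10(c.body_mass_kg), "right") - 1,
                0, n - 1,
            ))
            values[b] += (
                c.abundance if kind == "abundance"
                else c.abundance * c.individual_mass_kg
            )
        values = values / area_km2
        if kind == "nbs":
            values = values / widths_linear
        occupied = values > 0.0
        if int(np.sum(occupied)) < 3:
            continue
        slope, intercept = np.polyfit(centres[occupied], np.log10(values[occupied]), 1)
        rows.append({
            "trophic_level": tl, "kind": kind, "slope": float(slope),
            "intercept": float(intercept), "n_bins_occupied": int(np.sum(occupied)),
        })
    if not rows:
        raise ValueError(
            "undefined slope: fewer than 3 non-empty mass bins in every trophic level"
        )
    return pd.DataFrame(rows)


def life_history_summaries(
    life_history: pd.DataFrame,
    numerics: NumericsParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cohort life-history metrics and their body-mass scaling fits.

    From the engine's completed-lifetime log, computes realised growth rate
    (kg per year), time to maturity (years; only for cohorts that matured),
    lifespan (years), lifespan-inverse individual mortality rate (per year,
    bounded at 12 because the minimum simulated lifespan is one monthly
    step), and lifetime reproductive success (offspring per individual).
    Returns ``(records, fits)`` where ``fits`` holds the slope and
    intercept of log-log ordinary least squares against adult body mass.
    """
    if life_history.empty:
        raise ValueError("no completed lifetimes in the diagnostic window")
    steps_per_year = numerics.steps_per_year
    rec = life_history.copy()
    rec["lifespan_years"] = rec["lifespan_steps"] / steps_per_year
    rec["mortality_rate_per_year"] = np.minimum(
        1.0 / rec["lifespan_years"], MORTALITY_RATE_CAP_PER_YEAR
    )
    matured = rec["steps_to_maturity"].notna()
    rec["maturity_time_years"] = np.where(
        matured, rec["steps_to_maturity"] / steps_per_year, np.nan
    )
    growth_time = np.where(
        matured, rec["steps_to_maturity"], rec["lifespan_steps"]
    ).astype(float) / steps_per_year
    growth_gain = np.where(
        matured,
        rec["adult_mass_kg"] - rec["juvenile_mass_kg"],
        rec["max_mass_achieved_kg"] - rec["juvenile_mass_kg"],
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        rec["growth_rate_kg_per_year"] = np.where(
            growth_time > 0, growth_gain / np.maximum(growth_time, 1e-12), np.nan
        )
    rec["lifetime_reproductive_success"] = rec["offspring_per_capita"]

    fits = []
    for metric in (
        "growth_rate_kg_per_year", "maturity_time_years",
        "mortality_rate_per_year", "lifetime_reproductive_success",
    ):
        sub = rec[(rec[metric] > 0) & np.isfinite(rec[metric])]
        if len(sub) < 3:
            continue
        x = np.log10(sub["adult_mass_kg"].to_numpy())
        y = np.log10(sub[metric].to_numpy())
        if np.ptp(x) == 0.0:
            continue
        slope, intercept = np.polyfit(x, y, 1)
        fits.append({
            "metric": metric, "slope": float(slope),
            "intercept": float(intercept), "n": int(len(sub)),
        })
    return rec, pd.DataFrame(fits)
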