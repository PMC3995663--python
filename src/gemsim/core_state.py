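"""Domain types for the ecosystem state and seeding of initial communities.

The unit of heterotroph ecology is the :class:`Cohort`: a group of
identical-trait individuals characterised by a functional group, fixed
juvenile and adult body masses, and three dynamic state variables
(abundance ``N``, individual body mass ``M``, stored reproductive mass
``R``).  Autotrophs are :class:`Stock` biomass pools.  A :class:`GridCell`
holds the stocks and cohorts of one lat-lon cell together with its
environmental forcing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FunctionalGroup",
    "Cohort",
    "Stock",
    "GridCell",
    "cell_area_km2",
    "initialise_cell",
    "cell_snapshot",
    "restore_snapshot",
]

EARTH_RADIUS_KM = 6371.0

_REALMS = {"marine", "terrestrial"}
_FEEDING_MODES = {"herbivore", "omnivore", "carnivore"}
_MOBILITIES = {"planktonic", "mobile", "sessile"}
_REPRO = {"iteroparity", "semelparity"}
_THERMO = {"endotherm", "ectotherm"}


@dataclass(frozen=True)
class FunctionalGroup:
    """Bundle of categorical traits selecting process variants and parameters."""

    id: str
    realm: str
    feeding_mode: str
    mobility: str
    reproductive_strategy: str
    thermoregulation: str
    log10_min_mass_kg: float
    log10_max_mass_kg: float
    herbivory_assimilation: float
    carnivory_assimilation: float

    def __post_init__(self) -> None:
        if self.realm not in _REALMS:
            raise ValueError(f"unknown realm {self.realm!r}")
        if self.feeding_mode not in _FEEDING_MODES:
            raise ValueError(f"unknown feeding mode {self.feeding_mode!r}")
        if self.mobility not in _MOBILITIES:
            raise ValueError(f"unknown mobility {self.mobility!r}")
        if self.reproductive_strategy not in _REPRO:
            raise ValueError(f"unknown reproductive strategy {self.reproductive_strategy!r}")
        if self.thermoregulation not in _THERMO:
            raise ValueError(f"unknown thermoregulation {self.thermoregulation!r}")
        if not self.log10_min_mass_kg < self.log10_max_mass_kg:
            raise ValueError("log10_min_mass_kg must be < log10_max_mass_kg")
        for attr in ("herbivory_assimilation", "carnivory_assimilation"):
            v = getattr(self, attr)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{attr} must lie in [0, 1], got {v}")

    @property
    def min_mass_kg(self) -> float:
        return 10.0 ** self.log10_min_mass_kg

    @property
    def max_mass_kg(self) -> float:
        return 10.0 ** self.log10_max_mass_kg

    @property
    def trophic_level(self) -> str:
        """Feeding-mode trophic level used for community aggregation."""
        return self.feeding_mode


class Cohort:
    """A group of identical organisms; the atomic unit of heterotroph ecology.

    ``abundance`` only ever decreases through ecological processes within a
    cohort's lifetime; it increases only by the numerical merging of two
    cohorts.  ``body_mass_kg`` never exceeds ``max_mass_achieved_kg``.
    ``reproductive_pool_kg`` stays zero until maturity.
    """

    __slots__ = (
        "group",
        "juvenile_mass_kg",
        "adult_mass_kg",
        "abundance",
        "body_mass_kg",
        "reproductive_pool_kg",
        "max_mass_achieved_kg",
        "age_steps",
        "steps_to_maturity",
        "steps_since_maturity",
        "is_mature",
        "id",
        "parent_id",
        "birth_step",
        "offspring_per_capita",
        "last_mass_loss_fraction",
        "_bin",
        "_thin_seen",
    )

    def __init__(
        self,
        group: FunctionalGroup,
        juvenile_mass_kg: float,
        adult_mass_kg: float,
        abundance: float,
        body_mass_kg: float | None = None,
        reproductive_pool_kg: float = 0.0,
        id: int = -1,
        parent_id: int = -1,
        birth_step: int = 0,
    ) -> None:
        if juvenile_mass_kg > adult_mass_kg:
            raise ValueError("juvenile mass must not exceed adult mass")
        if abundance < 0:
            raise ValueError("abundance must be >= 0")
        body = juvenile_mass_kg if body_mass_kg is None else body_mass_kg
        if body <= 0:
            raise ValueError("body mass must be > 0")
        self.group = group
        self.juvenile_mass_kg = float(juvenile_mass_kg)
        self.adult_mass_kg = float(adult_mass_kg)
        self.abundance = float(abundance)
        self.body_mass_kg = float(body)
        self.reproductive_pool_kg = float(reproductive_pool_kg)
        self.max_mass_achieved_kg = float(body)
        self.age_steps = 0
        self.steps_to_maturity: int | None = None
        self.steps_since_maturity = 0
        self.is_mature = body >= adult_mass_kg
        if self.is_mature:
            self.steps_to_maturity = 0
        self.id = id
        self.parent_id = parent_id
        self.birth_step = birth_step
        self.offspring_per_capita = 0.0
        self.last_mass_loss_fraction = 0.0  # set each step; read by dispersal
        self._bin = -1  # prey mass-bin index, maintained by the engine
        self._thin_seen = 1.0  # last-seen predation survival product

    @property
    def individual_mass_kg(self) -> float:
        """Total mass of one individual including its reproductive pool."""
        return self.body_mass_kg + self.reproductive_pool_kg

    @property
    def total_biomass_kg(self) -> float:
        return self.abundance * self.individual_mass_kg

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"Cohort({self.group.id}, N={self.abundance:.3g}, "
            f"M={self.body_mass_kg:.3g} kg, R={self.reproductive_pool_kg:.3g} kg)"
        )


@dataclass
class Stock:
    """An autotroph biomass pool (phytoplankton or one leaf strategy)."""

    functional_group: str
    total_biomass_kg: float = 0.0
    leaf_strategy: str = "n/a"  # deciduous | evergreen | n/a

    def __post_init__(self) -> None:
        if self.total_biomass_kg < 0:
            raise ValueError("stock biomass must be >= 0")
        if self.leaf_strategy not in {"deciduous", "evergreen", "n/a"}:
            raise ValueError(f"unknown leaf strategy {self.leaf_strategy!r}")


def cell_area_km2(lat_deg: float, resolution_deg: float = 1.0) -> float:
    """Spherical area of a grid cell centred at ``lat_deg``.

    The cell spans ``resolution_deg`` in both axes with half-open
    ``[lower, upper)`` edges; area follows from the spherical zone between
    the bounding latitudes.
    """
    half = resolution_deg / 2.0
    lat_lo = math.radians(lat_deg - half)
    lat_hi = math.radians(lat_deg + half)
    dlon = math.radians(resolution_deg)
    area = EARTH_RADIUS_KM**2 * dlon * (math.sin(lat_hi) - math.sin(lat_lo))
    if area <= 0:
        raise ValueError(f"non-positive cell area at latitude {lat_deg}")
    return area


@dataclass
class GridCell:
    """Spatial container: area, realm, forcing, resident stocks and cohorts."""

    lat_deg: float
    lon_deg: float
    realm: str
    resolution_deg: float = 1.0
    area_km2: float = 0.0
    stocks: list[Stock] = field(default_factory=list)
    cohorts: list[Cohort] = field(default_factory=list)
    forcing: object | None = None  # ForcingSeries; typed loosely to avoid cycle
    active: bool = True
    next_cohort_id: int = 0  # monotone id counter for lineage tracking

    def __post_init__(self) -> None:
        if self.realm not in _REALMS:
            raise ValueError(f"unknown realm {self.realm!r}")
        if self.area_km2 <= 0.0:
            self.area_km2 = cell_area_km2(self.lat_deg, self.resolution_deg)

    @property
    def width_km(self) -> float:
        """Approximate cell width used by dispersal (geometric mean of spans)."""
        dy = EARTH_RADIUS_KM * math.radians(self.resolution_deg)
        dx = dy * max(math.cos(math.radians(self.lat_deg)), 1e-6)
        return math.sqrt(dx * dy)

    def total_heterotroph_biomass_kg(self) -> float:
        return sum(c.total_biomass_kg for c in self.cohorts)

    def total_stock_biomass_kg(self) -> float:
        return sum(s.total_biomass_kg for s in self.stocks)


def _make_stocks(realm: str) -> list[Stock]:
    if realm == "terrestrial":
        return [
            Stock("terrestrial_deciduous", 0.0, "deciduous"),
            Stock("terrestrial_evergreen", 0.0, "evergreen"),
        ]
    return [Stock("marine_phytoplankton", 0.0, "n/a")]


def initialise_cell(
    cell: GridCell,
    groups: Sequence[FunctionalGroup],
    n_cohorts_per_group: int,
    rng_seed: int,
    *,
    seed_biomass_density_kg_km2: float = 5.0e4,
    abundance_mass_exponent: float = -1.0,
    autotroph_params=None,
    trophic_fractions: dict[str, float] | None = None,
) -> GridCell:
    """Seed a cell with autotroph stocks and an initial cohort community.

    Each cohort's adult mass is drawn log-uniformly within its functional
    group's mass range and its juvenile mass log-uniformly between the group
    minimum and the adult mass; cohorts start at juvenile body mass.
    Initial abundance is a decreasing power function of adult mass
    (exponent ``abundance_mass_exponent``), normalised so the initial total
    heterotroph biomass density matches ``seed_biomass_density_kg_km2``,
    split across feeding modes by ``trophic_fractions`` (default 80%
    herbivore / 15% omnivore / 5% carnivore: a bottom-heavy community the
    young ecosystem's prey flux can carry).  Deterministic for a given
    ``rng_seed``.
    """
    if n_cohorts_per_group <= 0:
        raise ValueError("n_cohorts_per_group must be positive")
    groups = list(groups)
    for g in groups:
        if g.realm != cell.realm:
            raise ValueError(
                f"functional group {g.id!r} realm {g.realm!r} does not match "
                f"cell realm {cell.realm!r}"
            )
    if not groups:
        raise ValueError("no functional groups supplied for seeding")

    rng = np.random.default_rng(rng_seed)
    cell.stocks = _make_stocks(cell.realm)
    if cell.forcing is not None and autotroph_params is not None:
        _seed_stocks(cell, autotroph_params)
    cohorts: list[Cohort] = []
    next_id = 0
    for g in groups:
        lo, hi = g.log10_min_mass_kg, g.log10_max_mass_kg
        log_adult = rng.uniform(lo, hi, size=n_cohorts_per_group)
        log_juv = rng.uniform(lo, log_adult)
        for la, lj in zip(log_adult, log_juv):
            adult = 10.0**la
            juv = 10.0**lj
            cohorts.append(
                Cohort(g, juv, adult, abundance=adult**abundance_mass_exponent,
                       id=next_id)
            )
            next_id += 1
    # normalise the provisional power-law abundances to the target density,
    # one feeding mode at a time
    if trophic_fractions is None:
        trophic_fractions = {"herbivore": 0.80, "omnivore": 0.15, "carnivore": 0.05}
    target = seed_biomass_density_kg_km2 * cell.area_km2
    modes_present = {g.feeding_mode for g in groups}
    weight_total = sum(trophic_fractions[m] for m in modes_present)
    for mode in modes_present:
        members = [c for c in cohorts if c.group.feeding_mode == mode]
        provisional = sum(c.total_biomass_kg for c in members)
        scale = target * (trophic_fractions[mode] / weight_total) / provisional
        for c in members:
            c.abundance *= scale
    cell.cohorts = cohorts
    cell.next_cohort_id = next_id
    return cell


def _seed_stocks(cell: GridCell, autotroph_params) -> None:
    """Start stocks near their grazing-free balance so the seeded community
    does not face an empty larder in the first months."""
    # imported here: autotrophs depends on core_state for the Stock type
    from .autotrophs import evergreen_fraction, npp_to_wet_matter_kg, structural_fraction

    forcing = cell.forcing
    p = autotroph_params
    if cell.realm == "marine":
        monthly = npp_to_wet_matter_kg(
            float(np.mean(forcing.npp_gC_m2_month)), cell.area_km2,
            p.carbon_to_wet_marine, 1.0,
        )
        cell.stocks[0].total_biomass_kg = 2.0 * monthly
        return
    annual_edible = npp_to_wet_matter_kg(
        float(np.sum(forcing.npp_gC_m2_month)), cell.area_km2,
        p.carbon_to_wet_terrestrial, 1.0,
    ) * (1.0 - structural_fraction(forcing, p))
    f_ever = evergreen_fraction(forcing, p)
    for s in cell.stocks:
        if s.leaf_strategy == "evergreen":
            mu = max(p.mu_evergreen_per_year * p.leaf_fraction_of_mortality, 0.25)
            s.total_biomass_kg = annual_edible * f_ever / mu
        else:
            mu = max(p.mu_deciduous_per_year * p.leaf_fraction_of_mortality, 0.25)
            s.total_biomass_kg = annual_edible * (1.0 - f_ever) / mu


_SNAPSHOT_COLUMNS = [
    "kind", "functional_group", "juvenile_mass_kg", "adult_mass_kg",
    "abundance", "body_mass_kg", "reproductive_pool_kg", "max_mass_achieved_kg",
    "age_steps", "steps_to_maturity", "steps_since_maturity", "is_mature",
    "id", "parent_id", "birth_step", "offspring_per_capita", "leaf_strategy",
]


def cell_snapshot(cell: GridCell) -> pd.DataFrame:
    """Tabular snapshot of a cell's state (one row per cohort or stock)."""
    rows = []
    for s in cell.stocks:
        rows.append({
            "kind": "stock", "functional_group": s.functional_group,
            "abundance": np.nan, "body_mass_kg": s.total_biomass_kg,
            "leaf_strategy": s.leaf_strategy,
        })
    for c in cell.cohorts:
        rows.append({
            "kind": "cohort", "functional_group": c.group.id,
            "juvenile_mass_kg": c.juvenile_mass_kg,
            "adult_mass_kg": c.adult_mass_kg,
            "abundance": c.abundance, "body_mass_kg": c.body_mass_kg,
            "reproductive_pool_kg": c.reproductive_pool_kg,
            "max_mass_achieved_kg": c.max_mass_achieved_kg,
            "age_steps": c.age_steps,
            "steps_to_maturity": (
                np.nan if c.steps_to_maturity is None else c.steps_to_maturity
            ),
            "steps_since_maturity": c.steps_since_maturity,
            "is_mature": c.is_mature, "id": c.id, "parent_id": c.parent_id,
            "birth_step": c.birth_step,
            "offspring_per_capita": c.offspring_per_capita,
            "leaf_strategy": "n/a",
        })
    return pd.DataFrame(rows, columns=_SNAPSHOT_COLUMNS)


def restore_snapshot(
    cell: GridCell, snapshot: pd.DataFrame, groups: Iterable[FunctionalGroup]
) -> GridCell:
    """Rebuild a cell's stocks and cohorts from a :func:`cell_snapshot` table."""
    by_id = {g.id: g for g in groups}
    stocks: list[Stock] = []
    cohorts: list[Cohort] = []
    for _, row in snapshot.iterrows():
        if row["kind"] == "stock":
            stocks.append(Stock(row["functional_group"], float(row["body_mass_kg"]),
                                row["leaf_strategy"]))
            continue
        c = Cohort(
            by_id[row["functional_group"]],
            float(row["juvenile_mass_kg"]),
            float(row["adult_mass_kg"]),
            float(row["abundance"]),
            body_mass_kg=float(row["body_mass_kg"]),
            reproductive_pool_kg=float(row["reproductive_pool_kg"]),
            id=int(row["id"]), parent_id=int(row["parent_id"]),
            birth_step=int(row["birth_step"]),
        )
        c.max_mass_achieved_kg = float(row["max_mass_achieved_kg"])
        c.age_steps = int(row["age_steps"])
        c.steps_to_maturity = (
            None if pd.isna(row["steps_to_maturity"]) else int(row["steps_to_maturity"])
        )
        c.steps_since_maturity = int(row["steps_since_maturity"])
        c.is_mature = bool(row["is_mature"])
        c.offspring_per_capita = float(row["offspring_per_capita"])
        cohorts.append(c)
    cell.stocks = stocks
    cell.cohorts = cohorts
    return cell
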