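"""Movement of whole cohorts between grid cells.

Three mechanisms: diffusive natal dispersal of newly spawned cohorts, with
a characteristic distance that is a power law of body mass; responsive
dispersal of adults triggered by low intracohort density or by starvation;
and advective-diffusive dispersal of planktonic marine organisms driven by
ocean currents.  Cohorts move in their entirety — dispersal conserves
global cohort count, abundance and biomass exactly.  In a single-cell
simulation dispersal is disabled.
"""

from __future__ import annotations

import math

import numpy as np

from .core_state import Cohort, GridCell
from .params import DispersalParams

__all__ = [
    "NEIGHBOUR_OFFSETS",
    "is_planktonic",
    "natal_dispersal",
    "responsive_dispersal",
    "advective_dispersal",
]

#: 8-neighbour stencil as (d_lat_index, d_lon_index) offsets
NEIGHBOUR_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)

_SECONDS_PER_DAY = 86400.0


def is_planktonic(cohort: Cohort, params: DispersalParams) -> bool:
    """Planktonic-size organisms disperse by advection, not diffusion."""
    return (
        cohort.group.mobility == "planktonic"
        or cohort.body_mass_kg < params.planktonic_mass_threshold_kg
    )


def _random_direction(rng: np.random.Generator) -> tuple[int, int]:
    return NEIGHBOUR_OFFSETS[int(rng.integers(len(NEIGHBOUR_OFFSETS)))]


def _diffusive_move(
    distance_km: float, cell_width_km: float, rng: np.random.Generator
) -> tuple[int, int] | None:
    """Leave with probability min(1, distance / cell width), uniform direction."""
    p_leave = min(1.0, distance_km / cell_width_km)
    if rng.random() < p_leave:
        return _random_direction(rng)
    return None


def characteristic_distance_km(cohort: Cohort, params: DispersalParams) -> float:
    """Characteristic dispersal distance per step as a power law of body mass."""
    return params.reference_speed_km * (
        cohort.body_mass_kg / params.reference_mass_kg
    ) ** params.mass_exponent


def natal_dispersal(
    cohort: Cohort,
    cell: GridCell,
    params: DispersalParams,
    rng: np.random.Generator,
) -> tuple[int, int] | None:
    """Random diffusive dispersal of a newly spawned cohort.

    Returns a neighbour offset, or ``None`` to stay.  Planktonic-size
    organisms are excluded (they disperse advectively).
    """
    if cohort.age_steps != 0:
        raise ValueError("natal dispersal applies to newborn cohorts only")
    if is_planktonic(cohort, params):
        return None
    return _diffusive_move(
        characteristic_distance_km(cohort, params), cell.width_km, rng
    )


def responsive_dispersal(
    cohort: Cohort,
    cell: GridCell,
    mass_loss_fraction: float,
    params: DispersalParams,
    rng: np.random.Generator,
) -> tuple[int, int] | None:
    """Active dispersal of a mature cohort.

    A move is attempted iff the intracohort adult density is strictly below
    the mass-related threshold, or the fraction of body mass lost this step
    strictly exceeds the starvation threshold; otherwise the cohort stays.
    """
    if not cohort.is_mature:
        return None
    density = cohort.abundance / cell.area_km2
    threshold = params.density_threshold_const * (
        cohort.body_mass_kg**params.density_threshold_exponent
    )
    triggered = density < threshold or mass_loss_fraction > params.starvation_mass_loss_threshold
    if not triggered:
        return None
    return _diffusive_move(
        characteristic_distance_km(cohort, params), cell.width_km, rng
    )


def advective_dispersal(
    cohort: Cohort,
    cell: GridCell,
    u_ms: float,
    v_ms: float,
    params: DispersalParams,
    rng: np.random.Generator,
    dt_days: float,
) -> tuple[int, int] | None:
    """Advective-diffusive dispersal of planktonic marine cohorts.

    Displacement is the current vector integrated over the step plus an
    isotropic Gaussian diffusive kick; crossing a cell boundary moves the
    whole cohort to the entered cell.  The expected move (in cells) equals
    the advective displacement divided by the cell width: fractional
    displacements are resolved by stochastic rounding.
    """
    if cell.realm != "marine":
        raise ValueError("advective dispersal applies in the marine realm only")
    km = _SECONDS_PER_DAY * dt_days / 1000.0
    dx = u_ms * km
    dy = v_ms * km
    if params.advective_diffusion_km > 0.0:
        dx += params.advective_diffusion_km * rng.standard_normal()
        dy += params.advective_diffusion_km * rng.standard_normal()
    w = cell.width_km
    dj = int(math.floor(dx / w + rng.random()))  # lon: east positive
    di = int(math.floor(dy / w + rng.random()))  # lat: north positive
    if di == 0 and dj == 0:
        return None
    return di, dj
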