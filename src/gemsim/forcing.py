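"""Monthly environmental forcing per grid cell.

Forcing is a repeating 12-month climatology (interannual variability is out
of scope): air or sea-surface temperature, NPP, and — per realm —
precipitation, soil-water availability and frost days (terrestrial) or
current velocities (marine).  Synthetic climatologies are sinusoidal cycles
about a stated mean; four named archetypes emulate a tropical aseasonal and
a temperate seasonal terrestrial cell, and a low-productivity aseasonal and
a high-productivity seasonal marine cell.  Real gridded products can be
read from NetCDF-style files instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import xarray as xr

from .core_state import GridCell

__all__ = [
    "ForcingSeries",
    "SyntheticForcingSpec",
    "generate_synthetic_forcing",
    "archetype_spec",
    "ARCHETYPES",
    "write_gridded_forcing",
    "load_gridded_forcing",
]

N_MONTHS = 12


@dataclass
class ForcingSeries:
    """Length-12 monthly climatology arrays for one grid cell."""

    temperature_C: np.ndarray
    npp_gC_m2_month: np.ndarray
    precipitation_mm: np.ndarray | None = None
    soil_water_availability: np.ndarray | None = None
    frost_days: np.ndarray | None = None
    current_u_ms: np.ndarray | None = None
    current_v_ms: np.ndarray | None = None

    def __post_init__(self) -> None:
        for f in fields(self):
            arr = getattr(self, f.name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (N_MONTHS,):
                raise ValueError(f"{f.name} must have shape (12,), got {arr.shape}")
            setattr(self, f.name, arr)
        if np.any(self.npp_gC_m2_month < 0):
            raise ValueError("NPP must be >= 0 in every month")
        if self.frost_days is not None and (
            np.any(self.frost_days < 0) or np.any(self.frost_days > 31)
        ):
            raise ValueError("frost_days must lie in [0, 31]")

    # climate statistics used by the thermal-activity estimation
    @property
    def annual_mean_temperature_C(self) -> float:
        return float(np.mean(self.temperature_C))

    @property
    def seasonal_temperature_range_C(self) -> float:
        """Half peak-to-trough range of the monthly temperature cycle."""
        t = self.temperature_C
        return float(np.max(t) - np.min(t)) / 2.0


@dataclass
class SyntheticForcingSpec:
    """Specification of a sinusoidal synthetic climatology.

    Seasonal cycles are ``mean * (1 + amp * cos(2*pi*(m - phase)/12))`` for
    quantities with fractional amplitudes (NPP, precipitation) and
    ``mean + amp * cos(...)`` for temperature; the 12-month mean equals the
    stated mean exactly.  ``phase_month`` is the month of the maximum.
    """

    realm: str
    annual_mean_npp_gC_m2_month: float
    npp_seasonal_amplitude: float = 0.0  # fraction of the mean, in [0, 1]
    mean_temperature_C: float = 20.0
    temperature_seasonal_amplitude_C: float = 0.0
    phase_month: int = 6
    mean_precipitation_mm: float = 80.0
    precipitation_seasonal_amplitude: float = 0.0
    soil_water_availability: float = 0.5
    current_speed_ms: float = 0.05  # zonal current magnitude (marine)

    def __post_init__(self) -> None:
        if self.realm not in {"marine", "terrestrial"}:
            raise ValueError(f"unknown realm {self.realm!r}")
        if self.annual_mean_npp_gC_m2_month < 0:
            raise ValueError("annual mean NPP must be >= 0")
        if not (0.0 <= self.npp_seasonal_amplitude <= 1.0):
            raise ValueError("npp_seasonal_amplitude must lie in [0, 1]")
        if self.temperature_seasonal_amplitude_C < 0:
            raise ValueError("temperature amplitude must be >= 0")
        if not (0.0 <= self.precipitation_seasonal_amplitude <= 1.0):
            raise ValueError("precipitation_seasonal_amplitude must lie in [0, 1]")


def _cycle(months: np.ndarray, phase: int) -> np.ndarray:
    return np.cos(2.0 * math.pi * (months - phase) / N_MONTHS)


def generate_synthetic_forcing(spec: SyntheticForcingSpec) -> ForcingSeries:
    """Build a 12-month :class:`ForcingSeries` from a synthetic spec."""
    m = np.arange(N_MONTHS, dtype=float)
    c = _cycle(m, spec.phase_month)
    temp = spec.mean_temperature_C + spec.temperature_seasonal_amplitude_C * c
    npp = spec.annual_mean_npp_gC_m2_month * (1.0 + spec.npp_seasonal_amplitude * c)

    if spec.realm == "terrestrial":
        precip = spec.mean_precipitation_mm * (
            1.0 + spec.precipitation_seasonal_amplitude * c
        )
        # frost days follow the temperature cycle through a logistic response
        frost = 31.0 / (1.0 + np.exp(temp / 3.0))
        return ForcingSeries(
            temperature_C=temp,
            npp_gC_m2_month=npp,
            precipitation_mm=precip,
            soil_water_availability=np.full(N_MONTHS, spec.soil_water_availability),
            frost_days=frost,
        )
    return ForcingSeries(
        temperature_C=temp,
        npp_gC_m2_month=npp,
        current_u_ms=np.full(N_MONTHS, spec.current_speed_ms),
        current_v_ms=np.zeros(N_MONTHS),
    )


#: The four focal-cell archetypes used throughout testing: mean NPP and
#: temperature chosen as field-typical values for a wet-tropical forest cell,
#: a temperate mixed-cover cell, an oligotrophic subtropical-gyre cell, and a
#: productive mid-latitude shelf/bloom cell.
ARCHETYPES: dict[str, SyntheticForcingSpec] = {
    "terrestrial_tropical_aseasonal": SyntheticForcingSpec(
        realm="terrestrial",
        annual_mean_npp_gC_m2_month=80.0,
        npp_seasonal_amplitude=0.0,
        mean_temperature_C=25.0,
        temperature_seasonal_amplitude_C=0.0,
        mean_precipitation_mm=150.0,
        soil_water_availability=0.8,
    ),
    "terrestrial_temperate_seasonal": SyntheticForcingSpec(
        realm="terrestrial",
        annual_mean_npp_gC_m2_month=45.0,
        npp_seasonal_amplitude=0.8,
        mean_temperature_C=10.0,
        temperature_seasonal_amplitude_C=8.0,
        mean_precipitation_mm=60.0,
        precipitation_seasonal_amplitude=0.2,
        soil_water_availability=0.6,
    ),
    "marine_low_productivity_aseasonal": SyntheticForcingSpec(
        realm="marine",
        annual_mean_npp_gC_m2_month=15.0,
        npp_seasonal_amplitude=0.0,
        mean_temperature_C=22.0,
        temperature_seasonal_amplitude_C=0.0,
        current_speed_ms=0.05,
    ),
    "marine_high_productivity_seasonal": SyntheticForcingSpec(
        realm="marine",
        annual_mean_npp_gC_m2_month=60.0,
        npp_seasonal_amplitude=0.8,
        mean_temperature_C=12.0,
        temperature_seasonal_amplitude_C=6.0,
        current_speed_ms=0.15,
    ),
}


def archetype_spec(name: str) -> SyntheticForcingSpec:
    try:
        return ARCHETYPES[name]
    except KeyError:
        raise KeyError(
            f"unknown forcing archetype {name!r}; available: {sorted(ARCHETYPES)}"
        ) from None


# ---------------------------------------------------------------------------
# gridded file interface

_VARIABLES = {
    "temperature_C": "temperature",
    "npp_gC_m2_month": "npp",
    "precipitation_mm": "precipitation",
    "soil_water_availability": "soil_water",
    "frost_days": "frost_days",
    "current_u_ms": "u_current",
    "current_v_ms": "v_current",
}


def write_gridded_forcing(
    path: str | Path,
    lats: Sequence[float],
    lons: Sequence[float],
    series: dict[tuple[float, float], ForcingSeries],
) -> None:
    """Write per-cell climatologies to a self-describing gridded file.

    Cells absent from ``series`` are stored as NaN (inactive).  The writer
    and :func:`load_gridded_forcing` are mutual inverses at stored (float64)
    precision.
    """
    lats = np.asarray(sorted(set(float(x) for x in lats)))
    lons = np.asarray(sorted(set(float(x) for x in lons)))
    data = {}
    for attr, var in _VARIABLES.items():
        arr = np.full((N_MONTHS, len(lats), len(lons)), np.nan)
        present = False
        for (la, lo), fs in series.items():
            values = getattr(fs, attr)
            if values is None:
                continue
            present = True
            i = int(np.argmin(np.abs(lats - la)))
            j = int(np.argmin(np.abs(lons - lo)))
            arr[:, i, j] = values
        if present:
            data[var] = (("month", "lat", "lon"), arr)
    ds = xr.Dataset(
        data,
        coords={"month": np.arange(N_MONTHS), "lat": lats, "lon": lons},
    )
    ds.to_netcdf(path, engine="scipy")


def load_gridded_forcing(
    paths: Sequence[str | Path] | str | Path, cells: Sequence[GridCell]
) -> dict[int, ForcingSeries | None]:
    """Nearest-cell extraction of monthly climatologies for each grid cell.

    Returns a mapping from the index of each cell in ``cells`` to its
    :class:`ForcingSeries`, or ``None`` where all variables are missing, in
    which case the cell is flagged inactive.  Variables may be split across
    several files; month, lat and lon coordinates are required in each.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    datasets = [xr.open_dataset(p, engine="scipy") for p in paths]
    merged = xr.merge(datasets)
    for dim in ("month", "lat", "lon"):
        if dim not in merged.coords:
            raise ValueError(f"forcing file(s) lack required coordinate {dim!r}")
    if "temperature" not in merged or "npp" not in merged:
        missing = {"temperature", "npp"} - set(merged.data_vars)
        raise ValueError(f"forcing file(s) missing required variable(s): {sorted(missing)}")

    out: dict[int, ForcingSeries | None] = {}
    for idx, cell in enumerate(cells):
        point = merged.sel(lat=cell.lat_deg, lon=cell.lon_deg, method="nearest")
        kwargs = {}
        for attr, var in _VARIABLES.items():
            if var in point:
                values = np.asarray(point[var].values, dtype=float)
                kwargs[attr] = None if np.all(np.isnan(values)) else values
        temp = kwargs.get("temperature_C")
        npp = kwargs.get("npp_gC_m2_month")
        if temp is None or npp is None or np.any(np.isnan(temp)) or np.any(np.isnan(npp)):
            cell.active = False
            out[idx] = None
            continue
        out[idx] = ForcingSeries(**kwargs)
        cell.forcing = out[idx]
    for ds in datasets:
        ds.close()
    return out
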