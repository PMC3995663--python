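"""Configuration loading and validation, output writing, and run manifests.

A run is described by a single human-readable YAML document with four
sections: ``simulation`` (years, seed, ensemble, detail, grid extent),
``forcing`` (a named synthetic archetype, an explicit synthetic spec, or
gridded files), ``parameters`` (overrides of the packaged defaults, by
process), and ``functional_groups`` (optional path to an alternative group
table).  Unknown keys anywhere are rejected with a field-level message.
The packaged default group table defines exactly 19 cohort groups and 3
stock groups.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .core_state import FunctionalGroup
from .engine import CellSimulation, SimulationConfig
from .forcing import SyntheticForcingSpec, archetype_spec
from .params import ModelParameters, ParameterError

__all__ = [
    "load_functional_groups",
    "default_functional_groups",
    "load_config",
    "RunConfig",
    "RunManifest",
    "write_outputs",
    "read_outputs",
]


class ConfigError(ValueError):
    """Raised on schema violations in a run configuration."""


# ---------------------------------------------------------------------------
# functional-group tables

_COHORT_COLUMNS = {
    "Realm": "realm",
    "Feeding Mode": "feeding_mode",
    "Mobility": "mobility",
    "Reproductive Strategy": "reproductive_strategy",
    "Thermoregulation Mode": "thermoregulation",
    "Log10 Minimum Mass for Functional Group (kg)": "log10_min_mass_kg",
    "Log10 Maximum Mass for Functional Group (kg)": "log10_max_mass_kg",
    "Herbivory Proportional Assimilation Efficiency": "herbivory_assimilation",
    "Carnivory Proportional Assimilation Efficiency": "carnivory_assimilation",
}
_STOCK_COLUMNS = {"Realm", "Nutrition Source", "Mobility", "Leaf Strategy"}


@dataclass(frozen=True)
class StockGroup:
    """A stock functional-group row (autotroph pools)."""

    realm: str
    nutrition_source: str
    mobility: str
    leaf_strategy: str

    @property
    def id(self) -> str:
        if self.realm == "marine":
            return "marine_phytoplankton"
        return f"terrestrial_{self.leaf_strategy}"


def _cohort_group_from_row(row: dict) -> FunctionalGroup:
    unknown = set(row) - set(_COHORT_COLUMNS)
    if unknown:
        raise ConfigError(f"cohort functional group: unknown column(s) {sorted(unknown)}")
    missing = set(_COHORT_COLUMNS) - set(row)
    if missing:
        raise ConfigError(f"cohort functional group: missing column(s) {sorted(missing)}")
    kwargs = {}
    for col, attr in _COHORT_COLUMNS.items():
        v = row[col]
        kwargs[attr] = v.strip().lower() if isinstance(v, str) else float(v)
    gid = "_".join([
        kwargs["realm"], kwargs["feeding_mode"], kwargs["mobility"],
        kwargs["reproductive_strategy"], kwargs["thermoregulation"],
    ])
    try:
        return FunctionalGroup(id=gid, **kwargs)
    except ValueError as exc:
        raise ConfigError(f"cohort functional group {gid!r}: {exc}") from exc


def load_functional_groups(
    path: str | Path | None = None,
) -> tuple[list[FunctionalGroup], list[StockGroup]]:
    """Load (cohort groups, stock groups) from a YAML table document."""
    if path is None:
        source = resources.files("gemsim.data") / "functional_groups.yaml"
        text = source.read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    unknown = set(doc) - {"cohort_functional_groups", "stock_functional_groups"}
    if unknown:
        raise ConfigError(f"functional-group file: unknown section(s) {sorted(unknown)}")
    cohort_groups = [_cohort_group_from_row(r) for r in doc["cohort_functional_groups"]]
    if len({g.id for g in cohort_groups}) != len(cohort_groups):
        raise ConfigError("duplicate cohort functional-group definitions")
    stock_groups = []
    for row in doc["stock_functional_groups"]:
        unknown = set(row) - _STOCK_COLUMNS
        if unknown:
            raise ConfigError(f"stock functional group: unknown column(s) {sorted(unknown)}")
        stock_groups.append(StockGroup(
            realm=row["Realm"].strip().lower(),
            nutrition_source=row["Nutrition Source"].strip().lower(),
            mobility=row["Mobility"].strip().lower(),
            leaf_strategy=row["Leaf Strategy"].strip().lower(),
        ))
    return cohort_groups, stock_groups


def default_functional_groups() -> list[FunctionalGroup]:
    """The packaged default cohort functional groups (19 groups)."""
    return load_functional_groups()[0]


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Fully validated run configuration."""

    simulation: SimulationConfig
    forcing: SyntheticForcingSpec | list[str]  # synthetic spec or file paths
    parameters: ModelParameters
    groups: list[FunctionalGroup]
    raw: dict

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _simulation_config_from_dict(data: dict) -> SimulationConfig:
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"simulation: unknown key(s) {sorted(unknown)}")
    try:
        return SimulationConfig(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"simulation: {exc}") from exc


def _forcing_from_dict(data: dict) -> SyntheticForcingSpec | list[str]:
    unknown = set(data) - {"archetype", "synthetic", "files"}
    if unknown:
        raise ConfigError(f"forcing: unknown key(s) {sorted(unknown)}")
    given = [k for k in ("archetype", "synthetic", "files") if k in data]
    if len(given) != 1:
        raise ConfigError("forcing: give exactly one of archetype | synthetic | files")
    if "archetype" in data:
        try:
            return archetype_spec(data["archetype"])
        except KeyError as exc:
            raise ConfigError(str(exc)) from exc
    if "synthetic" in data:
        spec = data["synthetic"]
        known = {f.name for f in dataclasses.fields(SyntheticForcingSpec)}
        unknown = set(spec) - known
        if unknown:
            raise ConfigError(f"forcing.synthetic: unknown key(s) {sorted(unknown)}")
        try:
            return SyntheticForcingSpec(**spec)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"forcing.synthetic: {exc}") from exc
    return [str(p) for p in data["files"]]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a run configuration document."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ConfigError("configuration must be a mapping")
    unknown = set(doc) - {"simulation", "forcing", "parameters", "functional_groups"}
    if unknown:
        raise ConfigError(f"unknown configuration section(s): {sorted(unknown)}")
    if "forcing" not in doc:
        raise ConfigError("missing required section 'forcing'")
    sim = _simulation_config_from_dict(doc.get("simulation", {}))
    forcing = _forcing_from_dict(doc["forcing"])
    try:
        parameters = ModelParameters.from_dict(doc.get("parameters", {}))
    except ParameterError as exc:
        raise ConfigError(f"parameters: {exc}") from exc
    groups = load_functional_groups(doc.get("functional_groups"))[0]
    return RunConfig(sim, forcing, parameters, groups, raw=doc)


# ---------------------------------------------------------------------------
# outputs and manifest


@dataclass
class RunManifest:
    """Provenance record written alongside every run's outputs."""

    config_hash: str
    seeds: list[int]
    code_version: str
    started_at: float
    finished_at: float | None = None
    max_abs_residual: float | None = None

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def write_outputs(
    sims: dict[int, CellSimulation] | CellSimulation,
    out_dir: str | Path,
    detail: str = "summary",
    config_hash: str = "",
) -> list[Path]:
    """Write run outputs: CSV tables plus a gridded NetCDF summary.

    ``detail='summary'`` writes per-step biomass/abundance densities by
    functional group and the flux ledger; ``detail='detailed'`` adds the
    per-cohort life-history table.  Outputs are bit-stable across reruns
    with identical seeds.
    """
    if isinstance(sims, CellSimulation):
        sims = {0: sims}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__

    started = time.time()
    manifest = RunManifest(
        config_hash=config_hash,
        seeds=[s.seed for s in sims.values()],
        code_version=__version__,
        started_at=started,
    )
    manifest.write(out / "manifest.json")

    written: list[Path] = [out / "manifest.json"]
    histories = []
    fluxes = []
    max_resid = 0.0
    for member, sim in sims.items():
        h = sim.history().assign(member=member)
        f = sim.fluxes().assign(member=member)
        histories.append(h)
        fluxes.append(f)
        if len(f):
            max_resid = max(max_resid, float(f["residual_relative"].abs().max()))
        if detail == "detailed":
            lh = sim.life_history_table()
            p = out / f"life_history_member{member}.csv"
            lh.to_csv(p, index=False)
            written.append(p)
    history = pd.concat(histories, ignore_index=True)
    flux = pd.concat(fluxes, ignore_index=True)
    history.to_csv(out / "history.csv", index=False)
    flux.to_csv(out / "fluxes.csv", index=False)
    written += [out / "history.csv", out / "fluxes.csv"]

    # gridded self-describing summary: biomass density by (member, step, group)
    pivot = history.pivot_table(
        index=["member", "step"], columns="functional_group",
        values="biomass_density_kg_km2", aggfunc="sum",
    )
    ds = xr.Dataset(
        {
            "biomass_density_kg_km2": (
                ("record", "functional_group"),
                pivot.to_numpy(),
            )
        },
        coords={
            "member": ("record", pivot.index.get_level_values(0).to_numpy()),
            "step": ("record", pivot.index.get_level_values(1).to_numpy()),
            "functional_group": np.asarray(pivot.columns, dtype="S64"),
        },
    )
    ds.to_netcdf(out / "biomass_density.nc", engine="scipy")
    written.append(out / "biomass_density.nc")

    manifest.finished_at = time.time()
    manifest.max_abs_residual = max_resid
    manifest.write(out / "manifest.json")
    return written


def read_outputs(out_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Read back the tabular outputs of :func:`write_outputs`."""
    out = Path(out_dir)
    result = {
        "history": pd.read_csv(out / "history.csv"),
        "fluxes": pd.read_csv(out / "fluxes.csv"),
    }
    for p in sorted(out.glob("life_history_member*.csv")):
        result[p.stem] = pd.read_csv(p)
    return result
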