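"""Simulation engine: the per-step update loop, cohort bookkeeping, grids.

Each time step and cell proceeds in a fixed order: (1) autotroph growth and
leaf mortality; (2) each heterotroph cohort, in an order freshly randomised
every step, metabolises, eats, grows or stores reproductive mass, spawns,
and suffers non-predation mortality (predation losses accrue to the binned
prey pool as predators act and are realised on cohorts at the end of the
loop); (3) offspring cohorts are inserted (they first act next step);
(4) extinct cohorts are removed; (5) if the cohort count exceeds the
configured threshold, nearest-in-trait-space pairs of the same functional
group are merged, conserving biomass exactly.  Every biomass flux is
recorded in a per-step mass-balance ledger whose residual is checked each
step.
"""

from __future__ import annotations

import math
import pickle
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import dispersal as disp
from . import heterotrophs as het
from .autotrophs import grow_phytoplankton, grow_terrestrial_leaves, leaf_mortality
from .core_state import Cohort, FunctionalGroup, GridCell, initialise_cell
from .forcing import ForcingSeries, SyntheticForcingSpec, generate_synthetic_forcing
from .heterotrophs import OffspringSpec, PreyBins
from .params import ModelParameters

__all__ = [
    "SimulationConfig",
    "OffspringSpec",
    "StepDiagnostics",
    "CellSimulation",
    "step_cell",
    "merge_cohorts",
    "run_single_cell",
    "run_simulation",
    "GridSimulation",
    "save_checkpoint",
    "load_checkpoint",
]

#: ledger flux names; signs: positive entries are system gains, negative losses
LEDGER_FIELDS = (
    "stock_growth",
    "leaf_mortality",
    "herbivory_intake",
    "herbivory_assimilated",
    "predation_intake",
    "predation_assimilated",
    "metabolic_loss",
    "mortality_loss",
    "carcass_loss",
    "extinction_loss",
    "reproduction_alloc",
)

_RESIDUAL_TOLERANCE = 1.0e-9


@dataclass
class SimulationConfig:
    """Settings of one simulation run or ensemble."""

    years: int = 10
    seed: int = 0
    ensemble: int = 1
    n_cohorts_per_group: int = 100
    detail: str = "summary"  # "summary" | "detailed"
    # grid extent; ignored for single-cell runs
    lat_min: float = -1.0
    lat_max: float = 1.0
    lon_min: float = -1.0
    lon_max: float = 1.0
    resolution_deg: float = 1.0

    def __post_init__(self) -> None:
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.ensemble < 1:
            raise ValueError("ensemble must be >= 1")
        if self.detail not in {"summary", "detailed"}:
            raise ValueError("detail must be 'summary' or 'detailed'")


@dataclass
class StepDiagnostics:
    """Per-step fluxes and the mass-balance residual for one cell."""

    step: int
    fluxes: dict = dc_field(default_factory=dict)
    residual_relative: float = 0.0
    total_biomass_kg: float = 0.0
    n_cohorts: int = 0
    n_merged: int = 0


class NegativeStateError(RuntimeError):
    """A state variable went negative: hard failure with a diagnostic dump."""


def _realm_log10_range(groups: Sequence[FunctionalGroup]) -> tuple[float, float]:
    lo = min(g.log10_min_mass_kg for g in groups)
    hi = max(g.log10_max_mass_kg for g in groups)
    return lo, hi


def step_cell(
    cell: GridCell,
    month: int,
    rng: np.random.Generator,
    params: ModelParameters,
    groups: Sequence[FunctionalGroup],
    step: int = 0,
    life_history_log: list | None = None,
    bins: PreyBins | None = None,
) -> StepDiagnostics:
    """Advance one cell by one time step; returns per-step diagnostics.

    ``life_history_log`` (if given) receives one record per cohort whose
    lifetime completes this step.  ``bins`` may be passed to reuse the
    binned prey pool allocation across steps.
    """
    num = params.numerics
    dt_days = num.timestep_days
    forcing: ForcingSeries = cell.forcing
    if forcing is None:
        raise ValueError("cell has no forcing attached")
    fx = dict.fromkeys(LEDGER_FIELDS, 0.0)
    # per-trophic-level flux breakdown for the community metrics
    fx["herbivory_by_herbivores"] = 0.0
    fx["herbivory_by_omnivores"] = 0.0
    for consumer in ("omnivores", "carnivores"):
        for prey_tl in ("herbivore", "omnivore", "carnivore"):
            fx[f"predation_by_{consumer}_on_{prey_tl}s"] = 0.0
    for tl in ("herbivore", "omnivore", "carnivore"):
        fx[f"assimilated_by_{tl}s"] = 0.0
        fx[f"metabolic_by_{tl}s"] = 0.0
        fx[f"nonpredation_deaths_by_{tl}s"] = 0.0

    total_start = cell.total_stock_biomass_kg() + cell.total_heterotroph_biomass_kg()

    # (1) autotroph growth and non-herbivory stock mortality
    if cell.realm == "marine":
        gain = grow_phytoplankton(
            cell.stocks[0], float(forcing.npp_gC_m2_month[month]),
            cell.area_km2, params.autotroph, num,
        )
        fx["stock_growth"] += gain
    else:
        gains = grow_terrestrial_leaves(
            cell.stocks, forcing, month, cell.area_km2, params.autotroph, num
        )
        fx["stock_growth"] += sum(gains.values())
        for stock in cell.stocks:
            fx["leaf_mortality"] += leaf_mortality(
                stock, forcing, month, params.autotroph, num
            )

    # (2) heterotroph cohorts in freshly randomised order
    cohorts = cell.cohorts
    if bins is None:
        bins = PreyBins(
            _realm_log10_range(groups), params.feeding.prey_bin_width_log10,
            cell.area_km2,
        )
    bins.assign(cohorts)
    offspring: list[OffspringSpec] = []
    removed: set[int] = set()
    ambient = float(forcing.temperature_C[month])
    substeps = num.feeding_substeps
    # activity depends only on (functional group, month): evaluate once
    activity_by_group = {
        g.id: het.activity_fraction(g, forcing, month, params.metabolism)
        for g in groups
    }

    for idx in rng.permutation(len(cohorts)):
        c = cohorts[idx]
        bins.settle(c)
        if c.abundance <= 0.0:
            removed.add(idx)
            continue
        group = c.group
        body_at_start = c.body_mass_kg
        act = activity_by_group[group.id]
        met = het.metabolic_loss(
            c.body_mass_kg, ambient, act,
            group.thermoregulation == "endotherm", params.metabolism, dt_days,
        )
        eff_days = dt_days * act

        # feeding
        assim = 0.0
        mode = group.feeding_mode
        if mode == "herbivore":
            intake = het.herbivory_intake(
                c, cell.stocks, cell.area_km2, eff_days, params.feeding, substeps
            )
            assim = group.herbivory_assimilation * intake
            fx["herbivory_intake"] += intake
            fx["herbivory_assimilated"] += assim
            fx["herbivory_by_herbivores"] += intake
        else:
            # predators never eat their own cohort: withdraw it while acting
            bins.remove_cohort(c)
            if mode == "carnivore":
                intake_p, _kills, by_tl = het.predation_intake(
                    c, bins, eff_days, params.feeding, substeps
                )
                intake_h = 0.0
                consumer = "carnivores"
            else:
                intake_h, intake_p, _kills, by_tl = het.omnivory_intake(
                    c, cell.stocks, bins, eff_days, params.feeding, substeps
                )
                consumer = "omnivores"
                assim += group.herbivory_assimilation * intake_h
                fx["herbivory_intake"] += intake_h
                fx["herbivory_by_omnivores"] += intake_h
            assim_p = group.carnivory_assimilation * intake_p
            assim += assim_p
            fx["herbivory_assimilated"] += assim - assim_p if mode == "omnivore" else 0.0
            fx["predation_intake"] += intake_p
            fx["predation_assimilated"] += assim_p
            for tl_name, tl_idx in (("herbivore", 0), ("omnivore", 1), ("carnivore", 2)):
                fx[f"predation_by_{consumer}_on_{tl_name}s"] += float(by_tl[tl_idx])
            bins.add_cohort(c)
            c._thin_seen = bins.survival[c._bin]

        # growth, maturation, reproduction
        n0 = c.abundance
        im0 = c.individual_mass_kg
        assim_per_ind = assim / n0
        res = het.apply_growth_and_reproduction(
            c, assim_per_ind, met, params.reproduction, num
        )
        fx["metabolic_loss"] += n0 * res.metabolic_applied_kg
        fx[f"assimilated_by_{mode}s"] += assim
        fx[f"metabolic_by_{mode}s"] += n0 * res.metabolic_applied_kg
        if res.offspring is not None:
            offspring.append(res.offspring)
            fx["reproduction_alloc"] += n0 * res.offspring_alloc_per_parent_kg
        c.last_mass_loss_fraction = max(
            0.0, (body_at_start - c.body_mass_kg) / body_at_start
        )
        if res.parent_removed:
            bins.apply_cohort_delta(c, n0, im0)
            bins.remove_cohort(c)
            fx["carcass_loss"] += n0 * res.carcass_per_parent_kg
            if life_history_log is not None:
                life_history_log.append(_life_history_record(c, step, "semelparity"))
            c.abundance = 0.0
            removed.add(idx)
            continue
        bins.apply_cohort_delta(c, n0, im0)

        # non-predation mortality
        n1 = c.abundance
        im1 = c.individual_mass_kg
        lost = het.nonpredation_mortality(c, params.mortality, dt_days)
        fx["mortality_loss"] += lost * im1
        fx[f"nonpredation_deaths_by_{mode}s"] += lost * im1
        bins.apply_cohort_delta(c, n1, im1)

        c.age_steps += 1
        if c.is_mature:
            c.steps_since_maturity += 1

    # realise any predation thinning still pending
    for c in cohorts:
        bins.settle(c)

    # (4) extinction: remove cohorts below the abundance threshold
    survivors: list[Cohort] = []
    for idx, c in enumerate(cohorts):
        if idx in removed:
            continue
        if c.abundance < num.extinction_abundance:
            fx["extinction_loss"] += c.total_biomass_kg
            if life_history_log is not None:
                life_history_log.append(_life_history_record(c, step, "extinction"))
            continue
        survivors.append(c)

    # (3) offspring cohorts are inserted after the cohort loop
    for spec in offspring:
        child = Cohort(
            spec.functional_group, spec.juvenile_mass_kg, spec.adult_mass_kg,
            spec.abundance, id=cell.next_cohort_id, parent_id=spec.parent_id,
            birth_step=step,
        )
        cell.next_cohort_id += 1
        if child.abundance >= num.extinction_abundance:
            survivors.append(child)
        else:
            fx["extinction_loss"] += child.total_biomass_kg
    cell.cohorts = survivors

    # (5) merging down to the cohort threshold
    n_merged = merge_cohorts(cell, num.max_cohorts)

    # mass balance
    total_end = cell.total_stock_biomass_kg() + cell.total_heterotroph_biomass_kg()
    expected_delta = (
        fx["stock_growth"] - fx["leaf_mortality"]
        - (fx["herbivory_intake"] - fx["herbivory_assimilated"])
        - (fx["predation_intake"] - fx["predation_assimilated"])
        - fx["metabolic_loss"] - fx["mortality_loss"]
        - fx["carcass_loss"] - fx["extinction_loss"]
    )
    scale = max(total_start, total_end, 1.0)
    residual = ((total_end - total_start) - expected_delta) / scale
    _check_state(cell, residual, step)
    return StepDiagnostics(
        step=step, fluxes=fx, residual_relative=residual,
        total_biomass_kg=total_end, n_cohorts=len(cell.cohorts),
        n_merged=n_merged,
    )


def _check_state(cell: GridCell, residual: float, step: int) -> None:
    for s in cell.stocks:
        if s.total_biomass_kg < 0 or not math.isfinite(s.total_biomass_kg):
            raise NegativeStateError(
                f"step {step}: stock {s.functional_group} biomass "
                f"{s.total_biomass_kg!r}"
            )
    for c in cell.cohorts:
        if c.abundance < 0 or c.body_mass_kg <= 0 or c.reproductive_pool_kg < 0:
            raise NegativeStateError(
                f"step {step}: invalid cohort state {c!r} "
                f"(N={c.abundance}, M={c.body_mass_kg}, R={c.reproductive_pool_kg})"
            )
    if abs(residual) > _RESIDUAL_TOLERANCE:
        raise NegativeStateError(
            f"step {step}: mass-balance residual {residual:.3e} exceeds "
            f"{_RESIDUAL_TOLERANCE:.1e}"
        )


def _life_history_record(c: Cohort, death_step: int, cause: str) -> dict:
    return {
        "id": c.id,
        "parent_id": c.parent_id,
        "functional_group": c.group.id,
        "trophic_level": c.group.feeding_mode,
        "juvenile_mass_kg": c.juvenile_mass_kg,
        "adult_mass_kg": c.adult_mass_kg,
        "max_mass_achieved_kg": c.max_mass_achieved_kg,
        "birth_step": c.birth_step,
        "death_step": death_step,
        "lifespan_steps": max(death_step - c.birth_step + 1, 1),
        "steps_to_maturity": c.steps_to_maturity,
        "offspring_per_capita": c.offspring_per_capita,
        "cause": cause,
    }


# ---------------------------------------------------------------------------
# cohort merging


def merge_cohorts(cell: GridCell, max_cohorts: int) -> int:
    """Merge nearest-in-trait-space same-group cohort pairs down to the cap.

    Trait space is (log juvenile mass, log adult mass, log current body
    mass).  The smaller cohort of each pair is absorbed: its total biomass
    (including reproductive pools) is converted into an equivalent number of
    individuals of the survivor, conserving per-functional-group biomass
    exactly.  Returns the number of merges performed; if the cap is lower
    than the number of groups present, merging stops when every group holds
    a single cohort.
    """
    excess = len(cell.cohorts) - max_cohorts
    if excess <= 0:
        return 0
    merged_total = 0
    while excess > 0:
        cohorts = cell.cohorts
        traits = np.log10(np.array(
            [[c.juvenile_mass_kg, c.adult_mass_kg, c.body_mass_kg] for c in cohorts]
        ))
        group_ids = np.array([c.group.id for c in cohorts])
        cand_d: list[np.ndarray] = []
        cand_a: list[np.ndarray] = []
        cand_b: list[np.ndarray] = []
        for gid in np.unique(group_ids):
            idx = np.nonzero(group_ids == gid)[0]
            if idx.size < 2:
                continue
            dist, nn = cKDTree(traits[idx]).query(traits[idx], k=2, workers=1)
            a, b = idx, idx[nn[:, 1]]
            keep = a < b  # de-duplicate symmetric nearest-neighbour pairs
            cand_d.append(dist[keep, 1])
            cand_a.append(a[keep])
            cand_b.append(b[keep])
        if not cand_d:
            break
        d = np.concatenate(cand_d)
        a = np.concatenate(cand_a)
        b = np.concatenate(cand_b)
        order = np.argsort(d, kind="stable")
        used = np.zeros(len(cohorts), dtype=bool)
        progress = 0
        for k in order:
            if excess <= 0:
                break
            i, j = int(a[k]), int(b[k])
            if used[i] or used[j]:
                continue
            ci, cj = cohorts[i], cohorts[j]
            survivor, donor = (ci, cj) if ci.abundance >= cj.abundance else (cj, ci)
            survivor.abundance += donor.total_biomass_kg / survivor.individual_mass_kg
            used[i] = used[j] = True
            donor.abundance = -1.0  # sentinel: absorbed
            excess -= 1
            progress += 1
            merged_total += 1
        if progress == 0:
            break
        cell.cohorts = [c for c in cohorts if c.abundance >= 0.0]
    return merged_total


# ---------------------------------------------------------------------------
# single-cell simulation driver


class CellSimulation:
    """Stateful single-cell run supporting stepping and checkpointing."""

    def __init__(
        self,
        cell: GridCell,
        groups: Sequence[FunctionalGroup],
        params: ModelParameters,
        seed: int,
        detail: str = "summary",
    ) -> None:
        self.cell = cell
        self.groups = [g for g in groups if g.realm == cell.realm]
        self.params = params
        self.seed = seed
        self.detail = detail
        self.rng = np.random.default_rng(seed)
        self.step_index = 0
        self.history_rows: list[dict] = []
        self.flux_rows: list[dict] = []
        self.life_history: list[dict] = []
        self._bins = PreyBins(
            _realm_log10_range(self.groups),
            params.feeding.prey_bin_width_log10, cell.area_km2,
        )

    @property
    def steps_per_year(self) -> int:
        return self.params.numerics.steps_per_year

    def run_years(self, years: int) -> None:
        for _ in range(years * self.steps_per_year):
            self.advance_step()

    def advance_step(self) -> StepDiagnostics:
        month = self.step_index % 12
        log = self.life_history if self.detail == "detailed" else None
        diag = step_cell(
            self.cell, month, self.rng, self.params, self.groups,
            step=self.step_index, life_history_log=log, bins=self._bins,
        )
        self._record(diag)
        self.step_index += 1
        return diag

    def _record(self, diag: StepDiagnostics) -> None:
        area = self.cell.area_km2
        by_group: dict[str, list[float]] = {g.id: [0.0, 0.0] for g in self.groups}
        for c in self.cell.cohorts:
            acc = by_group[c.group.id]
            acc[0] += c.total_biomass_kg
            acc[1] += c.abundance
        group_lookup = {g.id: g for g in self.groups}
        for gid, (bm, ab) in sorted(by_group.items()):
            self.history_rows.append({
                "step": diag.step, "functional_group": gid,
                "trophic_level": group_lookup[gid].feeding_mode,
                "biomass_density_kg_km2": bm / area,
                "abundance_density_km2": ab / area,
            })
        for s in self.cell.stocks:
            self.history_rows.append({
                "step": diag.step, "functional_group": s.functional_group,
                "trophic_level": "autotroph",
                "biomass_density_kg_km2": s.total_biomass_kg / area,
                "abundance_density_km2": float("nan"),
            })
        row = {"step": diag.step, **diag.fluxes,
               "residual_relative": diag.residual_relative,
               "n_cohorts": diag.n_cohorts, "n_merged": diag.n_merged}
        self.flux_rows.append(row)

    # result tables -------------------------------------------------------
    def history(self) -> pd.DataFrame:
        return pd.DataFrame(self.history_rows)

    def fluxes(self) -> pd.DataFrame:
        return pd.DataFrame(self.flux_rows)

    def life_history_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.life_history)


def run_single_cell(
    forcing_spec: SyntheticForcingSpec | ForcingSeries,
    groups: Sequence[FunctionalGroup],
    params: ModelParameters,
    years: int,
    seed: int,
    n_cohorts_per_group: int = 100,
    detail: str = "summary",
    lat_deg: float = 0.0,
    lon_deg: float = 0.0,
) -> CellSimulation:
    """Seed and run one isolated cell (dispersal disabled) for ``years``."""
    if isinstance(forcing_spec, ForcingSeries):
        forcing = forcing_spec
        realm = "marine" if forcing.current_u_ms is not None else "terrestrial"
    else:
        forcing = generate_synthetic_forcing(forcing_spec)
        realm = forcing_spec.realm
    cell = GridCell(lat_deg=lat_deg, lon_deg=lon_deg, realm=realm)
    cell.forcing = forcing
    realm_groups = [g for g in groups if g.realm == realm]
    num = params.numerics
    initialise_cell(
        cell, realm_groups, n_cohorts_per_group, rng_seed=seed,
        seed_biomass_density_kg_km2=num.seed_biomass_density_kg_km2,
        abundance_mass_exponent=num.seed_abundance_mass_exponent,
        autotroph_params=params.autotroph,
        trophic_fractions={
            "herbivore": num.seed_fraction_herbivores,
            "omnivore": num.seed_fraction_omnivores,
            "carnivore": num.seed_fraction_carnivores,
        },
    )
    sim = CellSimulation(cell, realm_groups, params, seed, detail)
    sim.run_years(years)
    return sim


def run_simulation(
    config: SimulationConfig,
    forcing_spec: SyntheticForcingSpec,
    groups: Sequence[FunctionalGroup],
    params: ModelParameters,
) -> dict[int, CellSimulation]:
    """Run an ensemble of independent single-cell simulations.

    Members use seeds ``config.seed + k``; output schema is identical
    across members.  Returns a mapping from member index to its simulation.
    """
    out: dict[int, CellSimulation] = {}
    for k in range(config.ensemble):
        out[k] = run_single_cell(
            forcing_spec, groups, params, config.years,
            seed=config.seed + k,
            n_cohorts_per_group=config.n_cohorts_per_group,
            detail=config.detail,
        )
    return out


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(sim: CellSimulation, path: str | Path) -> None:
    """Serialise the full run state (including the RNG) to ``path``."""
    with open(path, "wb") as fh:
        pickle.dump(sim, fh)


def load_checkpoint(path: str | Path) -> CellSimulation:
    """Restore a run saved by :func:`save_checkpoint`; continuing it
    reproduces the unbroken run bit-exactly."""
    with open(path, "rb") as fh:
        return pickle.load(fh)


# ---------------------------------------------------------------------------
# multi-cell grid with dispersal


class GridSimulation:
    """A lat-lon grid of cells stepped together and coupled by dispersal.

    Each cell owns two independent RNG substreams (ecology, dispersal)
    spawned deterministically from the run seed, so trajectories do not
    depend on cell iteration order.  Dispersal moves are decided for all
    cells first and applied afterwards; advective moves that would land on
    a terrestrial cell are reflected back.
    """

    def __init__(
        self,
        cells: dict[tuple[int, int], GridCell],
        groups: Sequence[FunctionalGroup],
        params: ModelParameters,
        seed: int,
        dispersal_enabled: bool = True,
    ) -> None:
        self.cells = cells
        self.groups = list(groups)
        self.params = params
        self.dispersal_enabled = dispersal_enabled and len(cells) > 1
        self.step_index = 0
        keys = sorted(cells)
        seq = np.random.SeedSequence(seed)
        children = seq.spawn(2 * len(keys))
        self.ecology_rng = {
            k: np.random.default_rng(children[2 * i]) for i, k in enumerate(keys)
        }
        self.dispersal_rng = {
            k: np.random.default_rng(children[2 * i + 1]) for i, k in enumerate(keys)
        }

    def advance_step(self) -> dict[tuple[int, int], StepDiagnostics]:
        month = self.step_index % 12
        diags = {}
        for key in sorted(self.cells):
            cell = self.cells[key]
            if not cell.active:
                continue
            realm_groups = [g for g in self.groups if g.realm == cell.realm]
            diags[key] = step_cell(
                cell, month, self.ecology_rng[key], self.params, realm_groups,
                step=self.step_index,
            )
        if self.dispersal_enabled:
            self._dispersal_phase(month)
        self.step_index += 1
        return diags

    def run_years(self, years: int) -> None:
        steps = years * self.params.numerics.steps_per_year
        for _ in range(steps):
            self.advance_step()

    def _dispersal_phase(self, month: int) -> None:
        p = self.params.dispersal
        dt_days = self.params.numerics.timestep_days
        moves: list[tuple[tuple[int, int], tuple[int, int], Cohort]] = []
        for key in sorted(self.cells):
            cell = self.cells[key]
            if not cell.active:
                continue
            rng = self.dispersal_rng[key]
            for c in cell.cohorts:
                offset = self._decide_move(c, cell, month, rng, p, dt_days)
                if offset is None:
                    continue
                dest = self._destination(key, offset, cell)
                if dest is not None:
                    moves.append((key, dest, c))
        for src, dest, cohort in moves:
            self.cells[src].cohorts.remove(cohort)
            self.cells[dest].cohorts.append(cohort)

    def _decide_move(self, c, cell, month, rng, p, dt_days):
        if disp.is_planktonic(c, p):
            if cell.realm != "marine":
                return None
            f = cell.forcing
            u = float(f.current_u_ms[month]) if f.current_u_ms is not None else 0.0
            v = float(f.current_v_ms[month]) if f.current_v_ms is not None else 0.0
            return disp.advective_dispersal(c, cell, u, v, p, rng, dt_days)
        if c.age_steps == 0:
            return disp.natal_dispersal(c, cell, p, rng)
        if c.is_mature:
            return disp.responsive_dispersal(
                c, cell, c.last_mass_loss_fraction, p, rng
            )
        return None

    def _destination(self, key, offset, src_cell):
        di, dj = offset
        dest = (key[0] + di, key[1] + dj)
        target = self.cells.get(dest)
        if target is not None and target.active and target.realm == src_cell.realm:
            return dest
        # reflect moves that would leave the grid or land on the wrong realm
        reflected = (key[0] - di, key[1] - dj)
        target = self.cells.get(reflected)
        if target is not None and target.active and target.realm == src_cell.realm:
            return reflected
        return None

    def total_biomass_kg(self) -> float:
        return sum(
            c.total_stock_biomass_kg() + c.total_heterotroph_biomass_kg()
            for c in self.cells.values()
        )

    def total_abundance(self) -> float:
        return sum(
            sum(co.abundance for co in c.cohorts) for c in self.cells.values()
        )

    def total_cohorts(self) -> int:
        return sum(len(c.cohorts) for c in self.cells.values())
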