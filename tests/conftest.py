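"""Shared fixtures: functional groups, parameters, small seeded cells."""

from __future__ import annotations

import numpy as np
import pytest

from gemsim.core_state import GridCell, initialise_cell
from gemsim.forcing import archetype_spec, generate_synthetic_forcing
from gemsim.io_config import load_functional_groups
from gemsim.params import ModelParameters


@pytest.fixture(scope="session")
def groups():
    return load_functional_groups()[0]


@pytest.fixture(scope="session")
def terrestrial_groups(groups):
    return [g for g in groups if g.realm == "terrestrial"]


@pytest.fixture(scope="session")
def marine_groups(groups):
    return [g for g in groups if g.realm == "marine"]


@pytest.fixture()
def params():
    return ModelParameters()


def make_cell(realm, groups, params, n_per_group=8, seed=7, archetype=None):
    """A small seeded cell with archetype forcing attached."""
    if archetype is None:
        archetype = (
            "terrestrial_tropical_aseasonal"
            if realm == "terrestrial"
            else "marine_low_productivity_aseasonal"
        )
    cell = GridCell(lat_deg=0.0, lon_deg=0.0, realm=realm)
    cell.forcing = generate_synthetic_forcing(archetype_spec(archetype))
    realm_groups = [g for g in groups if g.realm == realm]
    initialise_cell(
        cell, realm_groups, n_per_group, rng_seed=seed,
        seed_biomass_density_kg_km2=params.numerics.seed_biomass_density_kg_km2,
        abundance_mass_exponent=params.numerics.seed_abundance_mass_exponent,
        autotroph_params=params.autotroph,
    )
    return cell


@pytest.fixture()
def terrestrial_cell(terrestrial_groups, params):
    return make_cell("terrestrial", terrestrial_groups, params)


@pytest.fixture()
def marine_cell(marine_groups, params):
    return make_cell("marine", marine_groups, params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
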