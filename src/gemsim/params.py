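"""Model parameters: rate constants, exponents, efficiencies and thresholds.

All parameters are grouped by ecological process into small frozen-ish
dataclasses, gathered under :class:`ModelParameters`.  Internal unit
conventions (fixed throughout the package):

* mass: kg wet matter
* area: km^2
* instantaneous rates: per day
* stock/biomass densities: kg km^-2; abundance densities: individuals km^-2
* forcing NPP: g C m^-2 month^-1, converted to wet matter at point of use
* temperature: degrees C in forcing, Kelvin inside metabolic evaluation

Every ``from_dict`` constructor rejects unknown keys so that a typo in a
configuration file fails loudly instead of silently using a default.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any, Mapping

__all__ = [
    "FeedingParams",
    "MetabolismParams",
    "ReproductionParams",
    "MortalityParams",
    "DispersalParams",
    "AutotrophParams",
    "NumericsParams",
    "ModelParameters",
]

BOLTZMANN_EV_PER_K = 8.617333262e-5


class ParameterError(ValueError):
    """Raised when a parameter value or key is invalid."""


def _from_dict(cls, data: Mapping[str, Any]):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ParameterError(
            f"{cls.__name__}: unknown parameter key(s): {sorted(unknown)}"
        )
    obj = cls(**data)
    obj.validate()
    return obj


def _check_finite(obj) -> None:
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, (int, float)) and not math.isfinite(v):
            raise ParameterError(f"{type(obj).__name__}.{f.name} is not finite: {v}")


@dataclass
class FeedingParams:
    """Holling Type III feeding parameters for herbivory and predation.

    The per-individual instantaneous intake rate on a resource of density
    ``D`` is ``a * D**2 / (1 + a * h * D**2)``: sigmoidal in density with a
    handling-time-limited ceiling ``1/h``.

    Herbivore search rate scales linearly with herbivore body mass
    (``a = herbivore_search_rate_per_mass * M``); herbivore handling time per
    kg of plant matter is a decreasing power law of herbivore mass.  Predator
    attack follows a size-structured niche kernel: the attack rate on a prey
    mass bin is weighted by a Gaussian (in log mass) centred on
    ``optimal_prey_mass_ratio * predator mass``.  Predator handling time per
    prey individual increases linearly with prey mass and decreases as a
    power law of predator mass.
    """

    #: herbivore attack coefficient per kg of herbivore body mass
    #: [km^4 kg^-2 day^-1 kg^-1]; attack = const * M_herbivore.  Terrestrial
    #: foliage is far harder to find and crop than phytoplankton, hence the
    #: realm contrast.
    herbivore_search_rate_per_mass_terrestrial: float = 1.5e-12
    herbivore_search_rate_per_mass_marine: float = 2.0e-7
    #: handling time for 1 kg of plant matter by a 1 kg herbivore [day kg^-1]
    herbivore_handling_const: float = 3.3
    #: handling time declines as M^-exponent
    herbivore_handling_exponent: float = 0.95
    #: predator attack prefactor [km^4 ind^-2 day^-1 kg^-exponent]; the
    #: realm contrast mirrors the very different prey densities and optimal
    #: prey sizes of pelagic versus terrestrial food webs
    predator_search_const_terrestrial: float = 5.2e-9
    predator_search_const_marine: float = 9.3e-11
    #: predator attack scales as M_predator^exponent; the steeper marine
    #: scaling reflects prey density declining steeply with prey size in
    #: pelagic webs, so that small and large predators saturate at
    #: comparable prey biomasses in both realms
    predator_search_exponent_terrestrial: float = 1.0
    predator_search_exponent_marine: float = 1.0
    #: centre of the log-Gaussian prey-preference kernel, terrestrial realm
    optimal_prey_mass_ratio_terrestrial: float = 0.5
    #: centre of the log-Gaussian prey-preference kernel, marine realm
    optimal_prey_mass_ratio_marine: float = 0.01
    #: s.d. of the preference kernel in ln(prey mass) units
    preference_gaussian_width: float = 0.8
    #: kernel weights below this are treated as zero (sparsity cut-off)
    preference_cutoff: float = 1.0e-3
    #: handling time per prey individual: const * M_prey * M_pred^-exponent [day]
    predator_handling_const: float = 12.0
    predator_handling_exponent: float = 0.95
    #: fraction of stock biomass experienced by one herbivore cohort (phi)
    stock_fraction_experienced_terrestrial: float = 0.1
    stock_fraction_experienced_marine: float = 1.0
    #: width of predator-facing prey mass bins in log10(kg)
    prey_bin_width_log10: float = 0.5
    #: fraction of each time step an omnivore spends on herbivory
    #: (remainder is spent on predation)
    omnivory_herbivory_time_fraction_terrestrial: float = 0.3
    omnivory_herbivory_time_fraction_marine: float = 0.2

    def validate(self) -> None:
        _check_finite(self)
        if not (0.0 < self.stock_fraction_experienced_terrestrial <= 1.0):
            raise ParameterError("stock_fraction_experienced_terrestrial must be in (0, 1]")
        if not (0.0 < self.stock_fraction_experienced_marine <= 1.0):
            raise ParameterError("stock_fraction_experienced_marine must be in (0, 1]")
        if self.preference_gaussian_width <= 0:
            raise ParameterError("preference_gaussian_width must be > 0")
        if self.herbivore_handling_const <= 0 or self.predator_handling_const <= 0:
            raise ParameterError("handling-time constants must be > 0")
        if (
            self.herbivore_search_rate_per_mass_terrestrial < 0
            or self.herbivore_search_rate_per_mass_marine < 0
            or self.predator_search_const_terrestrial < 0
            or self.predator_search_const_marine < 0
        ):
            raise ParameterError("search-rate constants must be >= 0")
        for name in ("omnivory_herbivory_time_fraction_terrestrial",
                     "omnivory_herbivory_time_fraction_marine"):
            if not (0.0 < getattr(self, name) < 1.0):
                raise ParameterError(f"{name} must be in (0, 1)")
        if self.prey_bin_width_log10 <= 0:
            raise ParameterError("prey_bin_width_log10 must be > 0")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "FeedingParams":
        return _from_dict(cls, data)

    def omnivory_herbivory_time_fraction(self, realm: str) -> float:
        return (
            self.omnivory_herbivory_time_fraction_marine
            if realm == "marine"
            else self.omnivory_herbivory_time_fraction_terrestrial
        )

    def predator_search_const(self, realm: str) -> float:
        return (
            self.predator_search_const_marine
            if realm == "marine"
            else self.predator_search_const_terrestrial
        )

    def predator_search_exponent(self, realm: str) -> float:
        return (
            self.predator_search_exponent_marine
            if realm == "marine"
            else self.predator_search_exponent_terrestrial
        )

    def herbivore_search_rate_per_mass(self, realm: str) -> float:
        return (
            self.herbivore_search_rate_per_mass_marine
            if realm == "marine"
            else self.herbivore_search_rate_per_mass_terrestrial
        )

    def stock_fraction_experienced(self, realm: str) -> float:
        return (
            self.stock_fraction_experienced_marine
            if realm == "marine"
            else self.stock_fraction_experienced_terrestrial
        )

    def optimal_prey_mass_ratio(self, realm: str) -> float:
        return (
            self.optimal_prey_mass_ratio_marine
            if realm == "marine"
            else self.optimal_prey_mass_ratio_terrestrial
        )


@dataclass
class MetabolismParams:
    """Boltzmann-Arrhenius metabolic costs with activity weighting.

    The metabolic biomass loss per individual per day is::

        (act * I_field + (1 - act) * I_basal) / energy_per_kg

    with ``I_x = rate_const_x * M**mass_exponent_x * exp(-E_A / (k_B * T))``
    in kJ day^-1, ``T`` the body temperature in Kelvin (310 K for
    endotherms, ambient for ectotherms) and ``act`` the fraction of the step
    the organism is active.  The rate constants are mass- and
    temperature-independent prefactors; their defaults are normalised so a
    1 kg endotherm at 310 K spends roughly 700 kJ day^-1 in the field.

    Thermal activity limits of terrestrial ectotherms are estimated from the
    cell's climatology (Deutsch-style): tolerance breadth widens with
    seasonality.
    """

    field_rate_const: float = 350.0 * 1.652e11  # kJ day^-1 kg^-exponent
    basal_rate_const: float = 150.0 * 1.652e11
    field_mass_exponent: float = 0.9
    basal_mass_exponent: float = 0.88
    activation_energy_eV: float = 0.69
    boltzmann_eV_per_K: float = BOLTZMANN_EV_PER_K
    endotherm_body_temp_K: float = 310.0
    #: energy content of wet tissue [kJ kg^-1]
    energy_per_kg: float = 7000.0
    #: upper activity limit = annual mean T + offset + slope * seasonal range
    thermal_upper_offset_C: float = 10.0
    thermal_upper_seasonality_slope: float = 0.6
    #: lower activity limit = annual mean T - (offset + slope * seasonal range)
    thermal_lower_offset_C: float = 10.0
    thermal_lower_seasonality_slope: float = 0.7
    #: assumed within-month ambient range (diurnal + synoptic), full width [C]
    within_month_temperature_range_C: float = 10.0

    def validate(self) -> None:
        _check_finite(self)
        for name in ("field_mass_exponent", "basal_mass_exponent"):
            v = getattr(self, name)
            if not (0.0 < v < 1.2):
                raise ParameterError(f"{name} must lie in (0, 1.2), got {v}")
        if self.field_rate_const <= 0 or self.basal_rate_const <= 0:
            raise ParameterError("metabolic rate constants must be > 0")
        if self.energy_per_kg <= 0:
            raise ParameterError("energy_per_kg must be > 0")
        if self.endotherm_body_temp_K <= 0:
            raise ParameterError("endotherm_body_temp_K must be > 0")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "MetabolismParams":
        return _from_dict(cls, data)


@dataclass
class ReproductionParams:
    """Thresholded reproduction out of a stored reproductive-potential pool."""

    #: reproductive event fires when R_i >= threshold * adult mass
    mass_threshold_ratio: float = 0.25
    #: fraction of body mass a semelparous parent additionally allocates
    semelparous_adult_mass_fraction: float = 0.5

    def validate(self) -> None:
        _check_finite(self)
        if self.mass_threshold_ratio <= 0:
            raise ParameterError("mass_threshold_ratio must be > 0")
        if not (0.0 <= self.semelparous_adult_mass_fraction <= 1.0):
            raise ParameterError("semelparous_adult_mass_fraction must be in [0, 1]")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ReproductionParams":
        return _from_dict(cls, data)


@dataclass
class MortalityParams:
    """Background, starvation and senescence mortality rates (all per day).

    Starvation mortality is a logistic function of the ratio of current body
    mass to the maximum mass ever achieved, saturating at ``starvation_max_rate``
    as the ratio falls; it is zero while no body mass has been lost.
    Senescence mortality is zero before maturity, equals
    ``senescence_rate_at_maturity`` at the point of maturity and grows
    exponentially with time since maturity measured in units of the time the
    cohort took to mature (Gompertz-like).
    """

    background_rate: float = 5.0e-4
    starvation_max_rate: float = 0.1
    #: body-mass ratio at which starvation mortality reaches half its maximum
    starvation_inflection: float = 0.6
    #: logistic scale of the starvation response (ratio units)
    starvation_scale: float = 0.05
    senescence_rate_at_maturity: float = 2.0e-4
    #: e-folding of the post-maturity senescence rate, in units of the time
    #: the cohort took to mature (larger = gentler ageing)
    senescence_time_scale: float = 3.0

    def validate(self) -> None:
        _check_finite(self)
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ParameterError(f"{f.name} must be >= 0")
        if self.starvation_scale == 0:
            raise ParameterError("starvation_scale must be > 0")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "MortalityParams":
        return _from_dict(cls, data)


@dataclass
class DispersalParams:
    """Diffusive natal, responsive, and advective dispersal parameters."""

    #: characteristic natal dispersal distance per step at the reference mass [km]
    reference_speed_km: float = 25.0
    reference_mass_kg: float = 1.0
    #: body-mass exponent of dispersal distance
    mass_exponent: float = 0.25
    #: responsive dispersal fires when adult density [ind km^-2] falls below
    #: density_threshold_const * M^density_threshold_exponent
    density_threshold_const: float = 1.0e-6
    density_threshold_exponent: float = -1.0
    #: ... or when the fraction of body mass lost in one step exceeds this
    starvation_mass_loss_threshold: float = 0.1
    #: s.d. of the random diffusive kick added to advection [km]
    advective_diffusion_km: float = 5.0
    #: organisms lighter than this disperse planktonically (advection)
    planktonic_mass_threshold_kg: float = 1.0e-5

    def validate(self) -> None:
        _check_finite(self)
        if self.reference_speed_km < 0:
            raise ParameterError("reference_speed_km must be >= 0")
        if self.reference_mass_kg <= 0:
            raise ParameterError("reference_mass_kg must be > 0")
        if self.density_threshold_const < 0 or self.starvation_mass_loss_threshold < 0:
            raise ParameterError("dispersal thresholds must be >= 0")
        if self.advective_diffusion_km < 0:
            raise ParameterError("advective_diffusion_km must be >= 0")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "DispersalParams":
        return _from_dict(cls, data)


@dataclass
class AutotrophParams:
    """Autotroph stock growth, allocation, and leaf-mortality parameters.

    The terrestrial climate-response surfaces (structural allocation
    ``f_struct``, evergreen fraction ``f_ever``, seasonal concentration of
    deciduous leaf fall) are parametric logistic forms with re-tuned
    coefficients; they are this package's own calibration, chosen so that
    warm, high-NPP climates allocate strongly to structural tissue and
    retain evergreen canopies, while cold-seasonal climates shed deciduous
    leaves in the cold months.
    """

    #: carbon -> wet matter conversion for phytoplankton (kg wet per kg C)
    carbon_to_wet_marine: float = 10.0
    #: carbon -> wet matter conversion for leaves (kg wet per kg C)
    carbon_to_wet_terrestrial: float = 7.0
    #: annual leaf mortality rates [yr^-1]
    mu_evergreen_per_year: float = 0.5
    mu_deciduous_per_year: float = 1.5
    #: fraction of whole-plant mortality that is leaf mortality (leaf pools
    #: only are tracked, so the neutral default is 1)
    leaf_fraction_of_mortality: float = 1.0
    #: f_struct = min + (max - min) * logistic((NPP_annual - x0) / scale)
    f_struct_min: float = 0.3
    f_struct_max: float = 0.8
    f_struct_npp0_gC_m2_yr: float = 500.0
    f_struct_npp_scale: float = 250.0
    #: f_ever = logistic((coldest monthly T - t0) / scale)
    f_ever_temp0_C: float = 5.0
    f_ever_temp_scale: float = 5.0
    #: deciduous leaf fall concentrates in months colder than this
    deciduous_fall_temp0_C: float = 10.0
    deciduous_fall_temp_scale: float = 3.0

    def validate(self) -> None:
        _check_finite(self)
        if self.carbon_to_wet_marine <= 0 or self.carbon_to_wet_terrestrial <= 0:
            raise ParameterError("carbon->wet conversions must be > 0")
        if self.mu_evergreen_per_year < 0 or self.mu_deciduous_per_year < 0:
            raise ParameterError("leaf mortality rates must be >= 0")
        if not (0.0 <= self.f_struct_min <= self.f_struct_max <= 1.0):
            raise ParameterError("need 0 <= f_struct_min <= f_struct_max <= 1")
        if not (0.0 <= self.leaf_fraction_of_mortality <= 1.0):
            raise ParameterError("leaf_fraction_of_mortality must be in [0, 1]")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "AutotrophParams":
        return _from_dict(cls, data)


@dataclass
class NumericsParams:
    """Time stepping, cohort-count control, and discretisation settings."""

    #: model time step in days (monthly default; use 1.0 for daily stepping)
    timestep_days: float = 30.0
    #: number of time steps per month of forcing (NPP month -> step conversion)
    months_per_step: float = 1.0
    #: cohort-count threshold above which merging is activated
    max_cohorts: int = 1000
    #: cohorts with fewer individuals than this are removed
    extinction_abundance: float = 1.0
    #: sub-steps of the within-step exponential depletion of feeding losses
    feeding_substeps: int = 8
    #: body mass never falls below this fraction of juvenile mass
    body_mass_floor_fraction: float = 0.01
    #: initial community: total heterotroph biomass density target
    seed_biomass_density_kg_km2: float = 5.0e4
    #: initial abundance scales as (adult mass)^exponent
    seed_abundance_mass_exponent: float = -1.0
    #: split of the seed biomass target across feeding modes (bottom-heavy,
    #: so the initial predator load does not exceed what the prey flux of
    #: the young community can support)
    seed_fraction_herbivores: float = 0.80
    seed_fraction_omnivores: float = 0.15
    seed_fraction_carnivores: float = 0.05

    def validate(self) -> None:
        _check_finite(self)
        if self.timestep_days <= 0:
            raise ParameterError("timestep_days must be > 0")
        if self.max_cohorts < 1:
            raise ParameterError("max_cohorts must be >= 1")
        if self.feeding_substeps < 1:
            raise ParameterError("feeding_substeps must be >= 1")
        if self.extinction_abundance < 0:
            raise ParameterError("extinction_abundance must be >= 0")
        if not (0.0 < self.body_mass_floor_fraction < 1.0):
            raise ParameterError("body_mass_floor_fraction must be in (0, 1)")
        if self.seed_biomass_density_kg_km2 <= 0:
            raise ParameterError("seed_biomass_density_kg_km2 must be > 0")
        if self.seed_abundance_mass_exponent >= 0:
            raise ParameterError("seed_abundance_mass_exponent must be < 0")
        fr = (self.seed_fraction_herbivores + self.seed_fraction_omnivores
              + self.seed_fraction_carnivores)
        if abs(fr - 1.0) > 1e-9 or min(
            self.seed_fraction_herbivores, self.seed_fraction_omnivores,
            self.seed_fraction_carnivores,
        ) <= 0:
            raise ParameterError("seed trophic fractions must be positive and sum to 1")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "NumericsParams":
        return _from_dict(cls, data)

    @property
    def steps_per_year(self) -> int:
        return max(1, round(365.0 / self.timestep_days))


@dataclass
class ModelParameters:
    """All rate constants, exponents, efficiencies and thresholds, by process."""

    feeding: FeedingParams = field(default_factory=FeedingParams)
    metabolism: MetabolismParams = field(default_factory=MetabolismParams)
    reproduction: ReproductionParams = field(default_factory=ReproductionParams)
    mortality: MortalityParams = field(default_factory=MortalityParams)
    dispersal: DispersalParams = field(default_factory=DispersalParams)
    autotroph: AutotrophParams = field(default_factory=AutotrophParams)
    numerics: NumericsParams = field(default_factory=NumericsParams)

    _SECTIONS = {
        "feeding": FeedingParams,
        "metabolism": MetabolismParams,
        "reproduction": ReproductionParams,
        "mortality": MortalityParams,
        "dispersal": DispersalParams,
        "autotroph": AutotrophParams,
        "numerics": NumericsParams,
    }

    def validate(self) -> None:
        for name in self._SECTIONS:
            getattr(self, name).validate()

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ModelParameters":
        unknown = set(data) - set(cls._SECTIONS)
        if unknown:
            raise ParameterError(f"unknown parameter section(s): {sorted(unknown)}")
        kwargs = {
            name: section_cls.from_dict(data.get(name, {}))
            for name, section_cls in cls._SECTIONS.items()
        }
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {name: dataclasses.asdict(getattr(self, name)) for name in self._SECTIONS}
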