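"""Per-cohort, per-step heterotroph ecology.

Feeding (herbivory, predation, omnivory) uses Holling Type III functional
responses: intake is sigmoidal in resource density with a
handling-time-limited ceiling.  Predation is size-structured: prey cohorts
are aggregated into log-mass bins and the attack rate on each bin is
weighted by a Gaussian kernel (in log mass) centred on an optimal prey:
predator mass ratio.  Within a time step, losses are applied with an
exponential discretisation of the summed instantaneous rates over a small
number of sub-steps, so that simultaneous consumers compete proportionally
and no state variable can go negative.

Metabolism follows a Boltzmann-Arrhenius mass power law with separate field
and basal rates weighted by the fraction of the step an organism is active.
Net biomass gain drives growth of juveniles and accumulation of
reproductive-potential mass in adults; reproduction is thresholded and
spawns offspring cohorts.  Non-predation mortality combines constant
background, starvation (logistic in the ratio of current to maximum body
mass) and Gompertz-like senescence channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

try:  # the jitted feeding kernels fall back to pure Python transparently
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a standard install
    def _njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda fn: fn

from .core_state import Cohort, FunctionalGroup, Stock
from .forcing import ForcingSeries
from .params import (
    FeedingParams,
    MetabolismParams,
    ModelParameters,
    MortalityParams,
    NumericsParams,
    ReproductionParams,
)

__all__ = [
    "OffspringSpec",
    "PreyBins",
    "activity_fraction",
    "herbivory_intake",
    "predation_intake",
    "omnivory_intake",
    "metabolic_loss",
    "apply_growth_and_reproduction",
    "nonpredation_mortality",
    "theoretical_max_growth_rate",
]

_TROPHIC_INDEX = {"herbivore": 0, "omnivore": 1, "carnivore": 2}
_TINY = 1.0e-30


@dataclass
class OffspringSpec:
    """Specification of an offspring cohort emitted by a reproductive event."""

    parent_id: int
    functional_group: FunctionalGroup
    abundance: float
    juvenile_mass_kg: float
    adult_mass_kg: float

    def __post_init__(self) -> None:
        if self.abundance <= 0:
            raise ValueError("offspring abundance must be > 0")


# ---------------------------------------------------------------------------
# thermal activity windows


def activity_fraction(
    group: FunctionalGroup,
    forcing: ForcingSeries,
    month: int,
    params: MetabolismParams,
) -> float:
    """Fraction of the time step an organism of ``group`` is active.

    Endotherms thermoregulate and marine ectotherms live in a thermally
    buffered medium: both are active the whole step.  Terrestrial ectotherms
    are active for the fraction of the month that ambient temperature falls
    inside climate-estimated activity limits: tolerance is centred on the
    annual mean and widens with seasonality, and within-month temperatures
    are assumed spread uniformly over a fixed range about the monthly mean.
    """
    if group.thermoregulation == "endotherm" or group.realm == "marine":
        return 1.0
    t_month = float(forcing.temperature_C[month])
    t_ann = forcing.annual_mean_temperature_C
    seas = forcing.seasonal_temperature_range_C
    upper = t_ann + params.thermal_upper_offset_C + params.thermal_upper_seasonality_slope * seas
    lower = t_ann - (params.thermal_lower_offset_C + params.thermal_lower_seasonality_slope * seas)
    half = params.within_month_temperature_range_C / 2.0
    if half <= 0.0:
        return 1.0 if lower <= t_month <= upper else 0.0
    overlap = min(t_month + half, upper) - max(t_month - half, lower)
    return min(max(overlap / (2.0 * half), 0.0), 1.0)


# ---------------------------------------------------------------------------
# herbivory


def herbivory_intake(
    cohort: Cohort,
    stocks: list[Stock],
    area_km2: float,
    effective_days: float,
    params: FeedingParams,
    substeps: int,
) -> float:
    """Graze ``stocks`` over the step; returns total pre-assimilation intake.

    The instantaneous per-individual rate on stock ``k`` with experienced
    biomass density ``D = phi * B_k / A`` is ``a * D^2 / (1 + sum_k a * h *
    D^2)`` (kg per day), with search rate ``a`` linear in herbivore mass and
    handling time ``h`` a decreasing power of herbivore mass.  Depletion is
    integrated over ``substeps`` exponential sub-steps; stocks are reduced
    in place by the cumulative intake of the cohort.
    """
    m = cohort.body_mass_kg
    n = cohort.abundance
    if n <= 0.0 or effective_days <= 0.0 or not stocks:
        return 0.0
    phi = params.stock_fraction_experienced(cohort.group.realm)
    attack = params.herbivore_search_rate_per_mass(cohort.group.realm) * m
    handling = params.herbivore_handling_const * m ** (-params.herbivore_handling_exponent)
    biomass = np.array([s.total_biomass_kg for s in stocks])
    eaten = _herbivory_kernel(
        biomass, attack, handling, phi, area_km2, n,
        effective_days / substeps, substeps,
    )
    for s, bm in zip(stocks, biomass):
        s.total_biomass_kg = bm
    return float(np.sum(eaten))


@_njit(cache=True)
def _herbivory_rates(biomass, attack, handling, phi, area, n, out):
    """Fractional grazing loss rate of each stock (per day)."""
    k = biomass.shape[0]
    denom = 1.0
    for i in range(k):
        d = phi * biomass[i] / area
        denom += attack * handling * d * d
    for i in range(k):
        if biomass[i] <= _TINY:
            out[i] = 0.0
        else:
            d = phi * biomass[i] / area
            out[i] = n * (attack * d * d / denom) / biomass[i]


@_njit(cache=True)
def _herbivory_kernel(biomass, attack, handling, phi, area, n, dt_sub, substeps):
    """Sub-stepped exponential depletion of the stocks by one cohort.

    Each sub-step uses Heun-type exponential differencing: the fractional
    loss rates are averaged between the sub-step start and a provisional
    end state, giving second-order accuracy in the sub-step length.
    """
    k = biomass.shape[0]
    eaten = np.zeros(k)
    lam1 = np.zeros(k)
    lam2 = np.zeros(k)
    trial = np.zeros(k)
    for _ in range(substeps):
        _herbivory_rates(biomass, attack, handling, phi, area, n, lam1)
        for i in range(k):
            trial[i] = biomass[i] * math.exp(-lam1[i] * dt_sub)
        _herbivory_rates(trial, attack, handling, phi, area, n, lam2)
        for i in range(k):
            if biomass[i] <= _TINY:
                continue
            # cap the exponent: exact exponential decay never reaches zero,
            # so keep the discrete state strictly positive too
            x = min(0.5 * (lam1[i] + lam2[i]) * dt_sub, 27.0)
            bite = biomass[i] * -math.expm1(-x)
            biomass[i] -= bite
            eaten[i] += bite
    return eaten


# ---------------------------------------------------------------------------
# size-structured predation on binned prey


class PreyBins:
    """Log-mass-binned aggregation of the cell's cohorts as a prey pool.

    Keeps per-bin abundance, biomass (body plus reproductive pool) and a
    biomass split by trophic class, all consistent with the cohort states:
    predation thins bins proportionally through a per-bin survival product
    that is applied lazily to member cohorts (:meth:`settle`), and cohort
    state changes are pushed back with :meth:`apply_cohort_delta`.  This
    keeps the cohort loop O(cohorts x bins) while conserving biomass to
    machine precision.
    """

    def __init__(self, realm_log10_range: tuple[float, float], width_log10: float,
                 area_km2: float) -> None:
        lo, hi = realm_log10_range
        n = max(1, int(math.ceil((hi - lo) / width_log10)))
        self.log10_lo = lo
        self.width = width_log10
        self.n_bins = n
        self.area_km2 = area_km2
        self.centers_kg = 10.0 ** (lo + (np.arange(n) + 0.5) * width_log10)
        self.abundance = np.zeros(n)
        self.biomass = np.zeros(n)
        self.biomass_by_trophic = np.zeros((n, 3))
        self.survival = np.ones(n)

    def bin_of(self, mass_kg: float) -> int:
        b = int((math.log10(mass_kg) - self.log10_lo) / self.width)
        return min(max(b, 0), self.n_bins - 1)

    def assign(self, cohorts: list[Cohort]) -> None:
        self.abundance[:] = 0.0
        self.biomass[:] = 0.0
        self.biomass_by_trophic[:] = 0.0
        self.survival[:] = 1.0
        for c in cohorts:
            b = self.bin_of(c.body_mass_kg)
            c._bin = b
            c._thin_seen = 1.0
            bm = c.abundance * c.individual_mass_kg
            self.abundance[b] += c.abundance
            self.biomass[b] += bm
            self.biomass_by_trophic[b, _TROPHIC_INDEX[c.group.feeding_mode]] += bm

    def settle(self, cohort: Cohort) -> None:
        """Apply any pending predation thinning to ``cohort``'s abundance."""
        s = self.survival[cohort._bin]
        if s != cohort._thin_seen:
            cohort.abundance *= s / cohort._thin_seen
            cohort._thin_seen = s

    def apply_cohort_delta(self, cohort: Cohort, old_abundance: float,
                          old_individual_mass: float) -> None:
        """Push a settled cohort's state change into the bin aggregates."""
        b = cohort._bin
        d_n = cohort.abundance - old_abundance
        d_bm = (cohort.abundance * cohort.individual_mass_kg
                - old_abundance * old_individual_mass)
        self.abundance[b] += d_n
        self.biomass[b] += d_bm
        self.biomass_by_trophic[b, _TROPHIC_INDEX[cohort.group.feeding_mode]] += d_bm

    def remove_cohort(self, cohort: Cohort) -> None:
        """Withdraw a settled cohort from the aggregates (death, move, self-exclusion)."""
        b = cohort._bin
        bm = cohort.abundance * cohort.individual_mass_kg
        self.abundance[b] -= cohort.abundance
        self.biomass[b] -= bm
        self.biomass_by_trophic[b, _TROPHIC_INDEX[cohort.group.feeding_mode]] -= bm

    def add_cohort(self, cohort: Cohort) -> None:
        b = cohort._bin
        bm = cohort.abundance * cohort.individual_mass_kg
        self.abundance[b] += cohort.abundance
        self.biomass[b] += bm
        self.biomass_by_trophic[b, _TROPHIC_INDEX[cohort.group.feeding_mode]] += bm

    def thin(self, kills: np.ndarray) -> tuple[float, np.ndarray]:
        """Remove ``kills`` individuals per bin proportionally across cohorts.

        Returns total biomass removed and its split by prey trophic class.
        """
        eaten_by_trophic = np.zeros(3)
        total = 0.0
        for b in np.nonzero(kills)[0]:
            avail = self.abundance[b]
            if avail <= _TINY:
                continue
            frac = min(kills[b] / avail, 1.0)
            removed_bm = self.biomass[b] * frac
            total += removed_bm
            eaten_by_trophic += self.biomass_by_trophic[b] * frac
            keep = 1.0 - frac
            self.abundance[b] *= keep
            self.biomass[b] *= keep
            self.biomass_by_trophic[b] *= keep
            self.survival[b] *= keep
        return total, eaten_by_trophic


def preference_kernel(
    predator_mass_kg: float, prey_masses_kg: np.ndarray, realm: str,
    params: FeedingParams,
) -> np.ndarray:
    """Gaussian prey-preference weights around the optimal prey mass."""
    optimum = params.optimal_prey_mass_ratio(realm) * predator_mass_kg
    z = np.log(prey_masses_kg / optimum) / params.preference_gaussian_width
    w = np.exp(-0.5 * z * z)
    w[w < params.preference_cutoff] = 0.0
    return w


def predation_intake(
    cohort: Cohort,
    bins: PreyBins,
    effective_days: float,
    params: FeedingParams,
    substeps: int,
) -> tuple[float, float, np.ndarray]:
    """Prey on the binned cohort pool over the step.

    The per-predator kill rate on bin ``b`` with abundance density ``D_b``
    is ``a * w_b * D_b^2 / (1 + a * sum_m w_m * h_m * D_m^2)`` (individuals
    per day): Holling Type III in the binned prey density, modulated by the
    Gaussian preference kernel; handling time per prey is linear in prey
    mass and a decreasing power of predator mass.  Kills are expected
    (real-valued) counts, applied with exponential depletion so prey
    abundance never goes negative.  The caller must exclude the predator's
    own cohort from ``bins`` beforehand.

    Returns ``(biomass eaten, individuals killed, biomass eaten per prey
    trophic class)``; assimilation efficiency is applied by the caller.
    """
    m = cohort.body_mass_kg
    n = cohort.abundance
    if n <= 0.0 or effective_days <= 0.0:
        return 0.0, 0.0, np.zeros(3)
    weights = preference_kernel(m, bins.centers_kg, cohort.group.realm, params)
    active = weights > 0.0
    if not np.any(active):
        return 0.0, 0.0, np.zeros(3)
    realm = cohort.group.realm
    attack = params.predator_search_const(realm) * m**params.predator_search_exponent(realm)
    handling_per_mass = params.predator_handling_const * m ** (
        -params.predator_handling_exponent
    )  # day per kg of prey
    total_biomass, total_kills, by_trophic = _predation_kernel(
        bins.abundance, bins.biomass, bins.biomass_by_trophic, bins.survival,
        weights, attack, handling_per_mass, n, bins.area_km2,
        effective_days / substeps, substeps,
    )
    return total_biomass, total_kills, by_trophic


@_njit(cache=True)
def _predation_rates(A, B, w, attack, handling_per_mass, n_pred, area, out):
    """Fractional kill rate of each prey bin (per day)."""
    nb = A.shape[0]
    denom = 1.0
    for b in range(nb):
        if w[b] > 0.0 and A[b] > _TINY:
            d = A[b] / area
            denom += attack * w[b] * d * d * handling_per_mass * (B[b] / A[b])
    for b in range(nb):
        if w[b] <= 0.0 or A[b] <= _TINY:
            out[b] = 0.0
        else:
            d = A[b] / area
            out[b] = n_pred * (attack * w[b] * d * d / denom) / A[b]


@_njit(cache=True)
def _predation_kernel(A, B, Bt, S, w, attack, handling_per_mass, n_pred, area,
                      dt_sub, substeps):
    """Sub-stepped Type III predation with proportional bin thinning.

    Heun-type exponential differencing (rates averaged between the sub-step
    start and a provisional end state) mutates the bin aggregates
    (abundance, biomass, per-trophic biomass, survival product) in place;
    returns the totals eaten.
    """
    nb = A.shape[0]
    total_bm = 0.0
    total_kills = 0.0
    by_tl = np.zeros(3)
    lam1 = np.zeros(nb)
    lam2 = np.zeros(nb)
    trial_a = np.zeros(nb)
    trial_b = np.zeros(nb)
    for _ in range(substeps):
        _predation_rates(A, B, w, attack, handling_per_mass, n_pred, area, lam1)
        for b in range(nb):
            keep = math.exp(-lam1[b] * dt_sub)
            trial_a[b] = A[b] * keep
            trial_b[b] = B[b] * keep
        _predation_rates(trial_a, trial_b, w, attack, handling_per_mass,
                         n_pred, area, lam2)
        for b in range(nb):
            if w[b] <= 0.0 or A[b] <= _TINY:
                continue
            frac = -math.expm1(-min(0.5 * (lam1[b] + lam2[b]) * dt_sub, 27.0))
            total_kills += A[b] * frac
            total_bm += B[b] * frac
            keep = 1.0 - frac
            for t in range(3):
                by_tl[t] += Bt[b, t] * frac
                Bt[b, t] *= keep
            A[b] *= keep
            B[b] *= keep
            S[b] *= keep
    return total_bm, total_kills, by_tl


def omnivory_intake(
    cohort: Cohort,
    stocks: list[Stock],
    bins: PreyBins,
    effective_days: float,
    params: FeedingParams,
    substeps: int,
) -> tuple[float, float, float, np.ndarray]:
    """Combined herbivory and predation for an omnivore cohort.

    The step's feeding time is split by the fixed omnivory time fraction:
    herbivory runs for ``f * effective_days`` and predation for the
    remainder, so each channel reduces to the corresponding pure process
    when the other's resources are absent.  Returns ``(herbivory intake,
    predation intake, kills, predation intake by prey trophic class)``.
    """
    f = params.omnivory_herbivory_time_fraction(cohort.group.realm)
    herb = herbivory_intake(
        cohort, stocks, bins.area_km2, effective_days * f, params, substeps
    )
    pred, kills, by_tl = predation_intake(
        cohort, bins, effective_days * (1.0 - f), params, substeps
    )
    return herb, pred, kills, by_tl


# ---------------------------------------------------------------------------
# metabolism


def metabolic_loss(
    body_mass_kg: float,
    ambient_C: float,
    activity: float,
    endotherm: bool,
    params: MetabolismParams,
    dt_days: float,
) -> float:
    """Biomass lost per individual to metabolism over ``dt_days``.

    Field metabolism is billed while active, basal metabolism while
    inactive; both are mass power laws times the Boltzmann-Arrhenius factor
    at body temperature (310 K for endotherms, ambient for ectotherms),
    converted from energy to biomass.
    """
    if body_mass_kg <= 0:
        raise ValueError("body mass must be > 0")
    t_body = params.endotherm_body_temp_K if endotherm else ambient_C + 273.15
    if t_body <= 0:
        raise ValueError(f"non-positive body temperature in kelvin: {t_body}")
    arrhenius = math.exp(
        -params.activation_energy_eV / (params.boltzmann_eV_per_K * t_body)
    )
    field = params.field_rate_const * body_mass_kg**params.field_mass_exponent
    basal = params.basal_rate_const * body_mass_kg**params.basal_mass_exponent
    rate_kj_day = (activity * field + (1.0 - activity) * basal) * arrhenius
    return rate_kj_day * dt_days / params.energy_per_kg


# ---------------------------------------------------------------------------
# growth and reproduction


@dataclass
class GrowthResult:
    """Per-individual outcome of one growth/reproduction update."""

    metabolic_applied_kg: float  # metabolic loss net of the body-mass floor
    offspring_alloc_per_parent_kg: float
    carcass_per_parent_kg: float  # semelparous post-reproductive body mass
    offspring: OffspringSpec | None
    parent_removed: bool


def apply_growth_and_reproduction(
    cohort: Cohort,
    assimilated_per_ind_kg: float,
    metabolic_per_ind_kg: float,
    repro: ReproductionParams,
    numerics: NumericsParams,
) -> GrowthResult:
    """Apply one step's net biomass flux to a cohort and handle reproduction.

    Immature cohorts put net gain into body mass and mature on first
    reaching adult mass (overshoot seeds the reproductive pool).  Mature
    cohorts accrue net gain to the reproductive pool; net losses come out of
    body mass, never below a small floor above zero.  When the pool reaches
    the threshold fraction of adult mass an offspring cohort is emitted:
    iteroparous parents allocate the full pool; semelparous parents also
    allocate a configured fraction of their body mass and are then removed.
    """
    net = assimilated_per_ind_kg - metabolic_per_ind_kg
    floor = cohort.juvenile_mass_kg * numerics.body_mass_floor_fraction
    met_applied = metabolic_per_ind_kg

    if not cohort.is_mature:
        new_mass = cohort.body_mass_kg + net
        if new_mass < floor:
            met_applied -= floor - new_mass  # the floor absorbed part of the loss
            new_mass = floor
        if new_mass >= cohort.adult_mass_kg:
            cohort.reproductive_pool_kg += new_mass - cohort.adult_mass_kg
            new_mass = cohort.adult_mass_kg
            cohort.is_mature = True
            cohort.steps_to_maturity = cohort.age_steps + 1
            cohort.steps_since_maturity = 0
        cohort.body_mass_kg = new_mass
    else:
        if net >= 0.0:
            # a starved adult first rebuilds body condition back to adult
            # mass; only the surplus is stored as reproductive potential
            deficit = cohort.adult_mass_kg - cohort.body_mass_kg
            if deficit > 0.0:
                rebuild = min(net, deficit)
                cohort.body_mass_kg += rebuild
                net -= rebuild
            cohort.reproductive_pool_kg += net
        else:
            new_mass = cohort.body_mass_kg + net
            if new_mass < floor:
                met_applied -= floor - new_mass
                new_mass = floor
            cohort.body_mass_kg = new_mass
    cohort.max_mass_achieved_kg = max(cohort.max_mass_achieved_kg, cohort.body_mass_kg)

    offspring = None
    alloc = 0.0
    carcass = 0.0
    removed = False
    threshold = repro.mass_threshold_ratio * cohort.adult_mass_kg
    if cohort.is_mature and cohort.reproductive_pool_kg >= threshold and cohort.abundance > 0:
        alloc = cohort.reproductive_pool_kg
        cohort.reproductive_pool_kg = 0.0
        if cohort.group.reproductive_strategy == "semelparity":
            body_alloc = repro.semelparous_adult_mass_fraction * cohort.body_mass_kg
            alloc += body_alloc
            carcass = cohort.body_mass_kg - body_alloc
            removed = True
        n_off = cohort.abundance * alloc / cohort.juvenile_mass_kg
        if n_off < 0:
            raise RuntimeError("negative offspring abundance: accounting bug")
        offspring = OffspringSpec(
            parent_id=cohort.id,
            functional_group=cohort.group,
            abundance=n_off,
            juvenile_mass_kg=cohort.juvenile_mass_kg,
            adult_mass_kg=cohort.adult_mass_kg,
        )
        cohort.offspring_per_capita += alloc / cohort.juvenile_mass_kg
    return GrowthResult(met_applied, alloc, carcass, offspring, removed)


# ---------------------------------------------------------------------------
# non-predation mortality


def nonpredation_mortality_rate(cohort: Cohort, params: MortalityParams) -> float:
    """Total instantaneous non-predation mortality rate (per day)."""
    rate = params.background_rate
    ratio = cohort.body_mass_kg / cohort.max_mass_achieved_kg
    if ratio < 1.0:
        z = (params.starvation_inflection - ratio) / params.starvation_scale
        rate += params.starvation_max_rate / (1.0 + math.exp(-z))
    if cohort.is_mature:
        t_pm = max(cohort.steps_to_maturity or 1, 1)
        rate += params.senescence_rate_at_maturity * math.exp(
            cohort.steps_since_maturity
            / (params.senescence_time_scale * t_pm)
        )
    return rate


def nonpredation_mortality(
    cohort: Cohort, params: MortalityParams, dt_days: float
) -> float:
    """Apply background + starvation + senescence mortality; returns the
    abundance loss.  Survival is exponential in the summed instantaneous
    rate, so abundance stays non-negative and non-increasing."""
    rate = nonpredation_mortality_rate(cohort, params)
    loss = cohort.abundance * -math.expm1(-rate * dt_days)
    cohort.abundance -= loss
    return loss


# ---------------------------------------------------------------------------
# theoretical growth ceiling (used as an emergent-rate bound)


def theoretical_max_growth_rate(
    body_mass_kg: float,
    group: FunctionalGroup,
    ambient_C: float,
    activity: float,
    params: ModelParameters,
) -> float:
    """Upper bound on net growth rate (kg/day) at saturating food density.

    At infinite resource density the Holling intake reaches its
    handling-time ceiling; the bound is the assimilated ceiling (weighted by
    the omnivory time split where both channels operate) minus metabolic
    loss at the given temperature and activity.
    """
    f = params.feeding
    herb_ceiling = body_mass_kg**f.herbivore_handling_exponent / f.herbivore_handling_const
    pred_ceiling = body_mass_kg**f.predator_handling_exponent / f.predator_handling_const
    mode = group.feeding_mode
    if mode == "herbivore":
        intake = group.herbivory_assimilation * herb_ceiling
    elif mode == "carnivore":
        intake = group.carnivory_assimilation * pred_ceiling
    else:
        t = f.omnivory_herbivory_time_fraction(group.realm)
        intake = (t * group.herbivory_assimilation * herb_ceiling
                  + (1.0 - t) * group.carnivory_assimilation * pred_ceiling)
    met = metabolic_loss(
        body_mass_kg, ambient_C, activity,
        group.thermoregulation == "endotherm", params.metabolism, 1.0,
    )
    return activity * intake - met
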