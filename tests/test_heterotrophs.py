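"""Feeding, metabolism, growth/reproduction and mortality processes.

The feeding tests check the engine's sub-stepped exponential-depletion
discretisation against an independent fine-grained (10^4 sub-step) explicit
Euler integration of the same instantaneous rates.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gemsim.core_state import Cohort, Stock
from gemsim.forcing import SyntheticForcingSpec, archetype_spec, generate_synthetic_forcing
from gemsim.heterotrophs import (
    PreyBins,
    activity_fraction,
    apply_growth_and_reproduction,
    herbivory_intake,
    metabolic_loss,
    nonpredation_mortality,
    nonpredation_mortality_rate,
    omnivory_intake,
    predation_intake,
    preference_kernel,
    theoretical_max_growth_rate,
)
from gemsim.params import ModelParameters

AREA = 1.0e4  # km^2, a ~1-degree equatorial cell
TERR_RANGE = (-6.4, 3.7)


@pytest.fixture()
def feeding(params):
    return params.feeding


def _group(groups, realm, mode, thermo=None, strategy=None):
    for g in groups:
        if g.realm != realm or g.feeding_mode != mode:
            continue
        if thermo and g.thermoregulation != thermo:
            continue
        if strategy and g.reproductive_strategy != strategy:
            continue
        return g
    raise LookupError((realm, mode, thermo, strategy))


# ---------------------------------------------------------------------------
# activity windows


class TestActivityFraction:
    def test_endotherm_always_fully_active(self, groups, params):
        g = _group(groups, "terrestrial", "herbivore", thermo="endotherm")
        forcing = generate_synthetic_forcing(
            archetype_spec("terrestrial_temperate_seasonal")
        )
        for month in range(12):
            assert activity_fraction(g, forcing, month, params.metabolism) == 1.0

    def test_marine_ectotherm_always_fully_active(self, groups, params):
        g = _group(groups, "marine", "herbivore", thermo="ectotherm")
        forcing = generate_synthetic_forcing(
            archetype_spec("marine_high_productivity_seasonal")
        )
        for month in range(12):
            assert activity_fraction(g, forcing, month, params.metabolism) == 1.0

    def test_terrestrial_ectotherm_frozen_month_is_inactive(self, groups, params):
        g = _group(groups, "terrestrial", "herbivore", thermo="ectotherm")
        # month far below the lower activity limit
        forcing = generate_synthetic_forcing(SyntheticForcingSpec(
            realm="terrestrial", annual_mean_npp_gC_m2_month=10.0,
            mean_temperature_C=5.0, temperature_seasonal_amplitude_C=60.0,
        ))
        coldest = int(np.argmin(forcing.temperature_C))
        assert activity_fraction(g, forcing, coldest, params.metabolism) == 0.0

    def test_activity_bounded_and_warmer_months_not_less_active(self, groups, params):
        g = _group(groups, "terrestrial", "omnivore", thermo="ectotherm")
        forcing = generate_synthetic_forcing(
            archetype_spec("terrestrial_temperate_seasonal")
        )
        acts = [activity_fraction(g, forcing, m, params.metabolism) for m in range(12)]
        assert all(0.0 <= a <= 1.0 for a in acts)


# ---------------------------------------------------------------------------
# herbivory


def euler_herbivory(stock_biomass, mass, abundance, days, feeding, realm, nsub=10_000):
    """Independent fine-grained integration of the grazing rate with depletion."""
    a = feeding.herbivore_search_rate_per_mass(realm) * mass
    h = feeding.herbivore_handling_const * mass**-feeding.herbivore_handling_exponent
    phi = feeding.stock_fraction_experienced(realm)
    b = stock_biomass
    total = 0.0
    dt = days / nsub
    for _ in range(nsub):
        d = phi * b / AREA
        rate = a * d * d / (1.0 + a * h * d * d)
        eat = min(abundance * rate * dt, b)
        b -= eat
        total += eat
    return total, b


class TestHerbivory:
    def test_no_resource_means_no_intake(self, groups, feeding):
        g = _group(groups, "terrestrial", "herbivore")
        c = Cohort(g, 0.1, 1.0, 100.0, body_mass_kg=0.5)
        stock = Stock("terrestrial_deciduous", 0.0, "deciduous")
        assert herbivory_intake(c, [stock], AREA, 30.0, feeding, 8) == 0.0

    def test_saturation_approaches_handling_ceiling(self, groups, feeding):
        """At enormous stock biomass, per-individual intake approaches the
        handling-limited ceiling for the step."""
        g = _group(groups, "terrestrial", "herbivore")
        mass = 1.0
        c = Cohort(g, 0.1, 2.0, 1.0, body_mass_kg=mass)
        stock = Stock("terrestrial_deciduous", 1.0e16, "deciduous")
        intake = herbivory_intake(c, [stock], AREA, 30.0, feeding, 8)
        ceiling = 30.0 * mass**feeding.herbivore_handling_exponent \
            / feeding.herbivore_handling_const
        assert intake == pytest.approx(ceiling, rel=1e-3)
        assert intake <= ceiling * (1 + 1e-12)

    def test_intake_monotone_in_stock_density(self, groups, feeding):
        g = _group(groups, "terrestrial", "herbivore")
        intakes = []
        for b0 in (1.0e7, 1.0e8, 1.0e9, 1.0e10):
            c = Cohort(g, 0.1, 2.0, 1.0e3, body_mass_kg=1.0)
            stock = Stock("terrestrial_deciduous", b0, "deciduous")
            intakes.append(herbivory_intake(c, [stock], AREA, 30.0, feeding, 8))
        assert all(x < y for x, y in zip(intakes, intakes[1:]))

    @pytest.mark.parametrize(
        "mass,abundance,b0",
        [
            (10.0, 5.0e6, 5.0e9),   # strong depletion
            (0.01, 1.0e9, 2.0e9),
            (100.0, 1.0e4, 1.0e10),  # light grazing
        ],
    )
    def test_step_matches_fine_grained_integration(self, groups, feeding, mass,
                                                   abundance, b0):
        g = _group(groups, "terrestrial", "herbivore")
        c = Cohort(g, mass / 10, mass * 2, abundance, body_mass_kg=mass)
        stock = Stock("terrestrial_deciduous", b0, "deciduous")
        got = herbivory_intake(c, [stock], AREA, 30.0, feeding, 8)
        expected, b_end = euler_herbivory(b0, mass, abundance, 30.0, feeding,
                                          "terrestrial")
        assert got == pytest.approx(expected, rel=1e-3)
        assert stock.total_biomass_kg == pytest.approx(b_end, rel=1e-3)
        assert stock.total_biomass_kg >= 0.0


# ---------------------------------------------------------------------------
# predation


def euler_predation(prey, predator_mass, predator_abundance, days, feeding,
                    realm="terrestrial", nsub=10_000):
    """Fine-grained integration of the binned Type III kill rates."""
    bins = PreyBins(TERR_RANGE, feeding.prey_bin_width_log10, AREA)
    a_bins = np.zeros(bins.n_bins)
    b_bins = np.zeros(bins.n_bins)
    for n, m in prey:
        b = bins.bin_of(m)
        a_bins[b] += n
        b_bins[b] += n * m
    w = preference_kernel(predator_mass, bins.centers_kg, realm, feeding)
    attack = feeding.predator_search_const(realm) \
        * predator_mass**feeding.predator_search_exponent(realm)
    hpm = feeding.predator_handling_const \
        * predator_mass**-feeding.predator_handling_exponent
    total = 0.0
    kills_total = 0.0
    dt = days / nsub
    for _ in range(nsub):
        denom = 1.0
        for b in range(bins.n_bins):
            if w[b] > 0 and a_bins[b] > 0:
                d = a_bins[b] / AREA
                denom += attack * w[b] * d * d * hpm * (b_bins[b] / a_bins[b])
        for b in range(bins.n_bins):
            if w[b] <= 0 or a_bins[b] <= 0:
                continue
            d = a_bins[b] / AREA
            rate = attack * w[b] * d * d / denom
            kills = min(predator_abundance * rate * dt, a_bins[b])
            frac = kills / a_bins[b]
            total += b_bins[b] * frac
            kills_total += kills
            b_bins[b] -= b_bins[b] * frac
            a_bins[b] -= kills
    return total, kills_total


def _binned_cohorts(groups, prey):
    g = _group(groups, "terrestrial", "herbivore")
    return [Cohort(g, m / 10, m * 4, n, body_mass_kg=m) for n, m in prey]


class TestPredation:
    def test_no_prey_gives_zero_intake(self, groups, feeding):
        bins = PreyBins(TERR_RANGE, feeding.prey_bin_width_log10, AREA)
        bins.assign([])
        pred = Cohort(_group(groups, "terrestrial", "carnivore"), 1.0, 20.0,
                      1.0e3, body_mass_kg=10.0)
        intake, kills, by_tl = predation_intake(pred, bins, 30.0, feeding, 8)
        assert intake == 0.0 and kills == 0.0

    def test_kernel_prefers_optimal_prey_mass(self, groups, feeding):
        """Two identical prey pools, one at the optimal mass ratio and one
        three kernel widths away: the optimal pool suffers more kills."""
        pred_mass = 10.0
        optimum = feeding.optimal_prey_mass_ratio("terrestrial") * pred_mass
        off = optimum * math.exp(3.0 * feeding.preference_gaussian_width)
        prey = [(1.0e6, optimum), (1.0e6, off)]
        bins = PreyBins(TERR_RANGE, feeding.prey_bin_width_log10, AREA)
        cohorts = _binned_cohorts(groups, prey)
        bins.assign(cohorts)
        a_before = bins.abundance.copy()
        pred = Cohort(_group(groups, "terrestrial", "carnivore"), 1.0, 20.0,
                      1.0e4, body_mass_kg=pred_mass)
        predation_intake(pred, bins, 30.0, feeding, 8)
        killed = a_before - bins.abundance
        assert killed[bins.bin_of(optimum)] > killed[bins.bin_of(off)]

    @pytest.mark.parametrize(
        "prey,pred_mass,pred_n",
        [
            ([(2.0e6, 0.5), (4.0e6, 0.15)], 10.0, 2.0e4),
            ([(5.0e7, 0.02), (1.0e6, 0.5)], 3.0, 5.0e5),   # heavy depletion
        ],
    )
    def test_step_kills_match_fine_grained_integration(self, groups, feeding,
                                                       prey, pred_mass, pred_n):
        bins = PreyBins(TERR_RANGE, feeding.prey_bin_width_log10, AREA)
        cohorts = _binned_cohorts(groups, prey)
        bins.assign(cohorts)
        pred = Cohort(_group(groups, "terrestrial", "carnivore"), 1.0, 20.0,
                      pred_n, body_mass_kg=pred_mass)
        got, kills, _ = predation_intake(pred, bins, 30.0, feeding, 8)
        expected, exp_kills = euler_predation(prey, pred_mass, pred_n, 30.0, feeding)
        assert got == pytest.approx(expected, rel=1e-3)
        assert kills == pytest.approx(exp_kills, rel=1e-3)

    def test_prey_abundance_never_negative_under_extreme_pressure(self, groups, feeding):
        prey = [(100.0, 0.5)]
        bins = PreyBins(TERR_RANGE, feeding.prey_bin_width_log10, AREA)
        cohorts = _binned_cohorts(groups, prey)
        bins.assign(cohorts)
        pred = Cohort(_group(groups, "terrestrial", "carnivore"), 1.0, 20.0,
                      1.0e12, body_mass_kg=10.0)
        predation_intake(pred, bins, 30.0, feeding, 8)
        for c in cohorts:
            bins.settle(c)
            assert c.abundance >= 0.0


class TestOmnivory:
    def _setup(self, groups, feeding, with_stock, with_prey):
        stock = Stock(
            "terrestrial_deciduous", 5.0e9 if with_stock else 0.0, "deciduous"
        )
        prey = [(2.0e6, 0.05)] if with_prey else []
        bins = PreyBins(TERR_RANGE, feeding.prey_bin_width_log10, AREA)
        bins.assign(_binned_cohorts(groups, prey))
        omn = Cohort(_group(groups, "terrestrial", "omnivore"), 0.1, 5.0,
                     1.0e4, body_mass_kg=1.0)
        return omn, stock, bins

    def test_reduces_to_time_weighted_herbivory_without_prey(self, groups, feeding):
        omn, stock, bins = self._setup(groups, feeding, True, False)
        herb, pred, _, _ = omnivory_intake(omn, [stock], bins, 30.0, feeding, 8)
        assert pred == 0.0
        twin = Cohort(omn.group, 0.1, 5.0, 1.0e4, body_mass_kg=1.0)
        stock2 = Stock("terrestrial_deciduous", 5.0e9, "deciduous")
        expected = herbivory_intake(
            twin, [stock2], AREA, 30.0 * feeding.omnivory_herbivory_time_fraction("terrestrial"),
            feeding, 8,
        )
        assert herb == pytest.approx(expected, rel=1e-12)

    def test_reduces_to_time_weighted_predation_without_stocks(self, groups, feeding):
        omn, _, bins = self._setup(groups, feeding, False, True)
        herb, pred, _, _ = omnivory_intake(omn, [], bins, 30.0, feeding, 8)
        assert herb == 0.0
        bins2 = PreyBins(TERR_RANGE, feeding.prey_bin_width_log10, AREA)
        bins2.assign(_binned_cohorts(groups, [(2.0e6, 0.05)]))
        twin = Cohort(omn.group, 0.1, 5.0, 1.0e4, body_mass_kg=1.0)
        expected, _, _ = predation_intake(
            twin, bins2, 30.0 * (1 - feeding.omnivory_herbivory_time_fraction("terrestrial")),
            feeding, 8,
        )
        assert pred == pytest.approx(expected, rel=1e-12)

    def test_both_channels_sum_of_independent_intakes(self, groups, feeding):
        omn, stock, bins = self._setup(groups, feeding, True, True)
        herb, pred, _, _ = omnivory_intake(omn, [stock], bins, 30.0, feeding, 8)
        assert herb > 0 and pred > 0
        # independent recomputation channel by channel
        stock2 = Stock("terrestrial_deciduous", 5.0e9, "deciduous")
        twin = Cohort(omn.group, 0.1, 5.0, 1.0e4, body_mass_kg=1.0)
        h_only = herbivory_intake(
            twin, [stock2], AREA, 30.0 * feeding.omnivory_herbivory_time_fraction("terrestrial"),
            feeding, 8,
        )
        bins2 = PreyBins(TERR_RANGE, feeding.prey_bin_width_log10, AREA)
        bins2.assign(_binned_cohorts(groups, [(2.0e6, 0.05)]))
        p_only, _, _ = predation_intake(
            twin, bins2, 30.0 * (1 - feeding.omnivory_herbivory_time_fraction("terrestrial")),
            feeding, 8,
        )
        assert herb + pred == pytest.approx(h_only + p_only, rel=1e-12)


# ---------------------------------------------------------------------------
# metabolism


class TestMetabolism:
    def test_endotherm_mass_ratio_follows_field_exponent(self, params):
        p = params.metabolism
        l1 = metabolic_loss(2.0, 25.0, 1.0, True, p, 30.0)
        l2 = metabolic_loss(0.5, 25.0, 1.0, True, p, 30.0)
        assert l1 / l2 == pytest.approx(4.0**p.field_mass_exponent, rel=1e-12)

    def test_ectotherm_temperature_ratio_is_arrhenius(self, params):
        p = params.metabolism
        t1, t2 = 10.0, 25.0
        l1 = metabolic_loss(1.0, t1, 1.0, False, p, 30.0)
        l2 = metabolic_loss(1.0, t2, 1.0, False, p, 30.0)
        expected = math.exp(
            -p.activation_energy_eV / p.boltzmann_eV_per_K
            * (1.0 / (t1 + 273.15) - 1.0 / (t2 + 273.15))
        )
        assert l1 / l2 == pytest.approx(expected, rel=1e-12)

    def test_mixed_activity_is_weighted_field_basal_sum(self, params):
        p = params.metabolism
        mass, temp, act = 3.0, 18.0, 0.5
        arr = math.exp(
            -p.activation_energy_eV / (p.boltzmann_eV_per_K * (temp + 273.15))
        )
        expected = (
            (act * p.field_rate_const * mass**p.field_mass_exponent
             + (1 - act) * p.basal_rate_const * mass**p.basal_mass_exponent)
            * arr * 30.0 / p.energy_per_kg
        )
        got = metabolic_loss(mass, temp, act, False, p, 30.0)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_endotherm_uses_fixed_body_temperature(self, params):
        p = params.metabolism
        assert metabolic_loss(1.0, -20.0, 1.0, True, p, 30.0) == pytest.approx(
            metabolic_loss(1.0, 35.0, 1.0, True, p, 30.0), rel=1e-12
        )

    def test_nonpositive_kelvin_rejected(self, params):
        with pytest.raises(ValueError, match="kelvin"):
            metabolic_loss(1.0, -300.0, 1.0, False, params.metabolism, 30.0)

    @given(
        m1=st.floats(1e-6, 1e4), factor=st.floats(1.1, 10.0),
        temp=st.floats(-5.0, 35.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_loss_strictly_increasing_in_mass(self, m1, factor, temp):
        p = ModelParameters().metabolism
        assert metabolic_loss(m1 * factor, temp, 1.0, False, p, 30.0) > \
            metabolic_loss(m1, temp, 1.0, False, p, 30.0)

    @given(t=st.floats(0.0, 30.0), dt=st.floats(1.0, 9.0))
    @settings(max_examples=60, deadline=None)
    def test_ectotherm_loss_increasing_in_temperature(self, t, dt):
        p = ModelParameters().metabolism
        assert metabolic_loss(1.0, t + dt, 1.0, False, p, 30.0) > \
            metabolic_loss(1.0, t, 1.0, False, p, 30.0)


# ---------------------------------------------------------------------------
# growth and reproduction


class TestGrowthAndReproduction:
    def test_immature_net_gain_goes_to_body_mass(self, groups, params):
        g = _group(groups, "terrestrial", "herbivore")
        c = Cohort(g, 0.1, 10.0, 50.0, body_mass_kg=1.0)
        res = apply_growth_and_reproduction(
            c, 0.4, 0.1, params.reproduction, params.numerics
        )
        assert c.body_mass_kg == pytest.approx(1.3)
        assert c.reproductive_pool_kg == 0.0
        assert res.offspring is None

    def test_maturation_records_time_and_caps_body_mass(self, groups, params):
        g = _group(groups, "terrestrial", "herbivore")
        c = Cohort(g, 0.1, 1.0, 50.0, body_mass_kg=0.95)
        c.age_steps = 7
        apply_growth_and_reproduction(c, 0.2, 0.05, params.reproduction, params.numerics)
        assert c.is_mature
        assert c.steps_to_maturity == 8
        assert c.body_mass_kg == pytest.approx(1.0)
        assert c.reproductive_pool_kg == pytest.approx(0.1)

    def test_pool_below_threshold_no_event(self, groups, params):
        g = _group(groups, "terrestrial", "herbivore", strategy="iteroparity")
        c = Cohort(g, 0.1, 1.0, 100.0, body_mass_kg=1.0)
        c.reproductive_pool_kg = params.reproduction.mass_threshold_ratio * 1.0 - 1e-6
        res = apply_growth_and_reproduction(
            c, 0.0, 0.0, params.reproduction, params.numerics
        )
        assert res.offspring is None

    def test_iteroparous_event_conserves_biomass(self, groups, params):
        """Adult 1 kg, juvenile 0.1 kg, pool crosses at 0.5 kg, N=100:
        offspring abundance 500 and total biomass unchanged."""
        g = _group(groups, "terrestrial", "herbivore", strategy="iteroparity")
        c = Cohort(g, 0.1, 1.0, 100.0, body_mass_kg=1.0)
        c.reproductive_pool_kg = 0.3
        before = c.total_biomass_kg + 0.2 * c.abundance  # incoming net gain
        res = apply_growth_and_reproduction(
            c, 0.2, 0.0, params.reproduction, params.numerics
        )
        assert res.offspring is not None
        assert res.offspring.abundance == pytest.approx(500.0)
        assert c.reproductive_pool_kg == 0.0
        offspring_biomass = res.offspring.abundance * 0.1
        assert c.total_biomass_kg + offspring_biomass == pytest.approx(before)

    def test_semelparous_parent_removed_and_mass_partitioned(self, groups, params):
        g = _group(groups, "terrestrial", "herbivore", strategy="semelparity")
        c = Cohort(g, 0.001, 0.5, 1000.0, body_mass_kg=0.5)
        c.reproductive_pool_kg = 0.2
        res = apply_growth_and_reproduction(
            c, 0.0, 0.0, params.reproduction, params.numerics
        )
        frac = params.reproduction.semelparous_adult_mass_fraction
        assert res.parent_removed
        expected_alloc = 0.2 + frac * 0.5
        assert res.offspring_alloc_per_parent_kg == pytest.approx(expected_alloc)
        assert res.carcass_per_parent_kg == pytest.approx((1 - frac) * 0.5)
        assert res.offspring.abundance == pytest.approx(1000.0 * expected_alloc / 0.001)

    def test_mature_net_loss_reduces_body_mass_not_pool(self, groups, params):
        g = _group(groups, "terrestrial", "herbivore")
        c = Cohort(g, 0.1, 1.0, 10.0, body_mass_kg=1.0)
        apply_growth_and_reproduction(c, 0.0, 0.2, params.reproduction, params.numerics)
        assert c.body_mass_kg == pytest.approx(0.8)
        assert c.max_mass_achieved_kg == pytest.approx(1.0)

    def test_body_mass_floor_holds_under_extreme_starvation(self, groups, params):
        g = _group(groups, "terrestrial", "herbivore")
        c = Cohort(g, 0.1, 1.0, 10.0, body_mass_kg=0.11)
        res = apply_growth_and_reproduction(
            c, 0.0, 5.0, params.reproduction, params.numerics
        )
        floor = 0.1 * params.numerics.body_mass_floor_fraction
        assert c.body_mass_kg == pytest.approx(floor)
        assert res.metabolic_applied_kg == pytest.approx(0.11 - floor)


# ---------------------------------------------------------------------------
# non-predation mortality


class TestNonPredationMortality:
    def test_immature_at_full_mass_suffers_background_only(self, groups, params):
        g = _group(groups, "terrestrial", "herbivore")
        c = Cohort(g, 0.1, 1.0, 100.0, body_mass_kg=0.5)
        c.max_mass_achieved_kg = 0.5
        rate = nonpredation_mortality_rate(c, params.mortality)
        assert rate == pytest.approx(params.mortality.background_rate)

    def test_senescence_equals_base_rate_at_maturity(self, groups, params):
        g = _group(groups, "terrestrial", "herbivore")
        c = Cohort(g, 0.1, 1.0, 100.0, body_mass_kg=1.0)
        c.steps_to_maturity = 10
        c.steps_since_maturity = 0
        rate = nonpredation_mortality_rate(c, params.mortality)
        assert rate == pytest.approx(
            params.mortality.background_rate
            + params.mortality.senescence_rate_at_maturity
        )

    def test_senescence_grows_with_time_since_maturity(self, groups, params):
        g = _group(groups, "terrestrial", "herbivore")
        rates = []
        for since in (0, 10, 30):
            c = Cohort(g, 0.1, 1.0, 100.0, body_mass_kg=1.0)
            c.steps_to_maturity = 10
            c.steps_since_maturity = since
            rates.append(nonpredation_mortality_rate(c, params.mortality))
        assert rates[0] < rates[1] < rates[2]

    def test_starvation_saturates_at_max_rate(self, groups, params):
        g = _group(groups, "terrestrial", "herbivore")
        c = Cohort(g, 0.1, 1.0, 100.0, body_mass_kg=0.5)
        c.max_mass_achieved_kg = 1.0e6  # body mass << maximum ever achieved
        c.body_mass_kg = 1.0e-3
        rate = nonpredation_mortality_rate(c, params.mortality)
        assert rate == pytest.approx(
            params.mortality.background_rate + params.mortality.starvation_max_rate,
            rel=1e-4,
        )
        assert rate <= (params.mortality.background_rate
                        + params.mortality.starvation_max_rate)

    @given(
        n0=st.floats(1.0, 1e9), ratio=st.floats(0.01, 1.0),
        dt=st.floats(1.0, 30.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_abundance_nonnegative_and_nonincreasing(self, n0, ratio, dt):
        params = ModelParameters()
        groups = __import__("gemsim").default_functional_groups()
        g = _group(groups, "terrestrial", "herbivore")
        c = Cohort(g, 0.1, 1.0, n0, body_mass_kg=max(ratio, 0.1))
        c.max_mass_achieved_kg = 1.0
        loss = nonpredation_mortality(c, params.mortality, dt)
        assert loss >= 0.0
        assert 0.0 <= c.abundance <= n0


# ---------------------------------------------------------------------------
# theoretical growth ceiling


class TestTheoreticalMaxGrowth:
    def test_bound_decomposes_into_intake_minus_metabolism(self, groups, params):
        g = _group(groups, "terrestrial", "herbivore", thermo="endotherm")
        mass = 10.0
        f = params.feeding
        ceiling = mass**f.herbivore_handling_exponent / f.herbivore_handling_const
        met = metabolic_loss(mass, 25.0, 1.0, True, params.metabolism, 1.0)
        expected = g.herbivory_assimilation * ceiling - met
        assert theoretical_max_growth_rate(mass, g, 25.0, 1.0, params) == \
            pytest.approx(expected, rel=1e-12)

    def test_saturated_feeding_never_exceeds_bound(self, groups, params):
        """A cohort feeding on an effectively unlimited stock grows no faster
        than the closed-form ceiling."""
        g = _group(groups, "terrestrial", "herbivore", thermo="endotherm")
        mass = 1.0
        c = Cohort(g, 0.5, 50.0, 1.0, body_mass_kg=mass)
        stock = Stock("terrestrial_deciduous", 1.0e18, "deciduous")
        intake = herbivory_intake(c, [stock], AREA, 30.0, params.feeding, 8)
        met = metabolic_loss(mass, 25.0, 1.0, True, params.metabolism, 30.0)
        growth = (g.herbivory_assimilation * intake - met) / 30.0
        assert growth <= theoretical_max_growth_rate(mass, g, 25.0, 1.0, params) \
            * (1 + 1e-9)
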