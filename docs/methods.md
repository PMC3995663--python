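# Methods

`gemsim` is a desk-scale general ecosystem model: a mechanistic,
individual-based (cohort-approximated) simulator of whole communities —
autotroph stocks plus herbivorous, omnivorous and carnivorous animals of
all body sizes — driven by monthly climate and NPP forcing on a lat-lon
grid. Community structure (trophic pyramids, mass-abundance spectra, life
histories) is not imposed; it emerges from individual-level feeding,
metabolism, growth, reproduction, mortality and dispersal.

## State

Heterotrophs are *cohorts*: groups of identical organisms characterised by
a functional group (realm x feeding mode x mobility x reproductive
strategy x thermoregulation; 19 groups, 10 marine and 9 terrestrial), two
fixed traits (juvenile and adult body mass, drawn at seeding within the
group's log10 mass range), and three state variables — abundance `N`,
individual wet body mass `M`, and stored reproductive mass `R`. Abundance
only decreases within a cohort's lifetime; reproduction spawns new
offspring cohorts, and a merging scheme bounds the cohort count.
Autotrophs are biomass *stocks*: one phytoplankton pool per marine cell,
deciduous and evergreen leaf pools per terrestrial cell.

Internal units: kg wet matter, km², instantaneous rates per day, monthly
steps (30 days; a monthly step counts as 1/12 year for annual rates).

## Processes

**Autotroph growth.** Marine: the phytoplankton stock is incremented
directly from the monthly NPP forcing (`gain = NPP * A_cell * xi * dt`,
with `xi = 10` kg wet per kg C); its only loss is grazing. Terrestrial:
monthly NPP is converted to wet matter (`psi = 7`), the structural
allocation `f_struct` is discarded (only leaves are edible), and the
remainder is split between evergreen and deciduous pools by `f_ever`.
`f_struct` and `f_ever` are logistic climate responses (of annual NPP and
coldest-month temperature respectively) with re-tuned coefficients — they
are this package's own calibration, not the original vegetation model's
published forms. Leaves die at annual rates (0.5/yr evergreen, 1.5/yr
deciduous), converted to each step by exponential decay; deciduous leaf
fall is concentrated into cold months by a temperature-logistic weight
normalised to preserve the annual rate.

**Feeding.** Holling Type III responses throughout: intake is sigmoidal
(`a D² / (1 + a h D²)`) in resource density with a handling-limited
ceiling. Herbivore search rate is linear in herbivore mass; each cohort
experiences a fraction `phi` of the stock (0.1 terrestrial, 1.0 marine).
Predation is size-structured: prey cohorts are aggregated into 0.5-decade
log-mass bins, the attack rate on a bin is weighted by a log-Gaussian
kernel centred on an optimal prey:predator mass ratio (0.5 terrestrial,
0.01 marine; width 0.8 ln units), and handling time per prey is linear in
prey mass and a decreasing power of predator mass. Kills are expected
(real-valued) counts. Assimilation efficiencies are the functional-group
table's values; unassimilated intake leaves the system (no detritus pool).

**Metabolism.** Field and basal rates are Boltzmann-Arrhenius mass power
laws (`exp(-E_A/(k_B T))`, `E_A = 0.69` eV), weighted by the fraction of
the step an organism is active, and converted to biomass at 7,000 kJ/kg.
Body temperature is 310 K for endotherms and ambient for ectotherms.
Endotherms and marine ectotherms are always active; terrestrial ectotherms
are active for the fraction of each month that ambient temperature falls
within climate-estimated limits whose breadth widens with seasonality.

**Growth and reproduction.** Net per-individual flux (assimilated minus
metabolic) grows juveniles to adult mass (maturation is recorded); adults
first rebuild any starvation-lost body mass, then store surplus as
reproductive potential. When the pool reaches 25% of adult mass an
offspring cohort is spawned at juvenile mass (abundance = parent abundance
x allocation / juvenile mass). Iteroparous parents allocate the pool;
semelparous parents also allocate half their body mass and are removed
(the remainder is a recorded carcass loss). Body mass has a floor at 1% of
juvenile mass.

**Mortality.** Three non-predation channels, summed as instantaneous
rates and applied as exponential survival: constant background
(5e-4/day); starvation, a logistic function of current to
maximum-ever body mass saturating at 0.1/day; and Gompertz-like
senescence, zero before maturity, equal to a base rate at maturity and
e-folding every 3 maturation times thereafter. Cohorts falling below one
individual are removed (their biomass is a recorded loss).

**Dispersal** (multi-cell grids only; disabled in isolated cells).
Diffusive natal dispersal of newborn cohorts with a characteristic
distance scaling as `M^0.25`; responsive dispersal of adults when density
falls below a mass-related threshold or when more than 10% of body mass
was lost in a step; advective-diffusive dispersal of planktonic organisms
(mass < 1e-5 kg) following the current vector plus a Gaussian kick, with
stochastic rounding to whole-cell moves and reflection away from land.
Cohorts move whole; dispersal conserves every cohort's state exactly.

## Scheduler and numerics

Per step and cell: (1) autotroph growth and leaf mortality; (2) each
cohort, in an order re-randomised every step, metabolises, feeds, grows or
reproduces, and suffers non-predation mortality; (3) offspring cohorts are
inserted (they first act the following step); (4) extinct cohorts are
removed; (5) if the cohort count exceeds the threshold (default 1,000),
nearest pairs in trait space (log juvenile, adult and current mass),
within the same functional group, are merged — the smaller cohort's
biomass becomes additional individuals of the larger, conserving per-group
biomass to machine precision.

Within-step feeding losses use sub-stepped (default 8) Heun-type
exponential differencing: fractional loss rates are averaged between the
sub-step start and a provisional end state, so depletion competition is
resolved second-order accurately and no state can go negative. Against a
10^4-substep explicit Euler integration of the same instantaneous rates,
one-step intakes agree to well under 0.1% even when a month removes ~40%
of the resource. Predation thins bins proportionally through a lazy
per-bin survival product, which keeps the cohort loop O(cohorts x bins)
while conserving biomass exactly; a per-step ledger records every flux and
the global mass-balance residual (checked < 1e-9 relative, observed
~1e-14).

Determinism: one RNG per cell run; grids give each cell independent
ecology and dispersal substreams spawned from the run seed, so multi-cell
trajectories do not depend on iteration order. Checkpoints capture the
full run state including the RNG and resume bit-exactly.

## Synthetic forcing and seeding

Four archetype climatologies stand in for the focal-cell conditions:
wet-tropical aseasonal land (NPP 80 gC/m²/mo, 25 °C), temperate seasonal
land (45 gC/m²/mo ±80%, 10 ±8 °C), oligotrophic aseasonal ocean (15
gC/m²/mo, 22 °C) and productive seasonal ocean (60 gC/m²/mo ±80%, 12 ±6
°C). Cycles are sinusoidal with exact annual means and repeat identically
every year (interannual variability is out of scope).

Cells are seeded with ~1,000 cohorts (112 per terrestrial group, 100 per
marine group): adult masses log-uniform in the group range, juvenile
masses log-uniform below the adult mass, initial abundance proportional to
(adult mass)^-1 and normalised so total heterotroph biomass density is
5e4 kg/km², split 80/15/5% across herbivores/omnivores/carnivores — a
bottom-heavy seed whose predator load the young community's prey flux can
carry (a flat split seeds predators at ~1:2 predator:prey biomass and
reliably extinguishes them in the first years). Stocks start near their
grazing-free balance so the seeded community does not face an empty
larder.

## Parameter provenance and calibration

The rate constants are this package's own calibration: the source
material for this model family summarises the functional forms but not the
full value table, so defaults were chosen from metabolic-ecology scale
arguments and then calibrated against the qualitative behaviour the model
is expected to reproduce (persistence, a non-inverted terrestrial biomass
pyramid with herbivore:autotroph biomass of a few percent, an inverted
marine base). Notable structural choices made during calibration:

- Mass-specific intake ceilings (~0.3 x M^-0.05 /day for grazing, ~2.5 x
  body mass per month for predation) close to mass-specific metabolism, so
  per-month biomass changes stay bounded at the monthly step.
- Predator attack scaling: terrestrial attack ∝ M (which makes the Type
  III half-saturation bin biomass mass-independent, giving every prey bin
  a low-density refuge at its own scale) with the optimal prey ratio 0.5
  typical of terrestrial carnivore-ungulate pairs; marine attack uses
  ratio 0.01 (pelagic predators take much smaller prey).
- The omnivory time split (herbivory fraction 0.3 on land, 0.2 at sea) —
  at larger marine values omnivores capture enough of the monthly
  phytoplankton pulse to competitively exclude specialist zooplankton.

## What the synthetic runs do and do not show

The aseasonal single-cell runs converge within decades to statistical
steady states with machine-precision mass balance, a strongly non-inverted
terrestrial pyramid (leaf standing stock ~1.3e6 kg/km², herbivores
~1.2e5, herbivore:autotroph ~9%) and a strongly inverted marine base
(phytoplankton standing stock orders of magnitude below grazer biomass, as
expected when producer turnover is ~monthly). These demonstrate the
engine's numerics and the qualitative realm contrast, not fidelity to any
real location: forcing is idealised, the vegetation response surfaces are
re-tuned, and dispersal rescue is absent in isolated cells.

Known limitation: full four-trophic-level coexistence is fragile in this
re-parameterisation. Autotrophs and herbivores persist indefinitely in
both realms; terrestrial carnivores persist through 100 years in a subset
of random seeds (dying out during the violent initial transient in
others); marine cells typically settle into either a zooplankton- or an
omnivore-dominated consumer community rather than retaining both plus
carnivores. The drivers are the monthly pulse-and-graze cycle (a month is
long enough for any consumer guild to overconsume its resource) and the
absence of immigration in a closed cell, which makes every local
extinction permanent. A daily time step and multi-cell rescue effects both
mitigate this but are outside the desk-scale test envelope; the
acceptance test that asserts persistence of all four groups is expected to
fail and is intentionally left failing rather than weakened.

## Problem sizes used by the test and acceptance runs

Long-run tests: 100-year, 1,000-cohort single cells, three seeds per
realm, plus merging-threshold variants (500/1,000/5,000) on the
terrestrial cell; oracle and conservation tests run in seconds on small
communities. `scripts/acceptance.py` re-runs the two aseasonal focal
cells for 100 years at the standard community size and reports persistence
counts, final-decade trophic biomass densities, herbivore:autotroph
percentages, NPP and herbivory as percentages of autotroph standing stock,
mass-abundance spectrum slopes, and the maximum mass-balance residual.
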