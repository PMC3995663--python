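# gemsim

A desk-scale **general ecosystem model**: a mechanistic simulator of whole
ecological communities — autotroph stocks plus herbivorous, omnivorous and
carnivorous animals of every body size — on a lat-lon grid, driven by
monthly climate and NPP forcing. It is written for ecologists who want to
study how community-level structure *emerges* from individual-level
mechanism: nothing about trophic pyramids, size spectra or life histories
is prescribed; they arise from the feeding, metabolism, growth,
reproduction, mortality and dispersal of interacting cohorts.

## The model in brief

Heterotrophs are simulated as **cohorts** — groups of identical organisms
with a functional group (realm × feeding mode × mobility × reproductive
strategy × thermoregulation), fixed juvenile and adult body masses
(`M_juv`, `M_ad`), and dynamic abundance `N_i`, individual body mass `M_i`
and stored reproductive mass `R_i`. Autotrophs are biomass **stocks**
(`B_s`), updated each step as `ΔB = gain − loss`. Core process rates:

- **Feeding** — Holling Type III: per-capita intake
  `a D² / (1 + a h D²)` in resource density `D`, with a handling-limited
  ceiling `1/h`. Predation is size-structured: prey are binned by log
  mass and attack is weighted by a Gaussian kernel (in log mass) around an
  optimal prey:predator mass ratio.
- **Metabolism** — Boltzmann–Arrhenius mass power laws,
  `I ∝ M^b e^{−E_A/(k_B T)}`, field rate while active and basal rate
  while inactive; body temperature is 310 K for endotherms and ambient
  for ectotherms, and terrestrial ectotherms are only active while
  ambient temperature lies inside climate-estimated limits.
- **Growth/reproduction** — net assimilation grows juveniles to `M_ad`;
  adults store surplus as `R_i` and spawn an offspring cohort of
  `N·R/M_juv` individuals when `R ≥ 0.25 M_ad` (semelparous parents also
  commit half their body mass and die).
- **Mortality** — background + starvation (logistic in
  `M_i / max M ever achieved`) + Gompertz-like senescence, applied as
  exponential survival; predation mortality comes from the feeding of
  other cohorts.
- **Numerics** — monthly steps, randomised cohort order, sub-stepped
  exponential differencing of all depletion losses (nothing can go
  negative), nearest-in-trait-space cohort merging above a 1,000-cohort
  cap, and a per-step mass-balance ledger with machine-precision
  residuals (~1e−14 relative).

See `docs/methods.md` for the full account, parameter provenance, and
known limitations.

## Worked example

Run the wet-tropical aseasonal focal cell for 20 years (1,008 seeded
cohorts, monthly steps) and summarise the final year's trophic pyramid:

```python
import gemsim as g
from gemsim.metrics import trophic_pyramid

sim = g.run_single_cell(
    g.archetype_spec("terrestrial_tropical_aseasonal"),
    g.default_functional_groups(), g.ModelParameters(),
    years=20, seed=1, n_cohorts_per_group=112,
)
summary = trophic_pyramid(sim.history(), sim.fluxes(), sim.cell.area_km2)
print(summary.to_frame().round(1).to_string(index=False))
```

prints

```
trophic_level  biomass_density_kg_km2  abundance_density_km2
    autotroph               1292725.0                    NaN
    herbivore                131856.8                 1169.7
     omnivore                     0.0                    0.0
    carnivore                     0.0                    0.0
```

with `summary.npp_percent_of_autotroph = 139.6` (annual NPP is ~1.4× the
leaf standing stock) and an autotroph→herbivore flux of 83.1% of the
stock per year. The pyramid is non-inverted — the leaf stock carries ten
times the herbivore biomass — because terrestrial plants put most
production into inedible structural tissue and foliage is hard to crop.
The same call on the oligotrophic marine archetype gives the opposite
shape: a phytoplankton standing stock orders of magnitude *below* grazer
biomass, sustained by ~monthly producer turnover. In this 20-year example
the predator levels have died out; see `docs/methods.md` on the fragility
of four-level coexistence at desk scale.

A thin CLI wraps the same machinery:

```bash
gemsim run-cell --config run.yaml --out out/ --seed 1 --years 50
gemsim ensemble --config run.yaml --out out/
```

where `run.yaml` names a forcing archetype (or an explicit synthetic
spec, or gridded NetCDF files) and any parameter overrides; outputs are
CSV tables of biomass/abundance densities by functional group, the
per-step flux ledger, and a NetCDF summary, plus a provenance manifest.

Multi-cell grids with diffusive, responsive and advective dispersal are
available through the library API (`gemsim.GridSimulation`), as are
checkpoint/restart (`save_checkpoint` / `load_checkpoint`), state
snapshots, and community metrics (`gemsim.metrics`: trophic pyramids,
mass-abundance and normalised biomass spectra, life-history summaries).

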