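# ecoevosim

Spatially explicit eco-evolutionary simulation of species diversification on
dynamic grid landscapes.

Macroecological patterns — foremost the latitudinal diversity gradient (LDG),
the equator-to-pole decline in species richness — emerge from the interplay of
speciation, dispersal, trait evolution, extinction, and ecological limits
acting over millions of years on changing geographies. `ecoevosim` is a
simulation engine for exploring that interplay: species are sets of
populations occupying grid cells; populations disperse, adapt, go locally
extinct, and — when geographic isolation persists long enough — split into
new species. The package is aimed at macroecologists and macroevolutionary
biologists who want to confront mechanistic hypotheses about diversity
gradients with data using pattern-oriented statistics.

## The model

A **dynamic landscape** is a lon/lat grid observed at discrete time steps
(default 170 kyr per step, counting down to 0 = the present). Each habitable
cell carries a normalized temperature (0.01 unit ≡ 1 °C) and an aridity index
in [0, 1]. Connection costs between cells are shortest paths on the
8-neighbour grid graph; hops through water cost twice the terrestrial rate.

Each step runs four processes in order:

1. **Speciation.** A species' occupied sites are partitioned into geographic
   clusters: connected components of the cost graph thresholded at the
   species' clustering distance (the median of its dispersal kernel).
   Site pairs in different clusters accumulate divergence at rate 1 per step
   (optionally up to 3× faster at warm sites, scaled as
   1 + 2·T^d_power); reconnected pairs decay back to zero. When the minimum
   divergence between clusters reaches the threshold Ϟ, the clusters become
   separate species (allopatric, divergence-threshold cladogenesis).
2. **Dispersal.** For every (occupied source, vacant habitable target) pair,
   colonization succeeds when the connection cost does not exceed a distance
   drawn from a Weibull(ɸ, Ψ) kernel; among successful sources one colonizer
   is chosen uniformly at random.
3. **Evolution.** Each population's temperature optimum `t_opt` evolves by
   Brownian motion (per-step SD σ), then is homogenized within each
   geographic cluster by an abundance-weighted mean (gene flow).
4. **Ecology.** Abundance follows a linear niche ramp,
   a = a_max·max(0, 1 − |t_opt − T|/ω), and sites enforce a carrying
   capacity k — uniform, or scaled with available energy,
   k = k_base·(T·(1 − aridity))^k_power — by removing individuals uniformly
   at random until the site total is at k. Populations hitting zero are
   locally extinct; species with no populations left are globally extinct.

Five canonical configurations bundle these processes: **M1** (neutral null:
no ecology, no trait evolution), **M2** (niche conservatism), **M3**
(temperature-dependent diversification rates), **M4** (uniform carrying
capacity), and **M5** (energy-scaled carrying capacity). Parameter-space
exploration uses Sobol quasi-random sampling over the declared ranges
(ɸ ∈ [2,5], Ψ ∈ [550,850] km, σ ∈ [0.001,0.01], Ϟ ∈ [6,60],
d_power ∈ [2,6], k_power ∈ [1,4]), with validity screens on the resulting
runs (≥ 20 extant species, < 50,000 species total, < 10,000 per site).

Summary statistics for pattern-oriented model confrontation: the LDG slope
(% richness loss per degree of |latitude|) and latitude-curve correlation,
Aldous' β-splitting tree-imbalance maximum-likelihood estimate, the
normalized lineage-through-time (nLTT) curve difference, range-size
distributions with a species-range-decrease slope, and per-latitude-band
speciation/extinction/migration rates.

## Worked example

```python
from ecoevosim import RunConfig, RichnessMap, ldg_percent_loss, make_model, run_simulation
from ecoevosim.worlds import latitudinal_world

world = latitudinal_world()          # 24×20 grid at 5°, 100 steps, cooling trend
model = make_model("M5")             # energy-limited carrying capacity
out = run_simulation(RunConfig(model=model, seed=42), world)

hab = world.slice_at_step(0).habitable
ldg = ldg_percent_loss(RichnessMap(out.present_richness[hab], world.lats[hab]))
print(f"species created: {out.total_species_created()}  extant: {out.extant_count()}")
print(f"LDG %loss per degree latitude: {ldg:.2f}")
print(f"speciation events: {len(out.genealogy.splits)}  extinctions: {len(out.genealogy.extinctions)}")
```

prints

```
species created: 16  extant: 16
LDG %loss per degree latitude: 2.93
speciation events: 15  extinctions: 0
```

A single ancestor spread over three seaway-separated continents diversified
into 16 species over 100 steps (17 Myr), and the energy-scaled carrying
capacity produced a clear latitudinal gradient: richness falls by about 2.9 %
of its maximum per degree of latitude toward the poles. Under the neutral
null M1 on the same world the gradient is absent (≈ 0), so the gradient here
is attributable to the ecological-limits mechanism, not to geometry.

The same toolkit is scriptable from the shell:

```sh
ecoevosim generate-landscape --kind latitudinal --out world.csv
ecoevosim run --config config.yaml --landscape world.csv --out run/ --seed 42
ecoevosim stats --run run/
ecoevosim explore --model M5 --n 16 --landscape world.csv --out sweep/
```

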