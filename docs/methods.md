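# Methods

## Model overview and assumptions

`ecoevosim` simulates clade diversification as a discrete-time Markov process
over a gridded landscape. The state is a set of species, each a collection of
populations (site, integer abundance, trait vector) plus a symmetric
divergence matrix over its occupied sites. The core assumptions:

- **Allopatric, divergence-threshold speciation.** Reproductive isolation is
  summarized by a scalar divergence per site pair that grows while the pair
  is in different geographic clusters and decays at the same rate while
  reconnected. Cladogenesis occurs when the minimum cross-cluster divergence
  reaches Ϟ. There is no sympatric or parapatric speciation and no explicit
  genetics; divergence units are abstract (1 unit ≈ one 170-kyr step of
  isolation at the base rate).
- **Clustering = dispersal reach on the cost graph.** Two occupied sites are
  in the same cluster when their connection cost is at most the species'
  clustering distance, fixed deterministically at the dispersal kernel's
  median, Ψ·(ln 2)^(1/ɸ). A stochastic redraw per step would make cluster
  membership — and hence speciation timing — jitter with no biological
  signal, so the deterministic median was preferred.
- **Single-trait niche.** The only evolving trait is the temperature optimum
  `t_opt`. Selection is implicit: Brownian mutation plus abundance-weighted
  homogenization within clusters biases cluster optima toward conditions
  where populations are abundant, which tracks a drifting climate.
- **Individual-based ecology only at the site level.** Abundances are
  integer "individual units"; carrying-capacity enforcement removes units
  uniformly at random without replacement (equivalently: survivors are a
  multivariate hypergeometric sample of size k). No interspecific
  differences in competitive ability.

## Step order

Within a step: (1) habitability update (populations on newly uninhabitable
sites die; empty species go extinct at this step); (2) speciation (cluster →
divergence update → split); (3) dispersal; (4) Brownian mutation;
(5) ecology (niche abundances, then capacity, then removal of zeroed
populations), followed by cluster-wise trait homogenization; (6) observers.
Speciation therefore sees the *previous* step's ranges, and homogenization
acts after ecological mortality has set the weights. Species are processed
in ascending id and sites in ascending id everywhere, so a single seeded RNG
stream makes runs bit-reproducible.

## Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| ɸ | Weibull dispersal shape | 2.0 | — |
| Ψ | Weibull dispersal scale | 700 | km |
| σ | per-step mutation SD of `t_opt` | 0.005 | normalized (0.01 ≡ 1 °C) |
| Ϟ | divergence threshold for speciation | 30 | steps of isolation (≈ 5 Myr) |
| d_power | temperature exponent of the divergence rate | 4 | — |
| ω | niche half-width | 0.1 | normalized (≡ 10 °C) |
| a_max | abundance at a perfect niche match | 10 | individuals |
| k_base | capacity of a maximal-energy site | 100 | individuals |
| k_power | energy exponent of the capacity | 2 | — |

Temperatures are normalized so that 0.01 unit ≡ 1 °C; the generators use an
affine anchor of −35 °C → 0 (so 0.65 ≈ +30 °C). σ is a standard deviation:
its stated ±0.1–1 °C-per-step correspondence only holds on that reading.
Exploration ranges are ɸ ∈ [2,5], Ψ ∈ [550,850], σ ∈ [0.001,0.010],
Ϟ ∈ [6,60], d_power ∈ [2,6], k_power ∈ [1,4]; defaults sit inside them.

Defaults were fixed once, on connectivity grounds rather than by output
tuning: with a 5° grid (~556 km between neighbouring cell centres at the
equator), Ψ = 700 with ɸ = 2 puts adjacent cells inside the clustering
median (583 km) — so continuous ranges behave as coherent gene-flow units —
while one-cell seaways (crossing cost ≈ 1,670 km, water hops doubled) remain
strong but leaky barriers (per-pair crossing probability ≈ 0.003 per step).
ɸ at the low end of its range gives the kernel the heavier tail that makes
rare long-distance colonization possible at all; larger shapes make seaways
effectively absolute. Ϟ = 30 corresponds to ≈ 5 Myr of uninterrupted
isolation, a mid-range allopatric speciation timescale.

## Cost matrices

Connection costs are Dijkstra shortest paths on the 8-neighbour grid graph
(queen adjacency avoids axis-aligned artifacts; optional longitude wrap for
global worlds). Each undirected hop is priced at its great-circle length
(haversine, R = 6371 km) times the mean of the two endpoint crossing factors
(1 for habitable, 2 for water). Pricing by the destination factor alone
would make path costs direction-dependent; endpoint averaging keeps the
matrix symmetric by construction and reproduces the standard corridor total
(land→water→land over equal hops = d·2 + d·1 = 3d on either accounting).
`local` mode truncates the matrix at a configurable range, which is also a
useful computational bound: survival probabilities beyond ~2,500 km are
negligible for the explored kernels.

## Divergence bookkeeping

Divergence is tracked per site pair and updated with cluster-uniform
increments, so it stays well defined through colonizations (a colonist
copies its seeding source's divergence row — it carries its source
population's incompatibilities), merges (same-cluster pairs decay to zero,
modeling introgression on secondary contact), and splits (cross-species
entries are dropped, within-species entries retained). The decay rate
defaults to the accumulation rate; nothing in the model pins it, and the
symmetric choice makes the "reconnection resets the clock" behaviour exact.
At a split, the connected component of still-compatible clusters carrying
the most total abundance keeps the parent's identity (ties: lowest cluster
label); fresh ids are assigned in cluster-label order so the genealogy is
reproducible.

## Synthetic landscapes

The generators provide the structure the simulations assume without any
external data:

- `latitudinal_world` (default 24 lon × 20 lat at 5°, 100 steps): a
  monotone equator-to-pole temperature gradient (0.65 → ~0.32 at |lat| 50°),
  a Gaussian subtropical arid belt (peak 0.8 at |25°|, width 12°), two
  one-cell meridional seaways splitting the land into three continents, a
  polar cold limit on habitability (0.25), and a secular cooling trend of
  0.10 normalized units (≈ 10 °C) over the run — or an oscillation, or a
  static climate. The 5° resolution was chosen so that adjacent cells sit
  within the dispersal kernels' clustering median, as in coarse-resolution
  continental grids; at 10° every site is beyond the median of every
  explored kernel, ranges pulverize into singleton clusters, and the
  neutral model (which has no mortality) grows per-site richness roughly
  exponentially until the abort caps fire — a degenerate regime, not a
  harder version of the same dynamics.
- `island_ontogeny`: a habitable disk whose radius follows a triangular
  rise-and-fall profile (maximum area at the midpoint step), with
  sinusoidal temperature variability — the growth-then-submergence life
  cycle of an oceanic island, not a geomorphological model.
- `barrier_toy`: a fixed 8×6 two-bank world split by a one-cell river,
  deterministic down to the byte; the reference fixture for divergence
  bookkeeping (two banks, rate 1, Ϟ = 6 → one split exactly at the 6th
  isolated step).

What these worlds do *not* emulate: continental drift, realistic coastline
or topography, spatially structured climate anomalies, and empirically
calibrated land areas per latitude band. Passing tests on them show the
engine's mechanisms are correct and that the energy-limited model generates
a poleward richness decline the neutral model does not; they do not show
that simulated gradients quantitatively match empirical tetrapod gradients,
which requires reconstructed paleolandscapes and empirical range and
phylogeny compilations outside this package's scope.

## Ecology functional forms

Only the qualitative shape of the abundance and capacity rules is pinned by
the model descriptions, so both are declared package choices: suitability is
a linear ramp of half-width ω (abundance increases as the mismatch between
niche optimum and site temperature *shrinks* — the intended niche logic),
and site energy is temperature × (1 − aridity) raised to k_power. The
temperature-dependent divergence rate is base·(1 + (m−1)·T^d_power) with
m = 3, which satisfies both printed anchors (base rate at the coldest sites,
3× at the warmest) for every d_power.

## Numerical choices

- Dispersal success per (source, target) pair is sampled as a Bernoulli
  with the kernel survival probability exp(−(cost/Ψ)^ɸ) — the same
  distribution as drawing a distance and comparing, at a fraction of the
  cost. `draw_dispersal` still produces literal kernel draws for
  calibration.
- Capacity reduction uses `Generator.multivariate_hypergeometric`, which is
  exactly the one-unit-at-a-time uniform urn.
- The β-splitting likelihood is maximized by bounded scalar search on
  (−2, 10]; per-node normalizations are computed by explicit log-sum-exp
  over all split sizes. The estimate is median-consistent; on 64-tip trees
  the sampling distribution of the MLE is strongly right-skewed, so means
  of per-tree estimates sit above the generating β even for exact
  likelihood code (verified against trees simulated directly from the
  beta-splitting model).
- The nLTT statistic normalizes each tree from its lineage origin (the stem
  start when a root edge exists, else the root split) to the present, and
  integrates the absolute difference of the normalized step functions over
  the merged event grid.
- LDG band means are normalized by their maximum ("normalized richness" is
  otherwise undefined); the curve statistic divides band sums by habitable
  sites per band as the area scaling; bands are unweighted in the
  regression. Octave (log₂) bins underlie the range-size histogram, with
  the SRD slope computed as OLS of log₁₀(frequency+1) on bin index; the
  empirical SRD magnitudes reported for real faunas are not reconstructible
  from their definition, so this slope is a package-defined substitute and
  not comparable to them.
- Tropic/polar band boundaries: 23.45° and 66.55°.

## Problem sizes

The default study conditions are the 24×20, 100-step latitudinal world;
single runs take seconds, and the test suite's ensembles (10 replicates per
model for the gradient contrast; 10 per threshold for the Ϟ sweep) complete
in minutes on one core. These are desk-scale analogues: global
production-style runs at 1–4° over hundreds of steps are out of scope here.

## Known limitations

- No plate tectonics or paleogeographic reconstructions; the landscape
  loader accepts CSV or netCDF series for users who have their own.
- No trait-mediated dispersal, competition kernels, or
  Ornstein–Uhlenbeck trait dynamics; the process interfaces are pluggable
  but only the rules above ship.
- Abundance is a coarse integer currency; demographic stochasticity exists
  only through capacity enforcement and colonization.
- The neutral model M1 has no mortality, so on landscapes with persistent
  fragmentation its species counts grow without bound; the global and
  per-site abort caps (50,000 and 10,000) are the intended guard rails.
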