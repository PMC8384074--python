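"""Simulation engine: the per-step process loop on a dynamic landscape.

Each time step (counting down to 0 = present) runs, in order:

1. habitability update — populations on newly uninhabitable sites are
   removed; species left with no populations go extinct at this step;
2. speciation — geographic clustering of each species' occupied sites,
   divergence accumulation/decay, and threshold splits;
3. dispersal — kernel-limited colonization of vacant habitable sites;
4. evolution — Brownian mutation of the temperature optimum;
5. ecology — niche-based abundances, carrying-capacity reduction, local and
   global extinction bookkeeping, then cluster-wise trait homogenization;
6. observer — scheduled, side-effect-free recording.

A single seeded RNG stream is consumed in a fixed order (species by
ascending id, sites by ascending id), so identical seed + configuration +
landscape reproduce byte-identical outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .landscape import DynamicLandscape, build_cost_matrix
from .models import ModelConfig
from .processes import (
    apply_carrying_capacity,
    dispersal_step,
    divergence_rate,
    evolution_step,
    homogenize_traits,
    niche_abundance,
    site_capacity,
)
from .species import (
    Genealogy,
    SpeciesState,
    cluster_sites,
    create_ancestor_species,
    split_species,
    update_divergence,
)

__all__ = ["RunConfig", "SimulationOutput", "Simulation", "run_simulation", "observer_record"]


@dataclass
class RunConfig:
    """Technical run settings: seed, time bounds, abort rules, observers."""

    model: ModelConfig
    seed: int = 0
    start_step: int | None = None  # default: oldest slice
    end_step: int = 0
    abort_max_species_global: int = 50_000
    abort_max_species_per_site: int = 10_000
    observer_every: int | None = None
    output_dir: str | Path | None = None
    n_ancestors: int = 1
    range_spec: object = "all_habitable"
    initial_traits_rule: object = "match_local"

    def __post_init__(self) -> None:
        if self.start_step is not None and self.start_step < self.end_step:
            raise ValueError("start_step must be ≥ end_step")
        if self.end_step < 0:
            raise ValueError("end_step must be ≥ 0")


@dataclass
class SimulationOutput:
    """Everything a finished (or aborted) run produced."""

    config: RunConfig
    genealogy: Genealogy
    species: list[SpeciesState]
    richness_by_step: dict[int, np.ndarray]
    species_tables: dict[int, pd.DataFrame]
    migrations: pd.DataFrame
    status: str  # "completed" | "aborted"
    abort_reason: str | None
    duration_kyr: float
    lats: np.ndarray
    lons: np.ndarray
    cell_area_km2: np.ndarray
    max_per_site_richness: int
    runtime_s: float

    def extant_count(self) -> int:
        return sum(1 for sp in self.species if not sp.is_extinct)

    def total_species_created(self) -> int:
        return len(self.species)

    def max_cohabitation(self) -> int:
        return int(self.max_per_site_richness)

    @property
    def present_richness(self) -> np.ndarray:
        step = min(self.richness_by_step)
        return self.richness_by_step[step]

    def newick(self, extant_only: bool = False) -> str:
        return self.genealogy.to_newick(
            duration_kyr=self.duration_kyr, extant_only=extant_only
        )

    def range_sizes_km2(self) -> np.ndarray:
        """Extant species range sizes: occupied sites × mean cell area."""
        mean_area = float(self.cell_area_km2.mean())
        return np.array(
            [sp.n_populations * mean_area for sp in self.species if not sp.is_extinct]
        )

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        rows = []
        for step, r in sorted(self.richness_by_step.items(), reverse=True):
            rows.append(
                pd.DataFrame(
                    {
                        "step": step,
                        "site_id": np.arange(r.size),
                        "lon": self.lons,
                        "lat": self.lats,
                        "richness": r,
                    }
                )
            )
        pd.concat(rows, ignore_index=True).to_csv(path / "richness.csv", index=False)
        tables = [t for _, t in sorted(self.species_tables.items(), reverse=True)]
        pd.concat(tables, ignore_index=True).to_csv(path / "species_table.csv", index=False)
        self.migrations.to_csv(path / "migrations.csv", index=False)
        self.genealogy.to_frame().to_csv(path / "genealogy.csv", index=False)
        (path / "phylogeny.nwk").write_text(self.newick() + "\n")
        if self.extant_count() >= 1:
            (path / "phylogeny_extant.nwk").write_text(self.newick(extant_only=True) + "\n")
        meta = {
            "status": self.status,
            "abort_reason": self.abort_reason,
            "seed": self.config.seed,
            "model": self.config.model.to_dict(),
            "n_species_total": self.total_species_created(),
            "n_species_extant": self.extant_count(),
            "max_per_site_richness": self.max_cohabitation(),
            "duration_kyr": self.duration_kyr,
            "runtime_s": round(self.runtime_s, 3),
        }
        (path / "run_meta.json").write_text(json.dumps(meta, indent=2, default=str) + "\n")


class Simulation:
    """Mutable simulation state plus the main loop."""

    def __init__(self, config: RunConfig, landscape: DynamicLandscape) -> None:
        self.config = config
        self.landscape = landscape
        self.model = config.model
        self.rng = np.random.default_rng(config.seed)
        steps = sorted((sl.step_index for sl in landscape.slices), reverse=True)
        self.start_step = config.start_step if config.start_step is not None else steps[0]
        if self.start_step not in steps or config.end_step not in steps:
            raise ValueError("start/end steps must exist in the landscape series")
        self.genealogy = Genealogy()
        self.active: list[SpeciesState] = []
        self.all_species: list[SpeciesState] = []
        self.next_id = 0
        self.clustering_distance = self.model.kernel.median_km()
        self._cost_cache: tuple[bytes, object] | None = None
        self.richness_by_step: dict[int, np.ndarray] = {}
        self.species_tables: dict[int, pd.DataFrame] = {}
        self.migration_rows: list[tuple[int, int, int, int, float, float]] = []
        self.max_per_site_richness = 0
        self.status = "completed"
        self.abort_reason: str | None = None

    # -- helpers ----------------------------------------------------------

    def _costs(self, slice_):
        key = slice_.habitable.tobytes()
        if self._cost_cache is None or self._cost_cache[0] != key:
            self._cost_cache = (key, build_cost_matrix(self.landscape, slice_))
        return self._cost_cache[1]

    def _richness(self) -> np.ndarray:
        r = np.zeros(self.landscape.n_sites, dtype=int)
        for sp in self.active:
            np.add.at(r, sp.site_ids, 1)
        return r

    def _mark_extinct(self, sp: SpeciesState, step: int) -> None:
        sp.extinction_step = step
        lat = sp.last_centroid_lat if sp.last_centroid_lat is not None else np.nan
        self.genealogy.record_extinction(sp.species_id, step, lat)

    def _species_table(self, step: int, costs) -> pd.DataFrame:
        rows = []
        for sp in self.active:
            labels = cluster_sites(sp, costs, self.clustering_distance)
            rows.append(
                pd.DataFrame(
                    {
                        "step": step,
                        "species_id": sp.species_id,
                        "site_id": sp.site_ids,
                        "abundance": sp.abundance,
                        "t_opt": sp.traits["t_opt"],
                        "cluster": labels,
                    }
                )
            )
        if not rows:
            return pd.DataFrame(
                columns=["step", "species_id", "site_id", "abundance", "t_opt", "cluster"]
            )
        return pd.concat(rows, ignore_index=True)

    def _scheduled(self, step: int) -> bool:
        if step == self.config.end_step:
            return True
        every = self.config.observer_every
        return every is not None and (self.start_step - step) % every == 0

    # -- the per-step update ----------------------------------------------

    def step(self, step: int) -> None:
        slice_ = self.landscape.slice_at_step(step)
        model = self.model

        # (1) habitability update
        for sp in list(self.active):
            keep = slice_.habitable[sp.site_ids]
            if not keep.all():
                sp.keep_mask(keep)
                if sp.is_extinct:
                    self._mark_extinct(sp, step)
                    self.active.remove(sp)
        costs = self._costs(slice_)

        # (2) speciation: cluster → divergence update → threshold split
        new_species: list[SpeciesState] = []
        for sp in self.active:
            labels = cluster_sites(sp, costs, self.clustering_distance)
            sp.last_cluster_labels = labels
            if model.divergence.mode == "temperature":
                mean_t = float(np.nanmean(slice_.temperature[sp.site_ids]))
                rate = divergence_rate(model.divergence, np.clip(mean_t, 0.0, 1.0))
            else:
                rate = model.divergence.base_rate
            update_divergence(sp, labels, rate)
            pieces, self.next_id = split_species(
                sp,
                labels,
                model.divergence_threshold,
                max(self.next_id, sp.species_id + 1),
                step,
                genealogy=self.genealogy,
                site_lats=self.landscape.lats,
            )
            new_species.extend(pieces[1:])
        self.active.extend(new_species)
        self.all_species.extend(new_species)
        self.active.sort(key=lambda s: s.species_id)

        # (3) dispersal
        habitable_ids = np.flatnonzero(slice_.habitable)
        for sp in self.active:
            records = dispersal_step(
                sp,
                costs,
                model.kernel,
                self.rng,
                habitable_ids,
                founder_abundance=model.founder_abundance,
            )
            for src, tgt in records:
                self.migration_rows.append(
                    (
                        step,
                        sp.species_id,
                        src,
                        tgt,
                        float(self.landscape.lats[src]),
                        float(self.landscape.lats[tgt]),
                    )
                )

        # (4) evolution: Brownian mutation of the temperature optimum
        if model.evolution.enabled:
            for sp in self.active:
                evolution_step(sp, model.evolution, self.rng)

        # (5) ecology: niche abundances, capacity, extinctions, homogenization
        eco = model.ecology
        if eco.mode != "none":
            for sp in self.active:
                sp.abundance = niche_abundance(
                    sp.traits["t_opt"],
                    slice_.temperature[sp.site_ids],
                    eco.niche_width,
                    eco.a_max,
                )
            if eco.mode == "niche+capacity":
                k = site_capacity(eco, slice_.temperature, slice_.aridity)
                totals = np.zeros(self.landscape.n_sites, dtype=int)
                occupants: dict[int, list[tuple[SpeciesState, int]]] = {}
                for sp in self.active:
                    np.add.at(totals, sp.site_ids, sp.abundance)
                    for pos, site in enumerate(sp.site_ids):
                        occupants.setdefault(int(site), []).append((sp, pos))
                over = np.flatnonzero(totals > k)
                for site in over:
                    occ = occupants.get(int(site), [])
                    if not occ:
                        continue
                    ab = np.array([sp.abundance[pos] for sp, pos in occ])
                    reduced = apply_carrying_capacity(ab, int(k[site]), self.rng)
                    for (sp, pos), a in zip(occ, reduced):
                        sp.abundance[pos] = a
            for sp in list(self.active):
                zero = sp.abundance == 0
                if zero.any():
                    sp.keep_mask(~zero)
                    if sp.is_extinct:
                        self._mark_extinct(sp, step)
                        self.active.remove(sp)
        if model.evolution.enabled and model.evolution.homogenize:
            for sp in self.active:
                labels = cluster_sites(sp, costs, self.clustering_distance)
                homogenize_traits(sp, labels)

        # bookkeeping: centroids, per-site richness, abort rules
        for sp in self.active:
            sp.last_centroid_lat = sp.centroid_lat(self.landscape.lats)
        r = self._richness()
        peak = int(r.max()) if r.size else 0
        self.max_per_site_richness = max(self.max_per_site_richness, peak)
        if len(self.all_species) > self.config.abort_max_species_global:
            self.status, self.abort_reason = "aborted", "global species cap exceeded"
        elif peak > self.config.abort_max_species_per_site:
            self.status, self.abort_reason = "aborted", "per-site species cap exceeded"

        # (6) observer
        if self._scheduled(step) or self.status == "aborted":
            observer_record(self, step, r, costs)

    def run(self) -> SimulationOutput:
        t0 = time.perf_counter()
        first_slice = self.landscape.slice_at_step(self.start_step)
        ancestors = create_ancestor_species(
            self.landscape,
            first_slice,
            range_spec=self.config.range_spec,
            initial_traits_rule=self.config.initial_traits_rule,
            n_ancestors=self.config.n_ancestors,
            initial_abundance=self.model.initial_abundance,
            genealogy=self.genealogy,
        )
        self.active = list(ancestors)
        self.all_species = list(ancestors)
        self.next_id = max(sp.species_id for sp in ancestors) + 1
        for sp in self.active:
            sp.last_centroid_lat = sp.centroid_lat(self.landscape.lats)
        for step in range(self.start_step, self.config.end_step - 1, -1):
            self.step(step)
            if self.status == "aborted":
                break
        out = SimulationOutput(
            config=self.config,
            genealogy=self.genealogy,
            species=sorted(self.all_species, key=lambda s: s.species_id),
            richness_by_step=self.richness_by_step,
            species_tables=self.species_tables,
            migrations=pd.DataFrame(
                self.migration_rows,
                columns=["step", "species_id", "source_site", "target_site", "source_lat", "target_lat"],
            ),
            status=self.status,
            abort_reason=self.abort_reason,
            duration_kyr=first_slice.duration_kyr,
            lats=self.landscape.lats,
            lons=self.landscape.lons,
            cell_area_km2=self.landscape.cell_area_km2,
            max_per_site_richness=self.max_per_site_richness,
            runtime_s=time.perf_counter() - t0,
        )
        if self.config.output_dir is not None:
            out.to_dir(self.config.output_dir)
        return out


def observer_record(sim: Simulation, step: int, richness: np.ndarray, costs) -> None:
    """Record the scheduled artifacts for one step.  Never mutates state
    (and never touches the engine RNG), so observer settings cannot change
    a run's trajectory."""
    sim.richness_by_step[step] = richness.copy()
    sim.species_tables[step] = sim._species_table(step, costs)


def run_simulation(config: RunConfig, landscape: DynamicLandscape) -> SimulationOutput:
    """Run one simulation to the present (or until an abort rule fires)."""
    return Simulation(config, landscape).run()
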