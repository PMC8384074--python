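"""Species state: populations, traits, divergence bookkeeping and genealogy.

A species is a set of populations (one per occupied site) with per-site
abundances and trait values, plus a symmetric divergence matrix over its
occupied sites.  Geographically isolated clusters of populations accumulate
divergence over time; when the divergence between clusters reaches the
speciation threshold the species splits (divergence-threshold cladogenesis,
in the spirit of Dobzhansky–Muller incompatibilities).  Reconnected clusters
decay their divergence back to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .landscape import ConnectionCostMatrix, DynamicLandscape, EnvironmentalSlice

__all__ = [
    "SpeciesState",
    "Genealogy",
    "create_ancestor_species",
    "cluster_sites",
    "update_divergence",
    "split_species",
]


class SpeciesState:
    """Populations of one species, aligned arrays over sorted occupied sites."""

    __slots__ = (
        "species_id",
        "parent_id",
        "origin_step",
        "extinction_step",
        "site_ids",
        "abundance",
        "traits",
        "divergence",
        "last_centroid_lat",
        "last_cluster_labels",
    )

    def __init__(
        self,
        species_id: int,
        site_ids: np.ndarray,
        abundance: np.ndarray,
        traits: dict[str, np.ndarray],
        parent_id: int | None = None,
        origin_step: int = 0,
        divergence: np.ndarray | None = None,
    ) -> None:
        order = np.argsort(site_ids)
        self.species_id = int(species_id)
        self.parent_id = parent_id
        self.origin_step = int(origin_step)
        self.extinction_step: int | None = None
        self.site_ids = np.asarray(site_ids, dtype=int)[order]
        self.abundance = np.asarray(abundance, dtype=int)[order]
        if np.any(self.abundance < 0):
            raise ValueError("abundance must be non-negative")
        self.traits = {k: np.asarray(v, dtype=float)[order] for k, v in traits.items()}
        n = self.site_ids.size
        if divergence is None:
            divergence = np.zeros((n, n))
        self.divergence = np.asarray(divergence, dtype=float)[np.ix_(order, order)]
        self.last_centroid_lat: float | None = None
        self.last_cluster_labels: np.ndarray | None = None

    @property
    def n_populations(self) -> int:
        return self.site_ids.size

    @property
    def is_extinct(self) -> bool:
        return self.site_ids.size == 0

    def centroid_lat(self, lats: np.ndarray) -> float:
        w = np.maximum(self.abundance, 1)
        return float(np.average(lats[self.site_ids], weights=w))

    def keep_mask(self, mask: np.ndarray) -> None:
        """Retain only populations where ``mask`` is True (aligned to sites)."""
        self.site_ids = self.site_ids[mask]
        self.abundance = self.abundance[mask]
        for k in self.traits:
            self.traits[k] = self.traits[k][mask]
        self.divergence = self.divergence[np.ix_(mask, mask)]

    def add_populations(
        self,
        new_sites: np.ndarray,
        new_abundance: np.ndarray,
        new_traits: dict[str, np.ndarray],
        source_positions: np.ndarray,
    ) -> None:
        """Colonize new sites; each new population copies the divergence row
        of the source population that seeded it (positions into the current
        arrays)."""
        if len(new_sites) == 0:
            return
        n_old = self.site_ids.size
        n_new = len(new_sites)
        div = np.zeros((n_old + n_new, n_old + n_new))
        div[:n_old, :n_old] = self.divergence
        rows = self.divergence[source_positions]  # (n_new, n_old)
        div[n_old:, :n_old] = rows
        div[:n_old, n_old:] = rows.T
        # divergence among colonists: inherited from their sources
        div[n_old:, n_old:] = self.divergence[np.ix_(source_positions, source_positions)]
        np.fill_diagonal(div, 0.0)
        site_ids = np.concatenate([self.site_ids, np.asarray(new_sites, dtype=int)])
        abundance = np.concatenate([self.abundance, np.asarray(new_abundance, dtype=int)])
        traits = {
            k: np.concatenate([self.traits[k], np.asarray(new_traits[k], dtype=float)])
            for k in self.traits
        }
        order = np.argsort(site_ids)
        self.site_ids = site_ids[order]
        self.abundance = abundance[order]
        self.traits = {k: v[order] for k, v in traits.items()}
        self.divergence = div[np.ix_(order, order)]


@dataclass
class Genealogy:
    """Event log of speciations and extinctions, convertible to Newick."""

    origins: dict[int, tuple[int | None, int]] = field(default_factory=dict)
    splits: list[tuple[int, int, int, float]] = field(default_factory=list)  # child, parent, step, lat
    extinctions: list[tuple[int, int, float]] = field(default_factory=list)  # species, step, lat

    def register_origin(self, species_id: int, parent_id: int | None, step: int) -> None:
        self.origins[species_id] = (parent_id, step)

    def record_split(self, child_id: int, parent_id: int, step: int, lat: float = np.nan) -> None:
        self.register_origin(child_id, parent_id, step)
        self.splits.append((child_id, parent_id, step, float(lat)))

    def record_extinction(self, species_id: int, step: int, lat: float = np.nan) -> None:
        self.extinctions.append((species_id, step, float(lat)))

    @property
    def n_species(self) -> int:
        return len(self.origins)

    def to_frame(self):
        import pandas as pd

        rows = [
            {"event": "speciation", "species_id": c, "parent_id": p, "step": s, "lat": la}
            for c, p, s, la in self.splits
        ] + [
            {"event": "extinction", "species_id": i, "parent_id": None, "step": s, "lat": la}
            for i, s, la in self.extinctions
        ]
        return pd.DataFrame(rows, columns=["event", "species_id", "parent_id", "step", "lat"])

    def to_newick(
        self,
        duration_kyr: float = 170.0,
        extant_only: bool = False,
        present_step: int = 0,
    ) -> str:
        """Newick tree over all species ever created.

        Branch lengths are in Myr (steps × slice duration); extinct tips end
        at their extinction time.  With ``extant_only`` the extinct lineages
        are pruned (an ultrametric tree of the survivors).
        """
        dt = duration_kyr / 1000.0  # Myr per step
        extinct_at = {i: s for i, s, _ in self.extinctions}
        children: dict[int, list[tuple[int, int]]] = {i: [] for i in self.origins}
        roots = []
        for sp, (parent, step) in self.origins.items():
            if parent is None:
                roots.append((sp, step))
            else:
                children[parent].append((step, sp))
        for sp in children:
            children[sp].sort(key=lambda e: (-e[0], e[1]))  # earliest (largest step) first

        def tip_time(sp: int) -> int:
            return extinct_at.get(sp, present_step)

        def survives(sp: int) -> bool:
            if sp not in extinct_at:
                return True
            return any(survives(c) for _, c in children[sp])

        def subtree(sp: int, from_step: int, pending: list[tuple[int, int]]) -> str | None:
            """Newick for the lineage of ``sp`` from time ``from_step`` on,
            with ``pending`` its remaining split events (earliest first)."""
            if extant_only and not (
                sp not in extinct_at or any(survives(c) for _, c in pending)
            ):
                return None
            if not pending:
                end = tip_time(sp)
                if extant_only and sp in extinct_at:
                    return None
                return f"s{sp}:{(from_step - end) * dt:.6f}"
            (step, child), rest = pending[0], pending[1:]
            left = subtree(sp, step, rest)
            right = subtree(child, step, children[child])
            parts = [p for p in (left, right) if p is not None]
            blen = (from_step - step) * dt
            if not parts:
                return None
            if len(parts) == 1:
                # collapse the degree-2 node left by pruning
                name, _, rem = parts[0].rpartition(":")
                return f"{name}:{float(rem) + blen:.6f}"
            return f"({parts[0]},{parts[1]}):{blen:.6f}"

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 10000))
        try:
            trees = []
            for sp, step in sorted(roots):
                t = subtree(sp, step, children[sp])
                if t is not None:
                    trees.append(t)
        finally:
            sys.setrecursionlimit(old)
        if not trees:
            return ";"
        if len(trees) == 1:
            return trees[0] + ";"
        return "(" + ",".join(trees) + ");"


def create_ancestor_species(
    landscape: DynamicLandscape,
    slice_: EnvironmentalSlice,
    range_spec="all_habitable",
    initial_traits_rule="match_local",
    n_ancestors: int = 1,
    initial_abundance: int = 10,
    genealogy: Genealogy | None = None,
) -> list[SpeciesState]:
    """Create the ancestor species on the oldest slice.

    ``range_spec`` is ``"all_habitable"`` (one range covering every habitable
    site) or a list of site-id collections, one per ancestor.  The default
    trait rule sets each population's temperature optimum ``t_opt`` to the
    local site temperature.
    """
    if range_spec == "all_habitable":
        ranges = [np.flatnonzero(slice_.habitable)]
        if n_ancestors != 1:
            raise ValueError("'all_habitable' defines a single ancestor range")
    else:
        ranges = [np.asarray(r, dtype=int) for r in range_spec]
        if n_ancestors != len(ranges):
            raise ValueError("n_ancestors must match the number of ranges")
    out = []
    for sid, sites in enumerate(ranges):
        sites = sites[slice_.habitable[sites]]
        if sites.size == 0:
            raise ValueError("ancestor range resolves to no habitable site")
        if initial_traits_rule == "match_local":
            t_opt = slice_.temperature[sites].copy()
        elif isinstance(initial_traits_rule, dict):
            t_opt = np.full(sites.size, float(initial_traits_rule["t_opt"]))
        else:
            raise ValueError(f"unknown traits rule {initial_traits_rule!r}")
        sp = SpeciesState(
            species_id=sid,
            site_ids=sites,
            abundance=np.full(sites.size, int(initial_abundance)),
            traits={"t_opt": t_opt},
            parent_id=None,
            origin_step=slice_.step_index,
        )
        if genealogy is not None:
            genealogy.register_origin(sid, None, slice_.step_index)
        out.append(sp)
    return out


def cluster_sites(
    species: SpeciesState,
    costs: ConnectionCostMatrix,
    clustering_distance_km: float,
) -> np.ndarray:
    """Geographic clusters of the species' occupied sites.

    Two occupied sites join the same cluster iff their connection cost is at
    most the clustering distance (connected components of the thresholded
    cost graph).  Labels are deterministic: the lowest site id in each
    component.
    """
    n = species.n_populations
    if n == 0:
        return np.empty(0, dtype=int)
    sub = species_cost_block(species, costs)
    adj = np.isfinite(sub) & (sub <= clustering_distance_km)
    _, comp = connected_components(csr_matrix(adj), directed=False)
    labels = np.empty(n, dtype=int)
    for c in np.unique(comp):
        members = comp == c
        labels[members] = species.site_ids[members].min()
    return labels


def species_cost_block(species: SpeciesState, costs: ConnectionCostMatrix) -> np.ndarray:
    try:
        return costs.submatrix(species.site_ids)
    except KeyError as exc:
        raise RuntimeError(
            f"species {species.species_id} occupies a site missing from the cost matrix"
        ) from exc


def update_divergence(
    species: SpeciesState,
    cluster_labels: np.ndarray,
    rate_per_pair: float,
    decay_rate: float | None = None,
) -> np.ndarray:
    """Accumulate divergence between clusters, decay it within clusters.

    Cross-cluster site pairs gain ``rate_per_pair`` per step; same-cluster
    pairs decay by ``decay_rate`` (default: same as the accumulation rate)
    down to zero.
    """
    if rate_per_pair < 0:
        raise ValueError("divergence rate must be non-negative")
    if decay_rate is None:
        decay_rate = rate_per_pair if rate_per_pair > 0 else 1.0
    div = species.divergence
    same = cluster_labels[:, None] == cluster_labels[None, :]
    div[~same] += rate_per_pair
    div[same] = np.maximum(div[same] - decay_rate, 0.0)
    np.fill_diagonal(div, 0.0)
    return div


def split_species(
    species: SpeciesState,
    cluster_labels: np.ndarray,
    threshold: float,
    next_species_id: int,
    step: int,
    genealogy: Genealogy | None = None,
    site_lats: np.ndarray | None = None,
) -> tuple[list[SpeciesState], int]:
    """Split a species whose clusters have diverged past the threshold Ϟ.

    Clusters whose minimum cross-pair divergence is still below Ϟ remain
    conspecific (edges of a compatibility graph); the connected components
    of that graph become species.  The component carrying the most total
    abundance keeps the parent's identity (ties: lowest cluster label); the
    others receive fresh ids and a genealogy record.  Cross-species
    divergence entries are dropped, within-species entries retained.

    Returns the list of resulting species (the parent first) and the next
    unused species id.
    """
    if threshold <= 0:
        raise ValueError("speciation threshold must be positive")
    labels = np.asarray(cluster_labels)
    uniq = np.unique(labels)
    if uniq.size <= 1:
        return [species], next_species_id
    k = uniq.size
    # minimum cross-pair divergence per cluster pair
    compat = np.eye(k, dtype=bool)
    for a in range(k):
        ia = labels == uniq[a]
        for b in range(a + 1, k):
            ib = labels == uniq[b]
            if species.divergence[np.ix_(ia, ib)].min() < threshold:
                compat[a, b] = compat[b, a] = True
    n_comp, comp = connected_components(csr_matrix(compat), directed=False)
    if n_comp == 1:
        return [species], next_species_id
    # component site masks, total abundance, lowest cluster label
    masks, totals, low_label = [], [], []
    for c in range(n_comp):
        cl = uniq[comp == c]
        m = np.isin(labels, cl)
        masks.append(m)
        totals.append(species.abundance[m].sum())
        low_label.append(cl.min())
    order = sorted(range(n_comp), key=lambda c: (-totals[c], low_label[c]))
    parent_comp = order[0]
    results = []
    # parent keeps its id, restricted to its component
    new_comps = sorted((c for c in range(n_comp) if c != parent_comp), key=lambda c: low_label[c])
    for c in new_comps:
        m = masks[c]
        child = SpeciesState(
            species_id=next_species_id,
            site_ids=species.site_ids[m],
            abundance=species.abundance[m],
            traits={k_: v[m] for k_, v in species.traits.items()},
            parent_id=species.species_id,
            origin_step=step,
            divergence=species.divergence[np.ix_(m, m)],
        )
        if genealogy is not None:
            lat = child.centroid_lat(site_lats) if site_lats is not None else np.nan
            genealogy.record_split(child.species_id, species.species_id, step, lat)
        results.append(child)
        next_species_id += 1
    species.keep_mask(masks[parent_comp])
    return [species] + results, next_species_id
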