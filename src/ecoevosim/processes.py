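"""The four customizable per-step processes: speciation support (divergence
rates), dispersal, trait evolution, and ecology.

Dispersal draws distances from a kernel and colonizes habitable sites whose
connection cost falls within the drawn distance.  Evolution is Brownian
motion on the temperature optimum, optionally homogenized per geographic
cluster by an abundance-weighted mean.  Ecology recomputes abundances from
the match between a population's temperature optimum and the site
temperature, and optionally enforces a per-site carrying capacity, uniform
or scaled with available energy (temperature × (1 − aridity))."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .landscape import ConnectionCostMatrix
from .species import SpeciesState

__all__ = [
    "DispersalKernel",
    "EvolutionRule",
    "EcologyRule",
    "DivergenceRateRule",
    "divergence_rate",
    "draw_dispersal",
    "dispersal_step",
    "evolution_step",
    "homogenize_traits",
    "niche_abundance",
    "site_capacity",
    "apply_carrying_capacity",
]


@dataclass
class DispersalKernel:
    """Dispersal-distance distribution: Weibull(shape ɸ, scale Ψ km) or a
    deterministic constant."""

    family: str = "weibull"  # "weibull" | "constant"
    shape: float = 2.0
    scale_km: float = 700.0
    value_km: float = 500.0

    def __post_init__(self) -> None:
        if self.family not in ("weibull", "constant"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family == "weibull" and (self.shape <= 0 or self.scale_km <= 0):
            raise ValueError("Weibull kernel needs positive shape and scale")
        if self.family == "constant" and self.value_km < 0:
            raise ValueError("constant kernel distance must be non-negative")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n < 0:
            raise ValueError("n must be non-negative")
        if self.family == "constant":
            return np.full(n, float(self.value_km))
        return self.scale_km * rng.weibull(self.shape, size=n)

    def survival(self, cost: np.ndarray) -> np.ndarray:
        """P(draw ≥ cost): the per-attempt colonization success probability."""
        cost = np.asarray(cost, dtype=float)
        if self.family == "constant":
            return np.where(np.isfinite(cost) & (cost <= self.value_km), 1.0, 0.0)
        out = np.exp(-((np.where(np.isfinite(cost), cost, np.inf) / self.scale_km) ** self.shape))
        return np.where(np.isfinite(cost), out, 0.0)

    def median_km(self) -> float:
        """Deterministic clustering distance: the kernel median."""
        if self.family == "constant":
            return float(self.value_km)
        return float(self.scale_km * np.log(2.0) ** (1.0 / self.shape))


@dataclass
class EvolutionRule:
    """Brownian-motion evolution of the temperature optimum.

    ``sigma`` is the per-step mutation standard deviation in normalized
    trait units (0.001–0.010 ≡ ±0.1–1 °C per step); traits are optionally
    homogenized per geographic cluster by an abundance-weighted mean."""

    sigma: float = 0.005
    homogenize: bool = True
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass
class EcologyRule:
    """Abundance model: none (neutral), niche, or niche plus carrying capacity.

    ``niche_width`` is the trait-mismatch half-width beyond which abundance
    is zero (normalized units; 0.1 ≡ 10 °C).  ``k_base`` is the capacity of
    a maximal-energy site, modulated by ``k_power`` when capacity scales
    with energy = temperature × (1 − aridity)."""

    mode: str = "none"  # "none" | "niche" | "niche+capacity"
    niche_width: float = 0.1
    a_max: int = 10
    k_base: int = 100
    k_power: float = 2.0
    energy_source: str = "uniform"  # "uniform" | "temp_aridity"

    def __post_init__(self) -> None:
        if self.mode not in ("none", "niche", "niche+capacity"):
            raise ValueError(f"unknown ecology mode {self.mode!r}")
        if self.niche_width <= 0:
            raise ValueError("niche width must be positive")
        if self.k_base < 1:
            raise ValueError("k_base must be at least 1")
        if self.energy_source not in ("uniform", "temp_aridity"):
            raise ValueError(f"unknown energy source {self.energy_source!r}")


@dataclass
class DivergenceRateRule:
    """Per-step divergence accumulation rate, constant or temperature-scaled.

    In temperature mode the rate rises from ``base_rate`` at the coldest
    normalized temperature to ``max_multiplier × base_rate`` at the warmest,
    as base·(1 + (m−1)·T^d_power)."""

    mode: str = "constant"  # "constant" | "temperature"
    base_rate: float = 1.0
    d_power: float = 4.0
    max_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "temperature"):
            raise ValueError(f"unknown divergence mode {self.mode!r}")
        if self.base_rate < 0:
            raise ValueError("base rate must be non-negative")


def divergence_rate(rule: DivergenceRateRule, mean_temp_norm: float) -> float:
    """Divergence accumulation rate at a given mean normalized temperature."""
    if rule.mode == "constant":
        return rule.base_rate
    t = float(mean_temp_norm)
    if not 0.0 <= t <= 1.0:
        warnings.warn(f"normalized temperature {t:.3f} outside [0, 1]; clamped")
        t = min(max(t, 0.0), 1.0)
    return rule.base_rate * (1.0 + (rule.max_multiplier - 1.0) * t**rule.d_power)


def draw_dispersal(kernel: DispersalKernel, n: int, rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. dispersal distances (km) from the kernel."""
    return kernel.draw(n, rng)


def dispersal_step(
    species: SpeciesState,
    costs: ConnectionCostMatrix,
    kernel: DispersalKernel,
    rng: np.random.Generator,
    habitable_site_ids: np.ndarray,
    founder_abundance: int = 5,
):
    """Colonization of vacant habitable sites.

    Every (occupied source, vacant habitable target) pair succeeds iff the
    connection cost does not exceed an independent kernel draw (simulated as
    a Bernoulli with the kernel's survival probability, which is the same
    distribution).  Among the successful sources of a target, the colonizer
    is selected uniformly at random; the new population copies the source's
    traits and divergence row and starts at the founder abundance.

    Returns a list of (source_site, target_site) colonization records.
    """
    if species.n_populations == 0:
        return []
    occupied = species.site_ids
    targets = np.setdiff1d(habitable_site_ids, occupied, assume_unique=False)
    if targets.size == 0:
        return []
    cost = costs.submatrix(occupied, targets)
    p = kernel.survival(cost)
    reachable_cols = p.max(axis=0) > 0.0
    if not reachable_cols.any():
        return []
    targets = targets[reachable_cols]
    p = p[:, reachable_cols]
    active_rows = p.max(axis=1) > 0.0
    row_pos = np.flatnonzero(active_rows)
    p = p[active_rows]
    success = rng.random(p.shape) < p
    col_ok = np.flatnonzero(success.any(axis=0))
    if col_ok.size == 0:
        return []
    new_sites, src_positions, records = [], [], []
    for c in col_ok:
        srcs = np.flatnonzero(success[:, c])
        pick = srcs[0] if srcs.size == 1 else srcs[rng.integers(srcs.size)]
        src_global = row_pos[pick]
        new_sites.append(int(targets[c]))
        src_positions.append(int(src_global))
        records.append((int(occupied[src_global]), int(targets[c])))
    src_positions = np.asarray(src_positions, dtype=int)
    new_traits = {k: v[src_positions].copy() for k, v in species.traits.items()}
    species.add_populations(
        np.asarray(new_sites, dtype=int),
        np.full(len(new_sites), int(founder_abundance)),
        new_traits,
        src_positions,
    )
    return records


def evolution_step(species: SpeciesState, rule: EvolutionRule, rng: np.random.Generator) -> None:
    """Brownian-motion mutation of the temperature optimum (one step)."""
    if not rule.enabled or rule.sigma == 0 or species.n_populations == 0:
        return
    species.traits["t_opt"] = species.traits["t_opt"] + rng.normal(
        0.0, rule.sigma, species.n_populations
    )


def homogenize_traits(species: SpeciesState, cluster_labels: np.ndarray) -> None:
    """Set every population of a cluster to the cluster's abundance-weighted
    mean temperature optimum (gene flow within connected ranges)."""
    t = species.traits["t_opt"]
    w = np.maximum(species.abundance, 1).astype(float)
    for lab in np.unique(cluster_labels):
        m = cluster_labels == lab
        t[m] = np.average(t[m], weights=w[m])


def niche_abundance(t_opt, site_temp, niche_width: float, a_max: int):
    """Abundance from the temperature-niche match: a linear ramp from a_max
    at a perfect match down to zero at a mismatch of one niche width."""
    if niche_width <= 0:
        raise ValueError("niche width must be positive")
    mismatch = np.abs(np.asarray(t_opt, dtype=float) - np.asarray(site_temp, dtype=float))
    suit = np.maximum(0.0, 1.0 - mismatch / niche_width)
    out = np.rint(a_max * suit).astype(int)
    return out if out.ndim else int(out)


def site_capacity(rule: EcologyRule, temp_norm, aridity):
    """Per-site carrying capacity k.

    Uniform mode: ``k_base`` everywhere.  Energy mode: k scales with
    (temperature × (1 − aridity)) ** k_power, floored at zero."""
    if rule.energy_source == "uniform":
        if np.ndim(temp_norm) == 0:
            return int(rule.k_base)
        return np.full(np.shape(temp_norm), int(rule.k_base))
    t = np.clip(np.nan_to_num(np.asarray(temp_norm, dtype=float)), 0.0, 1.0)
    a = np.clip(np.nan_to_num(np.asarray(aridity, dtype=float)), 0.0, 1.0)
    energy = t * (1.0 - a)
    k = np.rint(rule.k_base * energy**rule.k_power).astype(int)
    k = np.maximum(k, 0)
    return k if k.ndim else int(k)


def apply_carrying_capacity(
    abundances: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Randomly remove individual units across species until the site total
    is at the capacity k (a without-replacement urn: each removed unit is
    drawn uniformly from the remaining individuals).

    Returns the reduced abundance vector; entries hitting zero are local
    extinctions for the caller to apply.
    """
    abundances = np.asarray(abundances, dtype=int)
    if k < 0:
        raise ValueError("capacity must be non-negative")
    total = int(abundances.sum())
    if total <= k:
        return abundances.copy()
    # keeping k of `total` units uniformly without replacement ≡ removing
    # total−k units one at a time uniformly from the remainder
    return rng.multivariate_hypergeometric(abundances, k).astype(int)
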