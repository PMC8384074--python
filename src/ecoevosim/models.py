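"""The five case-study model configurations and parameter-space sampling.

M1  null model: no ecology, no trait evolution, constant divergence rate.
M2  niche conservatism: temperature-niche abundance, Brownian trait evolution.
M3  diversification rates: as M2, with divergence accumulating up to three
    times faster at the warmest sites (power d_power).
M4  carrying capacity: niche ecology plus a uniform per-site cap k.
M5  ecological limits: as M4, but k scales with site energy
    (temperature × (1 − aridity)) ** k_power.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .processes import DispersalKernel, DivergenceRateRule, EcologyRule, EvolutionRule

__all__ = [
    "ModelConfig",
    "ParameterRanges",
    "make_model",
    "sobol_sample",
    "validity_filter",
]


@dataclass
class ModelConfig:
    """Fully wired process bindings and parameters for a simulation."""

    name: str
    divergence_threshold: float  # Ϟ: divergence units needed for cladogenesis
    kernel: DispersalKernel
    evolution: EvolutionRule
    ecology: EcologyRule
    divergence: DivergenceRateRule
    initial_abundance: int = 10
    founder_abundance: int = 5
    trait_names: tuple[str, ...] = ("t_opt",)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["trait_names"] = list(self.trait_names)
        return d


@dataclass
class ParameterRanges:
    """Explored [low, high] bounds per parameter (dispersal shape ɸ and
    scale Ψ km, mutation scale σ, threshold Ϟ, and the two power-law
    modulators)."""

    phi: tuple[float, float] = (2.0, 5.0)
    psi: tuple[float, float] = (550.0, 850.0)
    sigma: tuple[float, float] = (0.001, 0.010)
    threshold: tuple[float, float] = (6.0, 60.0)
    d_power: tuple[float, float] = (2.0, 6.0)
    k_power: tuple[float, float] = (1.0, 4.0)

    def as_dict(self) -> dict[str, tuple[float, float]]:
        d = asdict(self)
        for k, (lo, hi) in d.items():
            if lo > hi:
                raise ValueError(f"range for {k} has low > high")
        return d


# parameters each model actually samples in the factorial exploration
MODEL_FREE_PARAMETERS: dict[str, tuple[str, ...]] = {
    "M1": ("phi", "psi", "threshold"),
    "M2": ("phi", "psi", "threshold", "sigma"),
    "M3": ("phi", "psi", "sigma", "d_power"),
    "M4": ("phi", "psi", "threshold", "sigma", "k_power"),
    "M5": ("phi", "psi", "threshold", "sigma", "k_power"),
}

# full factorial exploration sizes used at coarse resolution (presets only)
EXPLORATION_PRESETS = {"M1": 300, "M2": 780, "M3": 1020, "M4": 300, "M5": 780}

_DEFAULTS = dict(
    phi=2.0,
    psi=700.0,
    sigma=0.005,
    threshold=30.0,
    d_power=4.0,
    k_power=2.0,
    k_base=100,
    a_max=10,
    niche_width=0.1,
)


def make_model(
    name: str,
    allow_out_of_range: bool = False,
    kernel: DispersalKernel | None = None,
    **parameters,
) -> ModelConfig:
    """Build one of the named model configurations M1–M5.

    Keyword parameters: ``phi``, ``psi`` (Weibull dispersal), ``sigma``
    (trait mutation SD), ``threshold`` (Ϟ), ``d_power`` (M3), ``k_power``,
    ``k_base``, ``a_max``, ``niche_width``.  Sampled parameters must lie in
    the declared exploration ranges unless ``allow_out_of_range``.
    """
    name = name.upper()
    if name not in MODEL_FREE_PARAMETERS:
        raise ValueError(f"unknown model {name!r}; expected one of M1..M5")
    p = dict(_DEFAULTS)
    unknown = set(parameters) - set(p)
    if unknown:
        raise ValueError(f"unknown parameters: {sorted(unknown)}")
    p.update(parameters)
    if not allow_out_of_range:
        ranges = ParameterRanges().as_dict()
        for key, (lo, hi) in ranges.items():
            if key in parameters and not lo <= float(parameters[key]) <= hi:
                raise ValueError(f"{key}={parameters[key]} outside declared range [{lo}, {hi}]")
    if name == "M3" and "d_power" not in parameters and "d_power" not in _DEFAULTS:
        raise ValueError("M3 requires d_power")

    kern = kernel or DispersalKernel(family="weibull", shape=p["phi"], scale_km=p["psi"])
    if name == "M1":
        evolution = EvolutionRule(sigma=0.0, homogenize=False, enabled=False)
        ecology = EcologyRule(mode="none", a_max=p["a_max"])
    else:
        evolution = EvolutionRule(sigma=p["sigma"], homogenize=True, enabled=True)
        if name in ("M2", "M3"):
            ecology = EcologyRule(
                mode="niche", niche_width=p["niche_width"], a_max=p["a_max"]
            )
        else:  # M4 / M5
            ecology = EcologyRule(
                mode="niche+capacity",
                niche_width=p["niche_width"],
                a_max=p["a_max"],
                k_base=p["k_base"],
                k_power=p["k_power"],
                energy_source="uniform" if name == "M4" else "temp_aridity",
            )
    if name == "M3":
        divergence = DivergenceRateRule(
            mode="temperature", base_rate=1.0, d_power=p["d_power"], max_multiplier=3.0
        )
    else:
        divergence = DivergenceRateRule(mode="constant", base_rate=1.0)
    return ModelConfig(
        name=name,
        divergence_threshold=float(p["threshold"]),
        kernel=kern,
        evolution=evolution,
        ecology=ecology,
        divergence=divergence,
        initial_abundance=int(p["a_max"]),
        founder_abundance=max(1, round(p["a_max"] / 2)),
    )


def sobol_sample(
    ranges: ParameterRanges | dict,
    n: int,
    seed_policy: str = "fixed",
) -> pd.DataFrame:
    """First n points of an (unscrambled) Sobol sequence mapped to ranges.

    The all-zeros first point of the sequence is skipped; with the default
    fixed seed policy the sample is deterministic and prefix-stable (the
    first n of an (n+m)-sample equal the n-sample).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rd = ranges.as_dict() if isinstance(ranges, ParameterRanges) else dict(ranges)
    names = list(rd)
    if not names:
        raise ValueError("at least one parameter dimension is required")
    if seed_policy != "fixed":
        raise ValueError("only the deterministic 'fixed' seed policy is supported")
    sampler = qmc.Sobol(d=len(names), scramble=False)
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*balance properties.*")
        pts = sampler.random(n + 1)[1:]  # skip the all-zeros point
    lo = np.array([rd[k][0] for k in names])
    hi = np.array([rd[k][1] for k in names])
    return pd.DataFrame(lo + pts * (hi - lo), columns=names)


def validity_filter(
    output,
    min_extant: int = 20,
    max_total_species: int = 50_000,
    max_per_site: int = 10_000,
) -> dict:
    """Case-study validity screen for one finished (or aborted) run.

    A run is retained iff it has at least 20 extant species at the present,
    created fewer than 50,000 species in total, and never had 10,000 or more
    species cohabiting one site.
    """
    extant = output.extant_count()
    total = output.total_species_created()
    peak = output.max_cohabitation()
    flags = {
        "min_richness": extant >= min_extant,
        "global_cap": total < max_total_species,
        "local_cap": peak < max_per_site,
    }
    reasons = [k for k, ok in flags.items() if not ok]
    return {"valid": not reasons, "flags": flags, "reasons": reasons}
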