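"""Synthetic desk-scale landscapes: latitudinal-gradient worlds with
dynamic climates, island-ontogeny sequences, and a two-bank barrier toy.

These generators provide the structure the simulations assume — a
monotone equator-to-pole temperature gradient, a subtropical arid belt,
meridional seaways acting as dispersal barriers, and deep-time temperature
dynamics (a secular cooling trend or an oscillation) — without any external
data.  All generators are pure functions of their spec, so worlds are
hash-stable fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landscape import CostPolicy, DynamicLandscape, EnvironmentalSlice

__all__ = ["WorldSpec", "latitudinal_world", "island_ontogeny", "barrier_toy"]


@dataclass
class WorldSpec:
    """Parameters of a generated world.

    Temperatures are in normalized units (0.01 ≡ 1 °C): the default equator
    value 0.65 and 90°-pole value 0.05 correspond to +30 °C and −30 °C on an
    affine map anchored at −35 °C → 0.  The arid belt is a Gaussian bump in
    |latitude| centred on the subtropics.  ``ocean_columns`` lists grid
    columns that are permanent seaways (non-habitable, costlier to cross);
    sites also drop out of habitability when the local temperature falls
    below ``habitable_min_temp`` (a polar cold limit).  Dynamics add a
    global temperature trend: ``cooling_trend`` ramps down by ``amplitude``
    from the oldest slice to the present; ``oscillation`` is sinusoidal with
    ``oscillation_period`` steps.
    """

    n_lon: int = 24
    n_lat: int = 20
    resolution_deg: float = 5.0
    n_steps: int = 100
    duration_kyr: float = 170.0
    equator_temp: float = 0.65
    pole_temp: float = 0.05
    aridity_center_deg: float = 25.0
    aridity_width_deg: float = 12.0
    aridity_peak: float = 0.8
    ocean_columns: tuple[int, ...] = (7, 15)
    habitable_min_temp: float = 0.25
    dynamics: str = "cooling_trend"  # "static" | "cooling_trend" | "oscillation"
    amplitude: float = 0.10
    oscillation_period: int = 20
    wrap_lon: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lon < 2 or self.n_lat < 2:
            raise ValueError("grid dimensions must be at least 2")
        if not (0 <= self.pole_temp <= 1 and 0 <= self.equator_temp <= 1):
            raise ValueError("normalized temperatures must lie in [0, 1]")
        if self.dynamics not in ("static", "cooling_trend", "oscillation"):
            raise ValueError(f"unknown dynamics {self.dynamics!r}")


def _grid(spec: WorldSpec):
    res = spec.resolution_deg
    lat_centers = (np.arange(spec.n_lat)[::-1] - (spec.n_lat - 1) / 2) * res  # north→south
    lon_centers = (np.arange(spec.n_lon) - (spec.n_lon - 1) / 2) * res
    lons = np.tile(lon_centers, spec.n_lat)
    lats = np.repeat(lat_centers, spec.n_lon)
    return lons, lats


def _offset(spec: WorldSpec, i: int) -> float:
    if spec.dynamics == "static" or spec.n_steps == 1:
        return 0.0
    if spec.dynamics == "cooling_trend":
        return -spec.amplitude * i / (spec.n_steps - 1)
    return spec.amplitude * np.sin(2 * np.pi * i / spec.oscillation_period)


def latitudinal_world(spec: WorldSpec | None = None) -> DynamicLandscape:
    """A latitudinal-gradient world with seaway barriers and climate dynamics.

    Temperature decreases monotonically with |latitude| at every step;
    aridity peaks in the subtropical belt and is ~0 elsewhere.  The dynamics
    are a global additive trend or oscillation; sites colder than the cold
    limit (and the permanent ocean columns) are non-habitable.
    """
    spec = spec or WorldSpec()
    lons, lats = _grid(spec)
    base_temp = spec.equator_temp + (spec.pole_temp - spec.equator_temp) * np.abs(lats) / 90.0
    aridity = spec.aridity_peak * np.exp(
        -(((np.abs(lats) - spec.aridity_center_deg) / spec.aridity_width_deg) ** 2)
    )
    col = np.tile(np.arange(spec.n_lon), spec.n_lat)
    ocean = np.isin(col, spec.ocean_columns)
    slices = []
    for i in range(spec.n_steps):
        temp = base_temp + _offset(spec, i)
        habitable = ~ocean & (temp >= spec.habitable_min_temp)
        t = np.where(habitable, temp, np.nan)
        a = np.where(habitable, np.clip(aridity, 0.0, 1.0), np.nan)
        slices.append(
            EnvironmentalSlice(spec.n_steps - 1 - i, t, a, spec.duration_kyr)
        )
    return DynamicLandscape(
        lons,
        lats,
        slices,
        (spec.n_lat, spec.n_lon),
        wrap_lon=spec.wrap_lon,
        cost_policy=CostPolicy(),
    )


def island_ontogeny(spec: WorldSpec | None = None) -> DynamicLandscape:
    """An oceanic island that grows to a maximum area mid-sequence and then
    shrinks (a triangular ontogeny profile), with a configurable temporal
    temperature variability."""
    spec = spec or WorldSpec(
        n_lon=12, n_lat=12, resolution_deg=1.0, n_steps=41,
        dynamics="oscillation", amplitude=0.05, ocean_columns=(),
        habitable_min_temp=0.0,
    )
    lons, lats = _grid(spec)
    cr, cc = (spec.n_lat - 1) / 2, (spec.n_lon - 1) / 2
    row = np.repeat(np.arange(spec.n_lat), spec.n_lon)
    col = np.tile(np.arange(spec.n_lon), spec.n_lat)
    dist = np.hypot(row - cr, col - cc)
    r_max = min(spec.n_lat, spec.n_lon) / 2.0 - 0.5
    r_min = 1.0
    slices = []
    for i in range(spec.n_steps):
        u = i / (spec.n_steps - 1) if spec.n_steps > 1 else 0.5
        radius = r_min + (r_max - r_min) * (1.0 - abs(2 * u - 1.0))
        habitable = dist <= radius
        temp = spec.equator_temp - 0.02 * dist + _offset(spec, i)
        t = np.where(habitable, np.clip(temp, 0.0, 1.0), np.nan)
        a = np.where(habitable, 0.0, np.nan)
        slices.append(EnvironmentalSlice(spec.n_steps - 1 - i, t, a, spec.duration_kyr))
    return DynamicLandscape(
        lons, lats, slices, (spec.n_lat, spec.n_lon), wrap_lon=False, cost_policy=CostPolicy()
    )


def barrier_toy(n_steps: int = 12) -> DynamicLandscape:
    """A fixed 8×6 two-bank world split by a one-cell-wide river.

    Column 4 is non-habitable water; crossing it costs twice the terrestrial
    rate, so with a clustering distance below the river-crossing cost a
    species on both banks forms exactly two geographic clusters.  The world
    is fully deterministic (no RNG), hence byte-identical across calls.
    """
    spec = WorldSpec(
        n_lon=8,
        n_lat=6,
        resolution_deg=2.0,
        n_steps=n_steps,
        dynamics="static",
        ocean_columns=(4,),
        habitable_min_temp=0.0,
        equator_temp=0.60,
        pole_temp=0.40,
        aridity_peak=0.0,
    )
    return latitudinal_world(spec)
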