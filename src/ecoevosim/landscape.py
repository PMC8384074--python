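"""Dynamic gridded landscapes and connection-cost matrices.

A landscape is a regular lon/lat grid observed at a sequence of time steps
(oldest first, counting down to step 0 = present).  Each slice carries a
temperature and an aridity layer over the habitable sites; habitability is
simply "the environmental layers are defined here" (NaN means uninhabitable).
Connection costs between habitable sites are shortest-path distances on the
8-neighbour grid graph, where hops through non-habitable (aquatic) cells are
penalised by a crossing factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "Site",
    "CostPolicy",
    "EnvironmentalSlice",
    "DynamicLandscape",
    "ConnectionCostMatrix",
    "haversine_distance",
    "build_cost_matrix",
    "load_landscape_series",
    "save_landscape_csv",
    "save_landscape_netcdf",
]


@dataclass(frozen=True)
class Site:
    """One grid cell: a stable integer id plus cell-centre coordinates."""

    id: int
    lon: float
    lat: float


@dataclass
class CostPolicy:
    """How inter-cell hops are priced when building cost matrices.

    ``terrestrial_factor`` multiplies hops between habitable cells,
    ``aquatic_factor`` hops through non-habitable (water) cells — by default
    water is twice as difficult to cross.  ``mode='local'`` truncates the
    matrix at ``local_range_km`` (sparse storage for big worlds).
    """

    terrestrial_factor: float = 1.0
    aquatic_factor: float = 2.0
    mode: str = "full"  # "full" | "local"
    local_range_km: float = 2500.0

    def __post_init__(self) -> None:
        if self.terrestrial_factor <= 0 or self.aquatic_factor <= 0:
            raise ValueError("cost factors must be positive")
        if self.mode not in ("full", "local"):
            raise ValueError(f"unknown cost mode {self.mode!r}")


class EnvironmentalSlice:
    """Environmental layers of the landscape at one time step.

    ``temperature`` is in normalized units (0.01 unit ≡ 1 °C); ``aridity``
    lies in [0, 1].  Both are NaN at non-habitable sites, and habitability
    is derived from that (an explicit mask may be AND-ed in).
    """

    def __init__(
        self,
        step_index: int,
        temperature: np.ndarray,
        aridity: np.ndarray,
        duration_kyr: float = 170.0,
        habitable: np.ndarray | None = None,
    ) -> None:
        temperature = np.asarray(temperature, dtype=float)
        aridity = np.asarray(aridity, dtype=float)
        if temperature.shape != aridity.shape:
            raise ValueError("temperature and aridity must be aligned")
        if duration_kyr <= 0:
            raise ValueError("duration_kyr must be positive")
        ok = np.isfinite(aridity)
        if np.any((aridity[ok] < 0) | (aridity[ok] > 1)):
            raise ValueError("aridity must lie in [0, 1]")
        self.step_index = int(step_index)
        self.duration_kyr = float(duration_kyr)
        mask = np.isfinite(temperature)
        if habitable is not None:
            mask = mask & np.asarray(habitable, dtype=bool)
        self.habitable = mask
        self.temperature = np.where(mask, temperature, np.nan)
        self.aridity = np.where(mask, aridity, np.nan)

    @property
    def n_sites(self) -> int:
        return self.temperature.size

    @property
    def n_habitable(self) -> int:
        return int(self.habitable.sum())


class DynamicLandscape:
    """A site set plus an ordered series of environmental slices.

    Slices are stored oldest → present; ``slices[i].step_index`` counts down
    to 0 at the present.  Sites are row-major over the grid with latitude
    rows ordered from north to south.
    """

    def __init__(
        self,
        lons: np.ndarray,
        lats: np.ndarray,
        slices: list[EnvironmentalSlice],
        shape: tuple[int, int],
        wrap_lon: bool = False,
        cost_policy: CostPolicy | None = None,
    ) -> None:
        self.lons = np.asarray(lons, dtype=float)
        self.lats = np.asarray(lats, dtype=float)
        if not (np.isfinite(self.lons).all() and np.isfinite(self.lats).all()):
            raise ValueError("site coordinates must be finite")
        if not slices:
            raise ValueError("a landscape needs at least one slice")
        n = self.lons.size
        for sl in slices:
            if sl.n_sites != n:
                raise ValueError("every slice must reference the same site set")
        self.slices = list(slices)
        self.shape = (int(shape[0]), int(shape[1]))  # (n_rows=lat, n_cols=lon)
        if self.shape[0] * self.shape[1] != n:
            raise ValueError("shape does not match the number of sites")
        self.wrap_lon = bool(wrap_lon)
        self.cost_policy = cost_policy or CostPolicy()
        self._adjacency_cache: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    @property
    def n_sites(self) -> int:
        return self.lons.size

    @property
    def n_steps(self) -> int:
        return len(self.slices)

    @property
    def sites(self) -> list[Site]:
        return [Site(i, float(lo), float(la)) for i, (lo, la) in enumerate(zip(self.lons, self.lats))]

    def slice_at_step(self, step: int) -> EnvironmentalSlice:
        for sl in self.slices:
            if sl.step_index == step:
                return sl
        raise KeyError(f"no slice with step_index {step}")

    @property
    def cell_area_km2(self) -> np.ndarray:
        """Spherical cell areas from grid spacing (km²)."""
        n_rows, n_cols = self.shape
        lat_rows = self.lats.reshape(n_rows, n_cols)[:, 0]
        dlat = abs(float(np.diff(np.unique(self.lats)).min())) if n_rows > 1 else 1.0
        lons_row = self.lons.reshape(n_rows, n_cols)[0]
        dlon = abs(float(np.diff(np.unique(lons_row)).min())) if n_cols > 1 else 1.0
        top = np.radians(lat_rows + dlat / 2)
        bot = np.radians(lat_rows - dlat / 2)
        row_area = EARTH_RADIUS_KM**2 * math.radians(dlon) * (np.sin(top) - np.sin(bot))
        return np.repeat(np.abs(row_area), n_cols)

    # -- grid graph -------------------------------------------------------

    def _grid_adjacency(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Undirected 8-neighbour edges (i, j, hop length in km)."""
        if self._adjacency_cache is not None:
            return self._adjacency_cache
        n_rows, n_cols = self.shape
        idx = np.arange(self.n_sites).reshape(n_rows, n_cols)
        src, dst = [], []
        offsets = [(0, 1), (1, 0), (1, 1), (1, -1)]  # each undirected pair once
        for dr, dc in offsets:
            rows = np.arange(n_rows - dr)
            if dc >= 0:
                cols = np.arange(n_cols - dc) if not self.wrap_lon else np.arange(n_cols)
            else:
                cols = np.arange(-dc, n_cols) if not self.wrap_lon else np.arange(n_cols)
            rr, cc = np.meshgrid(rows, cols, indexing="ij")
            src.append(idx[rr, cc].ravel())
            dst.append(idx[(rr + dr) % n_rows, (cc + dc) % n_cols].ravel())
        i = np.concatenate(src)
        j = np.concatenate(dst)
        keep = i != j
        i, j = i[keep], j[keep]
        length = haversine_distance(self.lons[i], self.lats[i], self.lons[j], self.lats[j])
        self._adjacency_cache = (i, j, length)
        return self._adjacency_cache


def haversine_distance(a, b, c=None, d=None) -> np.ndarray | float:
    """Great-circle distance in km (Earth radius 6371 km).

    Accepts either two :class:`Site` objects or four arrays
    ``(lon1, lat1, lon2, lat2)`` in decimal degrees.
    """
    if isinstance(a, Site) and isinstance(b, Site):
        lon1, lat1, lon2, lat2 = a.lon, a.lat, b.lon, b.lat
    else:
        lon1, lat1, lon2, lat2 = a, b, c, d
    lon1, lat1, lon2, lat2 = (np.asarray(x, dtype=float) for x in (lon1, lat1, lon2, lat2))
    if not all(np.isfinite(x).all() for x in (lon1, lat1, lon2, lat2)):
        raise ValueError("coordinates must be finite")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    out = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return float(out) if out.ndim == 0 else out


class ConnectionCostMatrix:
    """Pairwise connection costs (km-equivalents) over habitable sites.

    Stored dense over the habitable subset with ``inf`` marking pairs that
    are unreachable or beyond the local range.  Symmetric, zero diagonal.
    """

    def __init__(self, site_ids: np.ndarray, costs: np.ndarray) -> None:
        self.site_ids = np.asarray(site_ids, dtype=int)
        self.costs = np.asarray(costs, dtype=float)
        self._index = {int(s): k for k, s in enumerate(self.site_ids)}

    @property
    def n(self) -> int:
        return self.site_ids.size

    def cost(self, i: int, j: int) -> float:
        return float(self.costs[self._index[int(i)], self._index[int(j)]])

    def submatrix(self, rows: np.ndarray, cols: np.ndarray | None = None) -> np.ndarray:
        """Dense cost block for site-id arrays (inf where no entry)."""
        try:
            r = np.fromiter((self._index[int(s)] for s in rows), dtype=int, count=len(rows))
            c = (
                r
                if cols is None
                else np.fromiter((self._index[int(s)] for s in cols), dtype=int, count=len(cols))
            )
        except KeyError as exc:  # occupied site missing from the matrix
            raise KeyError(f"site {exc} absent from cost matrix") from exc
        return self.costs[np.ix_(r, c)]

    def to_coo_frame(self) -> pd.DataFrame:
        """Sparse text export: one row per finite off-diagonal pair (i<j)."""
        iu, ju = np.triu_indices(self.n, k=1)
        fin = np.isfinite(self.costs[iu, ju])
        return pd.DataFrame(
            {
                "i": self.site_ids[iu[fin]],
                "j": self.site_ids[ju[fin]],
                "cost_km": self.costs[iu[fin], ju[fin]],
            }
        )


def build_cost_matrix(
    landscape: DynamicLandscape,
    slice_: EnvironmentalSlice,
    policy: CostPolicy | None = None,
) -> ConnectionCostMatrix:
    """Shortest-path connection costs between habitable sites of one slice.

    Each undirected grid hop costs its great-circle length times the mean of
    the two endpoint crossing factors (aquatic cells are pricier), and pair
    costs are Dijkstra shortest paths over that graph.  Averaging endpoint
    factors keeps the matrix exactly symmetric while reproducing the usual
    corridor accounting (land→water→land = d·2 + d·1 on either reading).
    """
    policy = policy or landscape.cost_policy
    hab = slice_.habitable
    site_ids = np.flatnonzero(hab)
    if site_ids.size == 0:
        return ConnectionCostMatrix(site_ids, np.zeros((0, 0)))
    i, j, length = landscape._grid_adjacency()
    factor = np.where(hab, policy.terrestrial_factor, policy.aquatic_factor)
    w = length * 0.5 * (factor[i] + factor[j])
    n = landscape.n_sites
    graph = coo_matrix((w, (i, j)), shape=(n, n)).tocsr()
    limit = policy.local_range_km if policy.mode == "local" else np.inf
    dist = dijkstra(graph, directed=False, indices=site_ids, limit=limit)
    costs = dist[:, site_ids]
    costs = 0.5 * (costs + costs.T)  # guard against float asymmetry
    np.fill_diagonal(costs, 0.0)
    return ConnectionCostMatrix(site_ids, costs)


# -- I/O -------------------------------------------------------------------

_CSV_COLUMNS = ["site_id", "lon", "lat", "step", "temperature", "aridity"]


def _grid_from_frame(frame: pd.DataFrame):
    sites = frame[["site_id", "lon", "lat"]].drop_duplicates().sort_values("site_id")
    if sites["site_id"].duplicated().any():
        raise ValueError("inconsistent lon/lat for a site_id across slices")
    lats_u = np.sort(sites["lat"].unique())[::-1]  # north → south rows
    lons_u = np.sort(sites["lon"].unique())
    n_rows, n_cols = lats_u.size, lons_u.size
    if n_rows * n_cols != len(sites):
        raise ValueError("sites do not form a complete regular grid")
    order = np.lexsort((sites["lon"].to_numpy(), -sites["lat"].to_numpy()))
    ids = sites["site_id"].to_numpy()[order]
    expected = np.arange(len(sites))
    if not np.array_equal(np.sort(ids), expected):
        raise ValueError("site ids must be 0..n-1")
    if not np.array_equal(ids, expected):
        raise ValueError("site ids must be row-major (north→south, west→east)")
    lons = np.tile(lons_u, n_rows)
    lats = np.repeat(lats_u, n_cols)
    return lons, lats, (n_rows, n_cols)


def load_landscape_series(
    source,
    wrap_lon: bool = False,
    cost_policy: CostPolicy | None = None,
    duration_kyr: float = 170.0,
) -> DynamicLandscape:
    """Load a landscape time series from long-format CSV, netCDF, or a DataFrame.

    CSV columns: ``site_id,lon,lat,step,temperature,aridity`` with ``step``
    the step index (0 = present, larger = older).  Sites absent from a step,
    or with missing temperature, are non-habitable at that step only.
    """
    if isinstance(source, pd.DataFrame):
        frame = source.copy()
    else:
        path = Path(source)
        if path.suffix in (".nc", ".cdf", ".netcdf"):
            return _load_netcdf(path, wrap_lon, cost_policy, duration_kyr)
        frame = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"landscape table missing columns: {missing}")
    lons, lats, shape = _grid_from_frame(frame)
    n = lons.size
    steps = np.sort(frame["step"].unique().astype(int))[::-1]  # oldest first
    slices = []
    for s in steps:
        sub = frame[frame["step"] == s]
        temp = np.full(n, np.nan)
        arid = np.full(n, np.nan)
        temp[sub["site_id"].to_numpy(int)] = sub["temperature"].to_numpy(float)
        arid[sub["site_id"].to_numpy(int)] = sub["aridity"].to_numpy(float)
        slices.append(EnvironmentalSlice(int(s), temp, arid, duration_kyr))
    return DynamicLandscape(lons, lats, slices, shape, wrap_lon=wrap_lon, cost_policy=cost_policy)


def _load_netcdf(path, wrap_lon, cost_policy, duration_kyr):
    import xarray as xr

    ds = xr.open_dataset(path, engine="scipy")
    for var in ("temperature", "aridity"):
        if var not in ds:
            raise ValueError(f"netCDF landscape missing layer {var!r}")
    steps = np.asarray(ds["step"].values, dtype=int)
    order = np.argsort(steps)[::-1]
    lats = np.sort(np.asarray(ds["lat"].values, dtype=float))[::-1]
    lons = np.sort(np.asarray(ds["lon"].values, dtype=float))
    t = ds["temperature"].sel(lat=lats, lon=lons).transpose("step", "lat", "lon").values
    a = ds["aridity"].sel(lat=lats, lon=lons).transpose("step", "lat", "lon").values
    slices = [
        EnvironmentalSlice(int(steps[k]), t[k].ravel(), a[k].ravel(), duration_kyr)
        for k in order
    ]
    shape = (lats.size, lons.size)
    full_lons = np.tile(lons, lats.size)
    full_lats = np.repeat(lats, lons.size)
    ds.close()
    return DynamicLandscape(full_lons, full_lats, slices, shape, wrap_lon=wrap_lon, cost_policy=cost_policy)


def landscape_to_frame(landscape: DynamicLandscape) -> pd.DataFrame:
    """Long-format table of every site at every slice (missing environmental
    values mark non-habitable sites, so the grid round-trips exactly)."""
    rows = []
    ids = np.arange(landscape.n_sites)
    for sl in landscape.slices:
        rows.append(
            pd.DataFrame(
                {
                    "site_id": ids,
                    "lon": landscape.lons,
                    "lat": landscape.lats,
                    "step": sl.step_index,
                    "temperature": sl.temperature,
                    "aridity": sl.aridity,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def save_landscape_csv(landscape: DynamicLandscape, path) -> None:
    landscape_to_frame(landscape).to_csv(path, index=False)


def save_landscape_netcdf(landscape: DynamicLandscape, path) -> None:
    import xarray as xr

    n_rows, n_cols = landscape.shape
    lats = landscape.lats.reshape(n_rows, n_cols)[:, 0]
    lons = landscape.lons.reshape(n_rows, n_cols)[0]
    steps = [sl.step_index for sl in landscape.slices]
    temp = np.stack([sl.temperature.reshape(n_rows, n_cols) for sl in landscape.slices])
    arid = np.stack([sl.aridity.reshape(n_rows, n_cols) for sl in landscape.slices])
    ds = xr.Dataset(
        {
            "temperature": (("step", "lat", "lon"), temp),
            "aridity": (("step", "lat", "lon"), arid),
        },
        coords={"step": steps, "lat": lats, "lon": lons},
    )
    ds.to_netcdf(path, engine="scipy")
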