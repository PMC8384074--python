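"""Pattern-oriented summary statistics for confronting simulations with
biodiversity data.

Implements the latitudinal diversity gradient slope (percent richness loss
per degree of latitude) and curve correlation, the maximum-likelihood
estimate of Aldous' β-splitting tree-imbalance statistic, the normalized
lineage-through-time (nLTT) curve difference, range-size distributions, and
latitude-band event rates, together with the combined pattern-oriented
acceptance verdict.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp

__all__ = [
    "RichnessMap",
    "PomCriteria",
    "RangeSizeStats",
    "ldg_percent_loss",
    "ldg_curve_correlation",
    "beta_splitting_ml",
    "nltt_difference",
    "range_size_stats",
    "band_rates",
    "pom_acceptance",
]

TROPIC_DEG = 23.45  # 23°27′
POLAR_DEG = 66.55  # 66°33′


@dataclass
class RichnessMap:
    """Per-site species counts at one step, with site coordinates."""

    counts: np.ndarray
    lats: np.ndarray
    lons: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.lats = np.asarray(self.lats, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("richness counts must be non-negative")


@dataclass
class PomCriteria:
    """Acceptance windows for the pattern-oriented screen."""

    ldg_range: tuple[float, float] = (1.1, 5.4)  # %/degree
    beta_range: tuple[float, float] = (-1.4, -0.3)
    ldg_curve_r_min: float = 0.4
    nltt_max: float = 0.15
    range_decrease_tolerance: float = 0.05
    min_extant: int = 20


def _infer_band_deg(lats: np.ndarray) -> float:
    u = np.unique(lats)
    return float(np.diff(u).min()) if u.size > 1 else 1.0


def _band_means(counts, lats, band_deg, absolute=True):
    x = np.abs(lats) if absolute else lats
    band = np.floor(x / band_deg).astype(int)
    frame = pd.DataFrame({"band": band, "richness": counts})
    g = frame.groupby("band")["richness"].mean()
    centers = (g.index.to_numpy() + 0.5) * band_deg
    return centers, g.to_numpy(dtype=float)


def ldg_percent_loss(map_: RichnessMap, band_deg: float | None = None) -> float:
    """Latitudinal diversity gradient as % richness loss per degree.

    Mean richness per |latitude| band is normalized by its maximum and
    regressed on band latitude by ordinary least squares; the statistic is
    −slope × 100, positive when richness declines poleward.
    """
    counts = np.asarray(map_.counts, dtype=float)
    if counts.sum() == 0:
        raise ValueError("richness is zero everywhere; LDG undefined")
    band_deg = band_deg or _infer_band_deg(map_.lats)
    centers, means = _band_means(counts, map_.lats, band_deg)
    if centers.size < 2:
        raise ValueError("need at least two latitude bands")
    y = means / means.max()
    slope = np.polyfit(centers, y, 1)[0]
    return float(-slope * 100.0)


def ldg_curve_correlation(
    map_: RichnessMap,
    reference_curve,
    band_deg: float | None = None,
    habitable_per_band: np.ndarray | None = None,
) -> float:
    """Pearson correlation of the standardized, area-scaled mean species
    number per latitude band against a reference curve.

    ``reference_curve`` is an array aligned to the map's latitude bands
    (south to north), or a mapping band-center → value.  Band richness is
    divided by the habitable-site count of the band (area scaling; by
    default every mapped site counts as habitable) and scaled to max 1.
    """
    band_deg = band_deg or _infer_band_deg(map_.lats)
    band = np.floor(map_.lats / band_deg).astype(int)
    frame = pd.DataFrame({"band": band, "richness": np.asarray(map_.counts, dtype=float)})
    g = frame.groupby("band")["richness"].agg(["sum", "count"])
    if habitable_per_band is not None:
        g["count"] = np.asarray(habitable_per_band, dtype=float)
    curve = (g["sum"] / g["count"]).to_numpy(dtype=float)
    if curve.max() > 0:
        curve = curve / curve.max()
    if isinstance(reference_curve, dict):
        centers = (g.index.to_numpy() + 0.5) * band_deg
        ref = np.array([reference_curve.get(round(float(c), 6), np.nan) for c in centers])
    else:
        ref = np.asarray(reference_curve, dtype=float)
        if ref.size != curve.size:
            raise ValueError("reference curve length must match the band count")
    ok = np.isfinite(ref) & np.isfinite(curve)
    if ok.sum() < 3:
        raise ValueError("need at least three common latitude bands")
    r = np.corrcoef(curve[ok], ref[ok])[0, 1]
    return float(r)


# -- tree statistics -------------------------------------------------------


def _as_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=str(tree), schema="newick")


def _split_sizes(tree: dendropy.Tree) -> list[tuple[int, int]]:
    """(clade size n, left-child size i) for every internal node, with
    polytomies resolved arbitrarily (a warning is emitted)."""
    t = tree.clone(depth=1)
    if any(len(nd.child_nodes()) > 2 for nd in t.preorder_internal_node_iter()):
        warnings.warn("polytomies resolved arbitrarily for the β-splitting statistic")
        t.resolve_polytomies()
    out = []
    sizes: dict = {}
    for nd in t.postorder_node_iter():
        kids = nd.child_nodes()
        if not kids:
            sizes[nd] = 1
            continue
        sizes[nd] = sum(sizes[k] for k in kids)
        if len(kids) == 2 and sizes[nd] >= 3:
            out.append((sizes[nd], sizes[kids[0]]))
        elif len(kids) == 2:
            out.append((sizes[nd], sizes[kids[0]]))
    return out


def beta_splitting_ml(tree, lo: float = -1.99, hi: float = 10.0) -> float:
    """Maximum-likelihood β of Aldous' beta-splitting model for a tree.

    For an internal node with n descendant tips split i | n−i, the split
    probability is q_β(i|n) ∝ Γ(β+i+1)Γ(β+n−i+1) / [Γ(i+1)Γ(n−i+1)],
    normalized over i = 1..n−1.  The log-likelihood sums over internal
    nodes and is maximized by bounded one-dimensional search over (−2, 10].
    β = 0 corresponds to Yule trees; more negative is more imbalanced.
    """
    splits = _split_sizes(_as_tree(tree))
    splits = [(n, i) for n, i in splits if n >= 2]
    if not splits or max(n for n, _ in splits) < 3:
        raise ValueError("β-splitting needs a tree with at least 3 tips")
    ns = np.array([n for n, _ in splits])
    iss = np.array([i for _, i in splits])

    uniq_n = np.unique(ns)

    def negloglik(beta: float) -> float:
        num = (
            gammaln(beta + iss + 1)
            + gammaln(beta + ns - iss + 1)
            - gammaln(iss + 1.0)
            - gammaln(ns - iss + 1.0)
        )
        norm = np.empty_like(num)
        lookup = {}
        for n in uniq_n:
            i_all = np.arange(1, n)
            terms = (
                gammaln(beta + i_all + 1)
                + gammaln(beta + n - i_all + 1)
                - gammaln(i_all + 1.0)
                - gammaln(n - i_all + 1.0)
            )
            lookup[n] = logsumexp(terms)
        for j, n in enumerate(ns):
            norm[j] = lookup[n]
        return float(-(num - norm).sum())

    res = minimize_scalar(negloglik, bounds=(lo, hi), method="bounded")
    return float(res.x)


def _ltt_events(tree: dendropy.Tree) -> tuple[np.ndarray, float, int]:
    """Internal-node times from the lineage start (stem origin if the tree
    has a root edge, else the root split at t=0), the total time span, and
    the tip count."""
    t = _as_tree(tree)
    t.calc_node_ages(ultrametricity_precision=False, is_force_max_age=True)
    root = t.seed_node
    stem = root.edge.length or 0.0
    root_age = root.age
    events = []
    for nd in t.preorder_internal_node_iter():
        events.append(stem + (root_age - nd.age))
    span = stem + root_age
    n_tips = len(t.leaf_nodes())
    if span <= 0:
        raise ValueError("tree has zero depth")
    return np.sort(np.asarray(events)), span, n_tips


def nltt_difference(tree_a, tree_b) -> float:
    """Normalized lineage-through-time curve difference in [0, 1].

    Both LTT curves are normalized to time in [0, 1] (lineage origin →
    present) and lineage count in (0, 1] (divided by the final count); the
    statistic integrates |f_a − f_b| over the merged step grid.
    """
    ea, sa, na = _ltt_events(_as_tree(tree_a))
    eb, sb, nb = _ltt_events(_as_tree(tree_b))
    if na < 2 or nb < 2:
        raise ValueError("nLTT needs trees with at least 2 tips")
    ta, tb = ea / sa, eb / sb

    def f(times, n, t):
        return (1 + np.searchsorted(times, t, side="right")) / n

    grid = np.unique(np.concatenate([ta, tb, [0.0, 1.0]]))
    grid = grid[(grid >= 0) & (grid <= 1)]
    total = 0.0
    for left, right in zip(grid[:-1], grid[1:]):
        fa = f(ta, na, left)
        fb = f(tb, nb, left)
        total += abs(fa - fb) * (right - left)
    return float(total)


@dataclass
class RangeSizeStats:
    bin_edges_km2: np.ndarray
    frequencies: np.ndarray
    srd_slope: float
    monotone_decrease_ok: bool


def range_size_stats(
    range_sizes_km2: np.ndarray,
    tolerance: float = 0.05,
) -> RangeSizeStats:
    """Range-size histogram over octave (log₂) bins plus the SRD slope.

    The species-range-decrease slope is the OLS slope of log₁₀(frequency+1)
    on the octave-bin midpoint.  The monotone-decrease check allows each bin
    to exceed its left neighbour by at most ``tolerance`` of the total
    species count.
    """
    sizes = np.asarray(range_sizes_km2, dtype=float)
    sizes = sizes[sizes > 0]
    if sizes.size == 0:
        raise ValueError("no ranges supplied")
    lo = sizes.min()
    octave = np.floor(np.log2(sizes / lo) + 1e-9).astype(int)
    n_bins = octave.max() + 1
    freq = np.bincount(octave, minlength=n_bins).astype(float)
    edges = lo * 2.0 ** np.arange(n_bins + 1)
    if n_bins >= 2:
        x = np.arange(n_bins) + 0.5
        slope = float(np.polyfit(x, np.log10(freq + 1.0), 1)[0])
    else:
        slope = 0.0
    tol = tolerance * sizes.size
    ok = all(freq[j] <= freq[j - 1] + tol for j in range(1, n_bins))
    return RangeSizeStats(edges, freq, slope, bool(ok))


def _band_label(lat: float, tropic: float = TROPIC_DEG, polar: float = POLAR_DEG) -> str:
    a = abs(lat)
    if a <= tropic:
        return "low"
    if a <= polar:
        return "high"
    return "polar"


def band_rates(
    genealogy,
    migrations: pd.DataFrame,
    duration_kyr: float = 170.0,
    window_myr: float = 1.0,
    tropic: float = TROPIC_DEG,
    polar: float = POLAR_DEG,
) -> pd.DataFrame:
    """Speciation/extinction counts per latitude band and directional
    migration counts per band pair, binned into 1-Myr windows.

    Bands follow the tropics (|lat| ≤ 23°27′) / high latitudes (up to
    66°33′) split; migrations are colonizations whose source and target
    fall in different bands.
    """
    rows = []
    myr_per_step = duration_kyr / 1000.0

    def window(step: int) -> int:
        return int(np.floor(step * myr_per_step / window_myr))

    for child, _parent, step, lat in genealogy.splits:
        rows.append((window(step), "speciation", _band_label(lat, tropic, polar), 1))
    for _sp, step, lat in genealogy.extinctions:
        rows.append((window(step), "extinction", _band_label(lat, tropic, polar), 1))
    if len(migrations):
        for _, m in migrations.iterrows():
            src = _band_label(float(m["source_lat"]), tropic, polar)
            tgt = _band_label(float(m["target_lat"]), tropic, polar)
            if src != tgt:
                rows.append((window(int(m["step"])), "migration", f"{src}->{tgt}", 1))
    if not rows:
        return pd.DataFrame(columns=["window_myr", "event", "band", "count"])
    frame = pd.DataFrame(rows, columns=["window_myr", "event", "band", "count"])
    return (
        frame.groupby(["window_myr", "event", "band"], as_index=False)["count"]
        .sum()
        .sort_values(["window_myr", "event", "band"], ignore_index=True)
    )


def pom_acceptance(bundle: dict, criteria: PomCriteria | None = None) -> dict:
    """Apply the pattern-oriented acceptance screen to a statistics bundle.

    ``bundle`` keys: ``ldg_percent_loss``, ``beta``, ``range_monotone_ok``,
    ``curve_r``, ``nltt``, ``extant``.  A missing or None statistic fails
    its criterion with a reason.  The combined verdict requires every
    criterion to pass.
    """
    c = criteria or PomCriteria()
    flags: dict[str, bool] = {}
    reasons: dict[str, str] = {}

    def check(key, fn, reason_if_missing="statistic unavailable"):
        val = bundle.get(key)
        if val is None:
            flags[key] = False
            reasons[key] = reason_if_missing
        else:
            flags[key] = bool(fn(val))

    check("ldg_percent_loss", lambda v: c.ldg_range[0] <= v <= c.ldg_range[1])
    check("beta", lambda v: c.beta_range[0] <= v <= c.beta_range[1])
    check("range_monotone_ok", bool)
    check("curve_r", lambda v: v > c.ldg_curve_r_min)
    check("nltt", lambda v: v < c.nltt_max)
    check("extant", lambda v: v >= c.min_extant)
    return {"flags": flags, "reasons": reasons, "combined": all(flags.values())}
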