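import math
import random

import dendropy
import numpy as np
import pandas as pd
import pytest

from ecoevosim.species import Genealogy
from ecoevosim.stats import (
    PomCriteria,
    RichnessMap,
    band_rates,
    beta_splitting_ml,
    ldg_curve_correlation,
    ldg_percent_loss,
    nltt_difference,
    pom_acceptance,
    range_size_stats,
)


def caterpillar_newick(n):
    s = "t0:1"
    for i in range(1, n):
        s = f"({s},t{i}:1):1"
    return s + ";"


def balanced_newick(depth):
    def rec(d, pre):
        if d == 0:
            return f"{pre}:1"
        return f"({rec(d - 1, pre + '0')},{rec(d - 1, pre + '1')}):1"

    return rec(depth, "t") + ";"


class TestLdgPercentLoss:
    def test_uniform_richness_has_zero_slope(self):
        lats = np.repeat(np.arange(-45.0, 50.0, 10.0), 3)
        assert ldg_percent_loss(RichnessMap(np.full(lats.size, 7), lats)) == pytest.approx(0.0)

    def test_linear_decline_recovers_one_percent_per_degree(self):
        lats = np.arange(-50.0, 51.0)
        counts = 100.0 - np.abs(lats)
        got = ldg_percent_loss(RichnessMap(counts, lats), band_deg=1.0)
        assert got == pytest.approx(1.0, abs=1e-9)

    def test_invariant_to_rescaling_richness(self):
        lats = np.repeat(np.arange(-47.5, 50.0, 5.0), 4)
        counts = np.maximum(0.0, 80.0 - np.abs(lats))
        a = ldg_percent_loss(RichnessMap(counts, lats))
        b = ldg_percent_loss(RichnessMap(counts * 13, lats))
        assert a == pytest.approx(b)

    def test_invariant_to_shuffling_within_bands(self, rng):
        lats = np.repeat(np.arange(-47.5, 50.0, 5.0), 6)
        counts = rng.integers(0, 50, lats.size).astype(float)
        a = ldg_percent_loss(RichnessMap(counts, lats))
        # shuffle counts among sites of the same |lat| band
        band = np.floor(np.abs(lats) / 5.0).astype(int)
        shuffled = counts.copy()
        for b in np.unique(band):
            idx = np.flatnonzero(band == b)
            shuffled[idx] = shuffled[rng.permutation(idx)]
        assert ldg_percent_loss(RichnessMap(shuffled, lats)) == pytest.approx(a)

    def test_all_zero_richness_signalled(self):
        with pytest.raises(ValueError, match="undefined"):
            ldg_percent_loss(RichnessMap(np.zeros(10), np.linspace(-40, 40, 10)))


class TestLdgCurveCorrelation:
    def _map(self):
        lats = np.repeat([-20.0, -10.0, 0.0, 10.0, 20.0], 4)
        counts = np.repeat([2.0, 5.0, 9.0, 5.0, 2.0], 4)
        return RichnessMap(counts, lats)

    def test_self_reference_gives_one(self):
        m = self._map()
        assert ldg_curve_correlation(m, [2, 5, 9, 5, 2]) == pytest.approx(1.0)

    def test_negated_reference_gives_minus_one(self):
        m = self._map()
        assert ldg_curve_correlation(m, [-2, -5, -9, -5, -2]) == pytest.approx(-1.0)

    def test_matches_textbook_pearson_formula(self):
        m = self._map()
        ref = np.array([1.0, 4.0, 7.0, 6.0, 3.0])
        got = ldg_curve_correlation(m, ref)
        curve = np.array([2, 5, 9, 5, 2]) / 9.0
        x, y = curve - curve.mean(), ref - ref.mean()
        expected = (x * y).sum() / math.sqrt((x**2).sum() * (y**2).sum())
        assert got == pytest.approx(expected)

    def test_too_few_bands_rejected(self):
        m = RichnessMap(np.array([1.0, 2.0]), np.array([0.0, 10.0]))
        with pytest.raises(ValueError):
            ldg_curve_correlation(m, [1.0, 2.0])


class TestBetaSplitting:
    def test_caterpillar_is_strongly_imbalanced(self):
        assert beta_splitting_ml(caterpillar_newick(64)) < -1.5

    def test_fully_balanced_tree_is_positive(self):
        assert beta_splitting_ml(balanced_newick(6)) > 0.0

    def test_matches_brute_force_grid_oracle(self, rng):
        """The bounded 1-D search lands on the grid argmax of an
        independently coded beta-splitting log-likelihood."""
        from scipy.special import gammaln

        def loglik_naive(newick, beta):
            tree = dendropy.Tree.get(data=newick, schema="newick")
            total = 0.0
            for nd in tree.postorder_internal_node_iter():
                kids = nd.child_nodes()
                n = sum(1 for _ in nd.leaf_iter())
                i = sum(1 for _ in kids[0].leaf_iter())
                if n < 3:
                    continue
                num = (
                    gammaln(beta + i + 1) + gammaln(beta + n - i + 1)
                    - gammaln(i + 1) - gammaln(n - i + 1)
                )
                terms = [
                    gammaln(beta + k + 1) + gammaln(beta + n - k + 1)
                    - gammaln(k + 1) - gammaln(n - k + 1)
                    for k in range(1, n)
                ]
                m = max(terms)
                norm = m + math.log(sum(math.exp(t - m) for t in terms))
                total += num - norm
            return total

        for seed in (0, 1, 2):
            t = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, num_extant_tips=24, rng=random.Random(seed)
            )
            nwk = t.as_string(schema="newick")
            grid = np.arange(-1.99, 10.0, 0.02)
            vals = [loglik_naive(nwk, b) for b in grid]
            oracle = grid[int(np.argmax(vals))]
            assert beta_splitting_ml(nwk) == pytest.approx(oracle, abs=0.05)

    def test_median_consistent_on_trees_simulated_at_known_beta(self, rng):
        """Trees generated directly from the beta-splitting Markov branching
        model at β = −1: the median of β̂ must recover the generating value
        (the per-tree MLE is median-consistent; its mean is right-skewed on
        small trees)."""
        from scipy.special import gammaln

        beta_true = -1.0

        def simulate(n):
            counter = [0]

            def split_probs(m):
                i = np.arange(1, m)
                logw = (
                    gammaln(m + 1) - gammaln(i + 1) - gammaln(m - i + 1)
                    + gammaln(beta_true + i + 1) + gammaln(beta_true + m - i + 1)
                )
                w = np.exp(logw - logw.max())
                return w / w.sum()

            def rec(m):
                if m == 1:
                    counter[0] += 1
                    return f"t{counter[0]}:1"
                i = int(rng.choice(np.arange(1, m), p=split_probs(m)))
                return f"({rec(i)},{rec(m - i)}):1"

            return rec(n) + ";"

        est = [beta_splitting_ml(simulate(64)) for _ in range(60)]
        assert np.median(est) == pytest.approx(beta_true, abs=0.3)

    def test_invariant_to_relabeling_and_branch_rescaling(self):
        a = "((A:1,B:1):1,((C:1,D:1):1,E:2):1);"
        b = "((E:9,(D:3,C:3):3):3,(B:3,A:3):3);"  # relabeled + rescaled mirror
        assert beta_splitting_ml(a) == pytest.approx(beta_splitting_ml(b), abs=1e-6)

    def test_tiny_tree_rejected(self):
        with pytest.raises(ValueError):
            beta_splitting_ml("(a:1,b:1);")


class TestNltt:
    def test_identical_trees_give_zero(self):
        t = "((a:0.2,b:0.2):0.6,c:0.8):0.2;"
        assert nltt_difference(t, t) == 0.0

    def test_symmetric_in_arguments(self):
        a = "((a:0.2,b:0.2):0.6,c:0.8):0.2;"
        b = "((a:0.1,b:0.1):0.4,c:0.5):0.5;"
        assert nltt_difference(a, b) == pytest.approx(nltt_difference(b, a))

    def test_hand_computed_three_tip_example(self):
        """Events at (0.2, 0.8) vs (0.5, 0.9) on unit-depth trees:
        ∫|Δf| = (1/3)(0.5−0.2) + (1/3)(0.9−0.8) = 0.13333."""
        a = "((a:0.2,b:0.2):0.6,c:0.8):0.2;"
        b = "((a:0.1,b:0.1):0.4,c:0.5):0.5;"
        assert nltt_difference(a, b) == pytest.approx(2 / 15, abs=1e-9)

    def test_bounded_on_random_tree_pairs(self):
        for seed in range(10):
            r = random.Random(seed)
            trees = [
                dendropy.simulate.treesim.birth_death_tree(
                    birth_rate=1.0, death_rate=0.0, num_extant_tips=r.randint(5, 40), rng=r
                )
                for _ in range(2)
            ]
            d = nltt_difference(*trees)
            assert 0.0 <= d <= 1.0


class TestRangeSizeStats:
    def test_all_single_site_species_pass(self):
        rs = range_size_stats(np.full(10, 50_000.0))
        assert rs.frequencies.tolist() == [10.0]
        assert rs.monotone_decrease_ok

    def test_decreasing_octaves_pass_with_negative_slope(self):
        sizes = np.concatenate(
            [np.full(10, 1.0), np.full(5, 2.5), np.full(2, 5.0), np.full(1, 10.0)]
        )
        rs = range_size_stats(sizes)
        assert rs.frequencies.tolist() == [10.0, 5.0, 2.0, 1.0]
        x = np.arange(4) + 0.5
        y = np.log10(rs.frequencies + 1)
        expected = np.polyfit(x, y, 1)[0]
        assert rs.srd_slope == pytest.approx(expected)
        assert rs.srd_slope < 0
        assert rs.monotone_decrease_ok

    def test_increase_beyond_tolerance_fails(self):
        sizes = np.concatenate([np.full(5, 1.0), np.full(5, 2.5), np.full(10, 5.0)])
        rs = range_size_stats(sizes)
        assert rs.frequencies.tolist() == [5.0, 5.0, 10.0]
        assert not rs.monotone_decrease_ok

    def test_tolerance_allows_small_bumps(self):
        sizes = np.concatenate([np.full(10, 1.0), np.full(10, 2.5)])
        rs = range_size_stats(sizes, tolerance=0.05)
        assert rs.monotone_decrease_ok  # equal bins are within tolerance


class TestBandRates:
    def test_no_events_gives_empty_table(self):
        gen = Genealogy()
        out = band_rates(gen, pd.DataFrame(columns=["step", "source_lat", "target_lat"]))
        assert out.empty

    def test_single_split_counts_in_low_band(self):
        gen = Genealogy()
        gen.register_origin(0, None, 10)
        gen.record_split(1, 0, 4, lat=10.0)
        out = band_rates(gen, pd.DataFrame(columns=["step", "source_lat", "target_lat"]))
        assert len(out) == 1
        row = out.iloc[0]
        assert row["event"] == "speciation" and row["band"] == "low" and row["count"] == 1

    def test_synthetic_log_matches_hand_count(self):
        gen = Genealogy()
        gen.register_origin(0, None, 50)
        gen.record_split(1, 0, 40, lat=5.0)   # low
        gen.record_split(2, 0, 40, lat=40.0)  # high
        gen.record_split(3, 1, 12, lat=-30.0) # high
        gen.record_extinction(2, 12, lat=50.0)  # high
        mig = pd.DataFrame(
            {
                "step": [40, 30, 30, 12],
                "species_id": [0, 0, 1, 1],
                "source_site": [0, 0, 0, 0],
                "target_site": [1, 1, 1, 1],
                "source_lat": [10.0, 10.0, 30.0, -10.0],
                "target_lat": [15.0, 30.0, 10.0, -40.0],
            }
        )
        out = band_rates(gen, mig, duration_kyr=1000.0)  # 1 Myr per step
        def count(event, band, window):
            rows = out[(out["event"] == event) & (out["band"] == band) & (out["window_myr"] == window)]
            return int(rows["count"].sum())

        assert count("speciation", "low", 40) == 1
        assert count("speciation", "high", 40) == 1
        assert count("speciation", "high", 12) == 1
        assert count("extinction", "high", 12) == 1
        assert count("migration", "low->high", 30) == 1
        assert count("migration", "high->low", 30) == 1
        assert count("migration", "low->high", 12) == 1
        # conservation: totals match the genealogy
        assert out[out["event"] == "speciation"]["count"].sum() == len(gen.splits)
        assert out[out["event"] == "extinction"]["count"].sum() == len(gen.extinctions)


class TestPomAcceptance:
    def _bundle(self, **over):
        base = dict(
            ldg_percent_loss=4.6, beta=-0.8, range_monotone_ok=True,
            curve_r=0.6, nltt=0.1, extant=25,
        )
        base.update(over)
        return base

    def test_passing_bundle_combined_pass(self):
        out = pom_acceptance(self._bundle())
        assert out["combined"] and all(out["flags"].values())

    def test_shallow_gradient_fails_ldg(self):
        out = pom_acceptance(self._bundle(ldg_percent_loss=0.5))
        assert not out["flags"]["ldg_percent_loss"] and not out["combined"]

    def test_too_few_extant_fails_combined(self):
        out = pom_acceptance(self._bundle(extant=19))
        assert not out["flags"]["extant"] and not out["combined"]

    def test_missing_statistic_fails_with_reason(self):
        out = pom_acceptance(self._bundle(beta=None))
        assert not out["flags"]["beta"]
        assert "beta" in out["reasons"]
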