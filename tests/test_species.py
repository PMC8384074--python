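import numpy as np
import pytest

import dendropy

from ecoevosim.species import (
    Genealogy,
    cluster_sites,
    create_ancestor_species,
    split_species,
    update_divergence,
)

from conftest import make_cost_matrix, make_species


def brute_force_components(site_ids, adjacency):
    """Independent clustering oracle: label propagation to convergence."""
    n = len(site_ids)
    labels = list(site_ids)
    changed = True
    while changed:
        changed = False
        for i in range(n):
            for j in range(n):
                if adjacency[i][j] and labels[j] < labels[i]:
                    labels[i] = labels[j]
                    changed = True
    return np.asarray(labels)


class TestCreateAncestors:
    def test_single_ancestor_covers_all_habitable(self, barrier_world):
        sl = barrier_world.slices[0]
        (sp,) = create_ancestor_species(barrier_world, sl)
        assert sp.n_populations == sl.n_habitable
        assert sp.parent_id is None
        assert np.all(sp.divergence == 0)
        assert sp.divergence.shape == (sp.n_populations,) * 2

    def test_match_local_rule_sets_topt_to_site_temperature(self, barrier_world):
        sl = barrier_world.slices[0]
        (sp,) = create_ancestor_species(barrier_world, sl)
        np.testing.assert_array_equal(sp.traits["t_opt"], sl.temperature[sp.site_ids])

    def test_two_ancestors_with_disjoint_ranges(self, barrier_world):
        sl = barrier_world.slices[0]
        hab = np.flatnonzero(sl.habitable)
        a, b = create_ancestor_species(
            barrier_world, sl, range_spec=[hab[:3], hab[3:6]], n_ancestors=2
        )
        assert (a.species_id, b.species_id) == (0, 1)
        assert a.parent_id is None and b.parent_id is None
        assert set(a.site_ids).isdisjoint(b.site_ids)

    def test_empty_range_is_configuration_error(self, barrier_world):
        sl = barrier_world.slices[0]
        water = np.flatnonzero(~sl.habitable)[:2]
        with pytest.raises(ValueError, match="no habitable site"):
            create_ancestor_species(barrier_world, sl, range_spec=[water], n_ancestors=1)


class TestClusterSites:
    def test_single_site_single_cluster(self):
        sp = make_species([7])
        costs = make_cost_matrix([7], [[0.0]])
        assert list(cluster_sites(sp, costs, 100.0)) == [7]

    def test_threshold_splits_or_joins_two_sites(self):
        sp = make_species([0, 1])
        costs = make_cost_matrix([0, 1], [[0, 500], [500, 0]])
        assert len(set(cluster_sites(sp, costs, 400.0))) == 2
        assert len(set(cluster_sites(sp, costs, 600.0))) == 1

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 50))
            sites = np.sort(rng.choice(200, size=n, replace=False))
            raw = rng.uniform(0, 1000, (n, n))
            dense = (raw + raw.T) / 2
            costs = make_cost_matrix(sites, dense.copy())
            thr = float(rng.uniform(100, 900))
            sp = make_species(sites)
            got = cluster_sites(sp, costs, thr)
            adj = (dense <= thr) | np.eye(n, dtype=bool)
            np.fill_diagonal(adj, True)
            expected = brute_force_components(list(sites), adj)
            np.testing.assert_array_equal(got, expected)

    def test_missing_site_in_cost_matrix_is_consistency_error(self):
        sp = make_species([0, 99])
        costs = make_cost_matrix([0, 1], np.zeros((2, 2)))
        with pytest.raises(RuntimeError, match="missing from the cost matrix"):
            cluster_sites(sp, costs, 100.0)


class TestUpdateDivergence:
    def test_cross_cluster_pairs_gain_rate(self):
        sp = make_species([0, 1, 2])
        labels = np.array([0, 0, 2])
        update_divergence(sp, labels, rate_per_pair=1.0)
        assert sp.divergence[0, 2] == sp.divergence[1, 2] == 1.0
        assert sp.divergence[0, 1] == 0.0

    def test_decay_reaches_zero_and_never_goes_negative(self):
        sp = make_species([0, 1])
        sp.divergence = np.array([[0.0, 3.0], [3.0, 0.0]])
        labels = np.zeros(2, dtype=int)
        for expected in (2.0, 1.0, 0.0, 0.0):
            update_divergence(sp, labels, rate_per_pair=1.0, decay_rate=1.0)
            assert sp.divergence[0, 1] == expected

    def test_single_cluster_zero_matrix_is_fixed_point(self):
        sp = make_species([0, 1, 2])
        update_divergence(sp, np.zeros(3, dtype=int), rate_per_pair=1.0)
        assert np.all(sp.divergence == 0)

    def test_negative_rate_rejected(self):
        sp = make_species([0, 1])
        with pytest.raises(ValueError):
            update_divergence(sp, np.zeros(2, dtype=int), rate_per_pair=-1.0)

    def test_symmetry_preserved_under_random_updates(self, rng):
        sp = make_species(np.arange(12))
        for _ in range(30):
            labels = rng.integers(0, 4, 12)
            update_divergence(sp, labels, float(rng.uniform(0, 2)), float(rng.uniform(0, 2)))
            np.testing.assert_array_equal(sp.divergence, sp.divergence.T)
            assert np.all(sp.divergence >= 0)
            assert np.all(np.diag(sp.divergence) == 0)


class TestSplitSpecies:
    def _two_cluster_species(self, div):
        sp = make_species([0, 1], abundance=[10, 5])
        sp.divergence = np.array([[0.0, div], [div, 0.0]])
        return sp, np.array([0, 1])

    def test_below_threshold_no_split(self):
        sp, labels = self._two_cluster_species(5.0)
        out, nid = split_species(sp, labels, threshold=6.0, next_species_id=1, step=3)
        assert out == [sp] and nid == 1

    def test_at_threshold_two_species_one_genealogy_record(self):
        gen = Genealogy()
        gen.register_origin(0, None, 10)
        sp, labels = self._two_cluster_species(6.0)
        out, nid = split_species(sp, labels, 6.0, next_species_id=1, step=4, genealogy=gen)
        assert len(out) == 2 and nid == 2
        parent, child = out
        assert parent.species_id == 0  # higher abundance keeps the identity
        assert child.species_id == 1 and child.parent_id == 0 and child.origin_step == 4
        assert gen.splits == [(1, 0, 4, np.nan)] or gen.splits[0][:3] == (1, 0, 4)

    def test_chain_of_compatible_clusters_stays_one_species(self):
        """A–B diverged past Ϟ but both still compatible with C: the
        compatibility graph is connected, so no split."""
        sp = make_species([0, 1, 2])
        div = np.array([[0.0, 9.0, 2.0], [9.0, 0.0, 2.0], [2.0, 2.0, 0.0]])
        sp.divergence = div
        out, nid = split_species(sp, np.array([0, 1, 2]), 6.0, 1, step=0)
        assert len(out) == 1 and nid == 1

    def test_divergence_reset_keeps_within_species_entries(self):
        sp = make_species([0, 1, 2], abundance=[10, 10, 1])
        div = np.array([[0.0, 1.0, 9.0], [1.0, 0.0, 9.0], [9.0, 9.0, 0.0]])
        sp.divergence = div
        out, _ = split_species(sp, np.array([0, 0, 2]), 6.0, 1, step=0)
        parent = out[0]
        assert parent.n_populations == 2
        assert parent.divergence[0, 1] == 1.0  # retained, below Ϟ
        child = out[1]
        assert child.n_populations == 1 and child.divergence.shape == (1, 1)

    def test_never_splits_single_cluster(self):
        sp = make_species([0, 1])
        sp.divergence = np.full((2, 2), 100.0)
        np.fill_diagonal(sp.divergence, 0)
        out, _ = split_species(sp, np.zeros(2, dtype=int), 6.0, 1, step=0)
        assert len(out) == 1


class TestGenealogyNewick:
    def test_tip_count_is_ancestors_plus_splits(self):
        gen = Genealogy()
        gen.register_origin(0, None, 10)
        gen.record_split(1, 0, 7)
        gen.record_split(2, 1, 4)
        gen.record_extinction(2, 2)
        tree = dendropy.Tree.get(data=gen.to_newick(duration_kyr=1000.0), schema="newick")
        labels = sorted(t.taxon.label for t in tree.leaf_node_iter())
        assert labels == ["s0", "s1", "s2"]

    def test_branch_lengths_follow_event_times(self):
        gen = Genealogy()
        gen.register_origin(0, None, 10)
        gen.record_split(1, 0, 6)
        nwk = gen.to_newick(duration_kyr=1000.0)  # 1 Myr per step
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        # both tips span origin (step 10) → present; the stem above the
        # split node covers steps 10 → 6
        depths = {t.taxon.label: t.distance_from_root() for t in tree.leaf_node_iter()}
        assert depths["s0"] == pytest.approx(10.0)
        assert depths["s1"] == pytest.approx(10.0)
        assert tree.seed_node.edge.length == pytest.approx(4.0)
        for leaf in tree.leaf_node_iter():
            assert leaf.edge.length == pytest.approx(6.0)

    def test_extant_only_prunes_extinct_lineages(self):
        gen = Genealogy()
        gen.register_origin(0, None, 10)
        gen.record_split(1, 0, 8)
        gen.record_split(2, 0, 5)
        gen.record_extinction(1, 3)
        nwk = gen.to_newick(duration_kyr=1000.0, extant_only=True)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        labels = sorted(t.taxon.label for t in tree.leaf_node_iter())
        assert labels == ["s0", "s2"]
        # ultrametric: both survivors reach the present
        depths = [t.distance_from_root() for t in tree.leaf_node_iter()]
        assert depths[0] == pytest.approx(depths[1])
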