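"""Wagner parsimony scoring, tree search, ancestor rooting and chronologies."""

import numpy as np
import pandas as pd
import pytest

import loopchron as lc
from loopchron.census import CharacterMatrix
from loopchron.parsimony import (
    _all_topologies,
    brute_force_length,
    root_placement_scores,
)
from loopchron.trees import RootedTree, UnrootedTree

from conftest import random_character_matrix


def matrix_from(states, n_states=24):
    states = np.asarray(states)
    return CharacterMatrix(
        pd.DataFrame(states, index=[f"t{i}" for i in range(states.shape[0])]), n_states
    )


def two_leaf_tree(names):
    return UnrootedTree({0: [1], 1: [0]}, names)


def quartet_tree(names):
    # ((t0,t1),(t2,t3)) unrooted: internals 4, 5
    return UnrootedTree({0: [4], 1: [4], 2: [5], 3: [5], 4: [0, 1, 5], 5: [2, 3, 4]}, names)


class TestSankoffLength:
    def test_uniform_states_cost_nothing(self):
        m = matrix_from([[5, 5], [5, 5], [5, 5], [5, 5]])
        assert lc.sankoff_length(quartet_tree(list(m.states.index)), m) == 0

    def test_two_leaves_cost_state_gap(self):
        m = matrix_from([[3], [7]])
        assert lc.sankoff_length(two_leaf_tree(["t0", "t1"]), m) == 4

    def test_quartet_hand_case(self):
        # states (3,7,5,5): best internal states are 5,5 -> |3-5|+|7-5| = 4
        m = matrix_from([[3], [7], [5], [5]])
        tree = quartet_tree(list(m.states.index))
        assert lc.sankoff_length(tree, m) == 4
        assert brute_force_length(tree, m) == 4

    def test_leaf_count_mismatch_rejected(self):
        m = matrix_from([[1], [2], [3]])
        with pytest.raises(ValueError):
            lc.sankoff_length(quartet_tree(["a", "b", "c", "d"]), m)

    @pytest.mark.parametrize("n_leaves", [4, 5, 6])
    def test_dp_equals_exhaustive_state_enumeration(self, rng, n_leaves):
        """Sankoff DP must match brute-force minimisation over internal states."""
        for _ in range(10):
            m = random_character_matrix(rng, n_leaves)
            trees = list(_all_topologies(n_leaves, list(m.states.index)))
            tree = trees[rng.integers(len(trees))]
            assert lc.sankoff_length(tree, m) == brute_force_length(tree, m)


class TestTreeSearch:
    def test_three_leaves_single_topology(self, rng):
        m = random_character_matrix(rng, 3)
        trees, _ = lc.exhaustive_search(m)
        assert len({t.topology_key() for t in trees}) == 1

    def test_four_leaves_optimum_over_three_topologies(self, rng):
        m = random_character_matrix(rng, 4)
        all_lengths = [
            lc.sankoff_length(t, m) for t in _all_topologies(4, list(m.states.index))
        ]
        assert len(all_lengths) == 3
        _, best = lc.exhaustive_search(m)
        assert best == min(all_lengths)

    def test_exhaustive_leaf_limit(self, rng):
        m = random_character_matrix(rng, 8)
        with pytest.raises(ValueError):
            lc.exhaustive_search(m, max_leaves=7)

    def test_more_restarts_never_hurt(self, rng):
        m = random_character_matrix(rng, 8, n_chars=5)
        _, l1 = lc.nni_search(m, n_starts=1, seed=0)
        _, l10 = lc.nni_search(m, n_starts=10, seed=0)
        assert l10 <= l1

    @pytest.mark.parametrize("n_leaves", [5, 6, 7])
    def test_nni_attains_exhaustive_optimum(self, rng, n_leaves):
        m = random_character_matrix(rng, n_leaves, n_chars=4)
        _, best = lc.exhaustive_search(m)
        _, found = lc.nni_search(m, n_starts=10, seed=1)
        assert found == best

    def test_recovers_homoplasy_free_tree(self):
        """States mutated by small ordered steps along a known tree come back."""
        # caterpillar ((((t0,t1),t2),t3),t4); each character increases by 3
        # at successive internal nodes -> perfectly nested, no homoplasy
        states = np.array([[0, 0], [0, 0], [3, 3], [6, 6], [9, 9]])
        m = matrix_from(states)
        tree, length = lc.nni_search(m, n_starts=5, seed=0)
        assert length == 18  # 2 characters x 9 total ordered change
        expected = UnrootedTree(
            {0: [5], 1: [5], 2: [6], 3: [7], 4: [7], 5: [0, 1, 6], 6: [5, 2, 7], 7: [6, 3, 4]},
            list(m.states.index),
        )
        assert tree.topology_key() == expected.topology_key()


class TestLundbergRooting:
    def test_all_max_leaf_attracts_root(self, rng):
        states = np.vstack([np.full((1, 3), 23), rng.integers(0, 12, size=(4, 3))])
        m = matrix_from(states)
        tree, _ = lc.nni_search(m, n_starts=3, seed=0)
        rooted = lc.lundberg_root(tree, m, ancestor="max")
        nd = lc.node_distances(rooted)
        assert nd["t0"] == 0.0

    def test_min_ancestor_mirrors_max(self, rng):
        states = np.vstack([np.zeros((1, 3), dtype=int), rng.integers(12, 24, size=(4, 3))])
        m = matrix_from(states)
        tree, _ = lc.nni_search(m, n_starts=3, seed=0)
        rooted = lc.lundberg_root(tree, m, ancestor="min")
        assert lc.node_distances(rooted)["t0"] == 0.0

    def test_identical_leaves_tie_on_every_branch(self, rng, caplog):
        m = matrix_from(np.full((4, 2), 7))
        tree, _ = lc.nni_search(m, n_starts=1, seed=0)
        import logging

        with caplog.at_level(logging.INFO, logger="loopchron.parsimony"):
            lc.lundberg_root(tree, m, ancestor="max")
        assert any("tied root placements" in r.message for r in caplog.records)

    def test_placement_matches_brute_force_oracle(self, rng):
        """DP-scored attachment must equal exhaustive state enumeration per branch."""
        for trial in range(5):
            m = random_character_matrix(rng, 5, n_chars=3)
            tree, _ = lc.nni_search(m, n_starts=2, seed=trial)
            anc = np.full(3, 23, dtype=np.int64)
            dp = root_placement_scores(tree, m, anc)
            bf = root_placement_scores(tree, m, anc, scorer=brute_force_length)
            assert [e for e, _ in dp] == [e for e, _ in bf]
            assert np.allclose([s for _, s in dp], [s for _, s in bf])


class TestNodeDistances:
    def test_ladder(self):
        # (((t3,t2),t1),t0) rooted: depths 1,2,3,3
        tree = RootedTree(root=4, children={4: [0, 5], 5: [1, 6], 6: [2, 3]},
                          leaf_names=["t0", "t1", "t2", "t3"])
        nd = lc.node_distances(tree)
        assert nd["t0"] == 0 and nd["t1"] == 0.5 and nd["t2"] == 1 and nd["t3"] == 1

    def test_two_leaf_degenerate(self):
        tree = RootedTree(root=2, children={2: [0, 1]}, leaf_names=["a", "b"])
        assert (lc.node_distances(tree) == 0).all()

    def test_balanced_quartet_all_maximal(self):
        tree = RootedTree(root=6, children={6: [4, 5], 4: [0, 1], 5: [2, 3]},
                          leaf_names=list("abcd"))
        assert (lc.node_distances(tree) == 1).all()

    def test_minmax_normalization_differs_only_by_offset(self):
        tree = RootedTree(root=4, children={4: [0, 5], 5: [1, 6], 6: [2, 3]},
                          leaf_names=["t0", "t1", "t2", "t3"])
        root_norm = lc.node_distances(tree, normalization="root")
        minmax = lc.node_distances(tree, normalization="minmax")
        assert (minmax == root_norm).all()  # identical here since min depth is 1


class TestClock:
    def test_default_anchors(self):
        clock = lc.calibrate_clock()
        assert clock.age(0.0) == pytest.approx(3.8)
        assert clock.age(1.0) == pytest.approx(0.0)

    def test_biomarker_anchor_pair(self):
        # ferritin family ~3 Gya at nd=0.180; PNP-oxidase 2.9 Gya at nd=0.210
        clock = lc.calibrate_clock([(0.180, 3.0), (0.210, 2.9)])
        assert clock.intercept == pytest.approx(3.6)
        assert clock.slope == pytest.approx(-10 / 3)
        assert clock.age(0.210) == pytest.approx(2.9)

    def test_negative_ages_clipped(self):
        clock = lc.calibrate_clock([(0.0, 1.0), (0.5, 0.0)])
        assert clock.age(1.0) == 0.0

    def test_coincident_anchors_rejected(self):
        with pytest.raises(ValueError):
            lc.calibrate_clock([(0.2, 3.0), (0.2, 2.0)])


class TestBuildChronology:
    def test_deterministic_under_seed(self, small_accretion):
        census, _ = small_accretion
        m = lc.encode_census(census)
        c1 = lc.build_chronology(m, n_starts=2, seed=5)
        c2 = lc.build_chronology(m, n_starts=2, seed=5)
        assert c1.nd.equals(c2.nd)

    def test_family_permutation_invariance(self, small_accretion):
        census, _ = small_accretion
        m = lc.encode_census(census)
        c1 = lc.build_chronology(m, n_starts=2, seed=5)
        perm = np.random.default_rng(3).permutation(m.states.shape[1])
        m2 = lc.encode_census(census)
        m2.states = m2.states.iloc[:, perm]
        c2 = lc.build_chronology(m2, n_starts=2, seed=5)
        # identical chronology up to the (sorted) family relabelling
        pd.testing.assert_series_equal(c1.nd, c2.nd)

    def test_nd_in_unit_interval_and_ages_monotone(self, small_accretion):
        census, _ = small_accretion
        chron = lc.build_chronology(lc.encode_census(census), n_starts=2, seed=5)
        assert chron.nd.between(0, 1).all()
        tab = chron.table()
        assert (np.diff(tab["age_Gya"].values) <= 1e-9).all()  # ages fall as nd rises

    def test_tsv_round_trip(self, small_accretion, tmp_path):
        census, _ = small_accretion
        chron = lc.build_chronology(lc.encode_census(census), n_starts=2, seed=5)
        path = tmp_path / "chrono.tsv"
        chron.to_tsv(path)
        back = lc.Chronology.from_tsv(path)
        assert np.allclose(back.nd.sort_index(), chron.nd.sort_index(), atol=1e-6)
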