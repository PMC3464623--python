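import itertools

import numpy as np
import pytest

from conftest import random_unit_similarity
from simlabel.discovery import (
    cluster_summary,
    discover,
    find_seed_pair,
    min_inner_similarity,
    split_cluster,
)
from simlabel.io import tree_to_newick
from simlabel.preprocess import UNIT, SimilarityMatrix
from simlabel.simulate import TwoClassSpec, make_block_similarity, make_two_class_similarity


class TestFindSeedPair:
    def test_unique_minimum_needs_no_powers(self):
        rng = np.random.default_rng(0)
        sim = random_unit_similarity(rng, 9)
        sim.values[3, 7] = sim.values[7, 3] = sim.values.min() / 2
        assert find_seed_pair(sim) == (3, 7)

    def test_three_component_graph_picks_nodes_1_and_6(self, three_component_graph):
        _, sim = three_component_graph
        with pytest.warns(RuntimeWarning, match="tied"):
            pair = find_seed_pair(sim)
        assert pair == (0, 5)  # nodes 1 and 6, 1-based

    def test_tie_broken_by_matrix_square_with_explicit_oracle(self):
        rng = np.random.default_rng(42)
        sim = random_unit_similarity(rng, 6)
        v = sim.values
        v[0, 1] = v[1, 0] = 0.05
        v[2, 3] = v[3, 2] = 0.05  # two tied minima

        # brute-force S^2 entries by triple loop
        s2 = np.zeros((6, 6))
        for i in range(6):
            for j in range(6):
                s2[i, j] = sum(v[i, k] * v[k, j] for k in range(6))
        tied = [(0, 1), (2, 3)]
        expected = min(tied, key=lambda p: s2[p])
        assert abs(s2[0, 1] - s2[2, 3]) > 1e-6  # the square really separates them
        assert find_seed_pair(sim) == expected

    def test_fully_tied_matrix_warns_and_falls_back_lexicographic(self):
        v = np.full((4, 4), 0.3)
        np.fill_diagonal(v, 1.0)
        sim = SimilarityMatrix(v, list("abcd"), UNIT)
        with pytest.warns(RuntimeWarning, match="tied"):
            assert find_seed_pair(sim) == (0, 1)

    def test_member_restriction(self):
        rng = np.random.default_rng(1)
        sim = random_unit_similarity(rng, 8)
        sim.values[0, 1] = sim.values[1, 0] = 0.0  # global min outside members
        members = [2, 3, 4, 5]
        a, b = find_seed_pair(sim, members)
        assert a in members and b in members


class TestSplitCluster:
    def test_three_component_first_split_with_pseudo_cluster(self, three_component_graph):
        _, sim = three_component_graph
        with pytest.warns(RuntimeWarning, match="tied"):
            zero, one, sol = split_cluster(sim)
        assert set(zero) == {0, 1, 2, 3, 4, 10, 11, 12, 13, 14}
        assert set(one) == {5, 6, 7, 8, 9}
        # nodes 11..15 are unattached to either seed and keep their
        # initialization value 0 exactly (the pseudo-cluster pathway)
        np.testing.assert_array_equal(sol.f[[10, 11, 12, 13, 14]], 0.0)

    def test_two_perfect_blocks_recovered(self):
        sim, labels = make_block_similarity((4, 6))
        zero, one, _ = split_cluster(sim)
        groups = {frozenset(zero.tolist()), frozenset(one.tolist())}
        assert groups == {frozenset(range(4)), frozenset(range(4, 10))}

    def test_matches_exhaustive_best_cut_on_small_noisy_instance(self):
        # downsized noisy two-class instance; compare the relaxed+thresholded
        # split to brute force over all labelings with the seeds fixed
        sim, _ = make_two_class_similarity(TwoClassSpec(size_small=4, ratio=1, sigma=0.1, seed=42))
        a, b = find_seed_pair(sim)
        zero, one, _ = split_cluster(sim, seed_pair=(a, b))
        w = np.clip(sim.values, 0.0, None)
        free = [i for i in range(8) if i not in (a, b)]
        best, best_obj = None, np.inf
        for bits in itertools.product([0, 1], repeat=len(free)):
            f = np.zeros(8)
            f[b] = 1.0
            f[free] = bits
            obj = 0.5 * np.sum(w * (f[:, None] - f[None, :]) ** 2)
            if obj < best_obj:
                best_obj, best = obj, f.copy()
        got = np.zeros(8)
        got[one] = 1.0
        np.testing.assert_array_equal(got, best)

    def test_cannot_split_singleton(self):
        rng = np.random.default_rng(2)
        sim = random_unit_similarity(rng, 4)
        with pytest.raises(ValueError):
            split_cluster(sim, members=[2])


class TestMinInnerSimilarity:
    def test_complete_component_closed_form(self, three_component_graph):
        _, sim = three_component_graph
        assert min_inner_similarity(sim, range(5, 10)) == pytest.approx(29 / 44)

    def test_singleton_is_infinite(self):
        rng = np.random.default_rng(3)
        assert min_inner_similarity(random_unit_similarity(rng, 4), [1]) == np.inf

    def test_pair_returns_its_similarity(self):
        v = np.array([[1.0, 0.3], [0.3, 1.0]])
        sim = SimilarityMatrix(v, list("ab"), UNIT)
        assert min_inner_similarity(sim) == pytest.approx(0.3)


class TestDiscover:
    def test_three_component_graph_three_leaves(self, three_component_graph):
        _, sim = three_component_graph
        with pytest.warns(RuntimeWarning, match="tied"):
            tree = discover(sim, threshold=0.0)
        leaves = {frozenset(m) for m in tree.leaf_members()}
        assert leaves == {
            frozenset(range(5)),
            frozenset(range(5, 10)),
            frozenset(range(10, 15)),
        }
        # second split separates 1..5 from 11..15
        root_children = {frozenset(c.members) for c in tree.root.children}
        assert frozenset(range(5, 10)) in root_children

    def test_threshold_below_all_similarities_single_leaf(self, three_component_graph):
        _, sim = three_component_graph
        tree = discover(sim, threshold=-1.0)
        assert len(tree.leaves()) == 1
        assert tree.root.is_leaf

    def test_threshold_above_all_gives_all_singletons(self):
        rng = np.random.default_rng(4)
        sim = random_unit_similarity(rng, 7)
        sim.values[np.triu_indices(7, 1)] *= 0.999  # keep off-diagonals below 1
        sim.values[np.tril_indices(7, -1)] = sim.values.T[np.tril_indices(7, -1)]
        tree = discover(sim, threshold=1.0)
        assert len(tree.leaves()) == 7
        assert all(len(m) == 1 for m in tree.leaf_members())

    def test_leaves_partition_samples(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(4, 16))
            sim = random_unit_similarity(rng, n)
            tree = discover(sim, threshold=float(rng.uniform(0, 1)))
            flat = sorted(i for m in tree.leaf_members() for i in m)
            assert flat == list(range(n))

    def test_monotone_threshold_never_fewer_leaves(self):
        rng = np.random.default_rng(6)
        sim = random_unit_similarity(rng, 12)
        counts = [
            len(discover(sim, threshold=t).leaves()) for t in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert counts == sorted(counts)

    def test_deterministic(self, three_component_graph):
        _, sim = three_component_graph
        with pytest.warns(RuntimeWarning):
            t1 = discover(sim, threshold=0.0)
        with pytest.warns(RuntimeWarning):
            t2 = discover(sim, threshold=0.0)
        assert tree_to_newick(t1) == tree_to_newick(t2)

    def test_criterion_scale_unit_shifts_threshold(self, three_component_graph):
        _, sim = three_component_graph
        # threshold 0.5 on the unit scale equals threshold 0 on the signed scale
        with pytest.warns(RuntimeWarning):
            t_unit = discover(sim, threshold=0.5, criterion_scale="unit")
        assert {frozenset(m) for m in t_unit.leaf_members()} == {
            frozenset(range(5)),
            frozenset(range(5, 10)),
            frozenset(range(10, 15)),
        }


class TestClusterSummary:
    def test_three_component_between_means_equal(self, three_component_graph):
        _, sim = three_component_graph
        with pytest.warns(RuntimeWarning):
            tree = discover(sim, threshold=0.0)
        table = cluster_summary(sim, tree)
        between = table[table.leaf_i != table.leaf_j].mean_similarity.to_numpy()
        assert np.ptp(between) < 1e-12

    def test_perfect_blocks_between_zero_within_one(self):
        sim, _ = make_block_similarity((3, 3))
        tree = discover(sim, threshold=0.5)
        table = cluster_summary(sim, tree)
        within = table[table.leaf_i == table.leaf_j].mean_similarity
        between = table[table.leaf_i != table.leaf_j].mean_similarity
        assert (within == 1.0).all()
        assert (between == 0.0).all()

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(7)
        sim = random_unit_similarity(rng, 10)
        tree = discover(sim, threshold=0.4)
        table = cluster_summary(sim, tree)
        leaves = tree.leaf_members()
        for _, row in table.iterrows():
            mi, mj = leaves[int(row.leaf_i)], leaves[int(row.leaf_j)]
            if row.leaf_i == row.leaf_j:
                vals = [sim.values[a, b] for a in mi for b in mj if a != b]
                if not vals:
                    assert np.isnan(row.mean_similarity)
                    continue
            else:
                vals = [sim.values[a, b] for a in mi for b in mj]
            assert row.mean_similarity == pytest.approx(np.mean(vals), abs=1e-12)
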