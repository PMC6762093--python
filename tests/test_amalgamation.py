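"""Quartet consistency, exact search and the divide-and-conquer heuristic."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from celltreeq import CellTree
from celltreeq.amalgamate import (
    consistency_count,
    exact_amalgamate,
    induced_quartets,
    is_consistent,
    qfm_amalgamate,
    rf_distance,
)
from celltreeq.quartets import Quartet, QuartetSet
from celltreeq.simulate import SimulationConfig, random_tree

from conftest import graph_distance_pairing

CATERPILLAR5 = "(a,(b,(c,(d,e))));"
BALANCED6 = "((a,b),(c,d),(e,f));"
CATERPILLAR6 = "(a,(b,(c,(d,(e,f)))));"


class TestIsConsistent:
    def test_induced_quartets_are_consistent(self):
        tree = CellTree.from_newick(CATERPILLAR5)
        for q in induced_quartets(tree):
            assert is_consistent(tree, q)

    def test_manual_cases_on_five_leaf_tree(self):
        tree = CellTree.from_newick("((a,b),(c,d),e);")
        assert is_consistent(tree, Quartet(("a", "b"), ("c", "e")))
        assert not is_consistent(tree, Quartet(("a", "c"), ("b", "e")))

    def test_unknown_label_rejected(self):
        tree = CellTree.from_newick(CATERPILLAR5)
        with pytest.raises(ValueError, match="leaf"):
            is_consistent(tree, Quartet(("a", "b"), ("c", "z")))

    def test_matches_path_distance_oracle(self):
        rng = np.random.default_rng(8)
        for seed in range(5):
            tree = random_tree(SimulationConfig(n_taxa=7, seed=seed))
            for subset in itertools.combinations(tree.leaves, 4):
                expected = graph_distance_pairing(tree, subset)
                assert expected is not None  # binary tree: always resolved
                q = Quartet(*expected)
                assert is_consistent(tree, q)
                for alt in (
                    Quartet((subset[0], subset[2]), (subset[1], subset[3])),
                    Quartet((subset[0], subset[3]), (subset[1], subset[2])),
                ):
                    if alt != q:
                        assert not is_consistent(tree, alt)


class TestConsistencyCountAndInduced:
    def test_complete_induced_set_scores_full(self):
        tree = CellTree.from_newick(BALANCED6)
        qs = induced_quartets(tree)
        assert len(qs) == 15
        assert consistency_count(tree, qs) == 15

    def test_empty_set_scores_zero(self):
        tree = CellTree.from_newick(CATERPILLAR5)
        assert consistency_count(tree, QuartetSet([])) == 0

    def test_half_conflicting_hand_set(self):
        tree = CellTree.from_newick(CATERPILLAR5)
        qs = QuartetSet(
            [
                Quartet(("a", "b"), ("c", "d")),  # consistent
                Quartet(("a", "b"), ("d", "e")),  # consistent
                Quartet(("a", "c"), ("b", "e")),  # conflicts
                Quartet(("a", "d"), ("c", "e")),  # conflicts
            ]
        )
        assert consistency_count(tree, qs) == 2

    def test_induced_sizes(self):
        assert len(induced_quartets(CellTree.from_newick(CATERPILLAR5))) == 5
        assert len(induced_quartets(CellTree.from_newick(BALANCED6))) == 15

    def test_caterpillar_restriction(self):
        qs = induced_quartets(CellTree.from_newick(CATERPILLAR5))
        assert qs.get(["a", "b", "d", "e"]) == Quartet(("a", "b"), ("d", "e"))


class TestExactAmalgamate:
    def test_consistent_seven_taxon_input_recovers_model_tree(self):
        tree = random_tree(SimulationConfig(n_taxa=7, seed=2))
        qs = induced_quartets(tree)
        best, count = exact_amalgamate(qs)
        assert count == 35
        assert rf_distance(best, tree) == 0

    def test_single_quartet(self):
        q = Quartet(("a", "b"), ("c", "d"))
        best, count = exact_amalgamate(QuartetSet([q]))
        assert count == 1
        assert is_consistent(best, q)

    def test_one_flipped_quartet_still_recovers_model_tree(self):
        tree = random_tree(SimulationConfig(n_taxa=6, seed=5))
        quartets = induced_quartets(tree).quartets
        subset = quartets[0].labels
        flipped = Quartet(
            (subset[0], subset[2]), (subset[1], subset[3])
        )
        assert flipped != quartets[0]
        qs = QuartetSet([flipped] + quartets[1:])
        best, count = exact_amalgamate(qs)
        assert count == 14  # C(6,4) - 1
        assert rf_distance(best, tree) == 0

    def test_guard_on_taxon_count(self):
        tree = random_tree(SimulationConfig(n_taxa=11, seed=1))
        qs = induced_quartets(tree)
        with pytest.raises(ValueError, match="qfm_amalgamate"):
            exact_amalgamate(qs)
        with pytest.raises(ValueError):
            exact_amalgamate(QuartetSet([]))


class TestQfmAmalgamate:
    def test_recovers_model_tree_from_complete_consistent_input(self):
        tree = random_tree(SimulationConfig(n_taxa=12, seed=9))
        result = qfm_amalgamate(induced_quartets(tree))
        assert rf_distance(result, tree) == 0

    def test_four_taxa_returns_the_lone_quartet_tree(self):
        q = Quartet(("a", "b"), ("c", "d"))
        tree = qfm_amalgamate(QuartetSet([q]))
        assert is_consistent(tree, q)

    def test_output_is_binary(self):
        tree = random_tree(SimulationConfig(n_taxa=9, seed=12))
        result = qfm_amalgamate(induced_quartets(tree))
        assert result.is_binary()

    def test_near_exact_on_random_weighted_sets(self):
        # fully conflicting random inputs: over a fixed-seed batch of 50 the
        # heuristic's consistency stays within 5% of the exact optimum, and
        # never exceeds it
        rng = np.random.default_rng(100)
        total_heur = total_best = 0
        for trial in range(50):
            n = int(rng.integers(6, 9))
            labels = [f"t{i}" for i in range(n)]
            quartets = []
            for subset in itertools.combinations(labels, 4):
                topo = rng.integers(3)
                a, b, c, d = subset
                pairs = [((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))]
                quartets.append(
                    Quartet(*pairs[topo], weight=float(rng.uniform(0.1, 1)))
                )
            qs = QuartetSet(quartets)
            _, best = exact_amalgamate(qs)
            heur = consistency_count(qfm_amalgamate(qs), qs)
            assert heur <= best  # the exact count is an upper bound
            total_heur += heur
            total_best += best
        assert total_heur >= 0.95 * total_best

    def test_invariant_under_quartet_input_order(self):
        tree = random_tree(SimulationConfig(n_taxa=8, seed=14))
        quartets = induced_quartets(tree).quartets
        reversed_qs = QuartetSet(list(reversed(quartets)))
        t1 = qfm_amalgamate(QuartetSet(quartets))
        t2 = qfm_amalgamate(reversed_qs)
        assert rf_distance(t1, t2) == 0

    def test_relabeling_equivariance_on_consistent_input(self):
        tree = random_tree(SimulationConfig(n_taxa=8, seed=15))
        mapping = {l: f"X{ord(l[1]) * 7 % 97}_{l}" for l in tree.leaves}
        relabeled_qs = QuartetSet(
            [
                Quartet(
                    (mapping[q.pair1[0]], mapping[q.pair1[1]]),
                    (mapping[q.pair2[0]], mapping[q.pair2[1]]),
                )
                for q in induced_quartets(tree)
            ]
        )
        result = qfm_amalgamate(relabeled_qs)
        # map back and compare against the model tree
        back = {v: k for k, v in mapping.items()}
        renamed = CellTree.from_newick(
            _rename_newick(result, back)
        )
        assert rf_distance(renamed, tree) == 0

    def test_deterministic_given_seed(self):
        tree = random_tree(SimulationConfig(n_taxa=10, seed=16))
        qs = induced_quartets(tree)
        t1 = qfm_amalgamate(qs, seed=3)
        t2 = qfm_amalgamate(qs, seed=3)
        assert t1.canonical_newick() == t2.canonical_newick()

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            qfm_amalgamate(QuartetSet([]))

    def test_weighted_unit_weights_match_unweighted(self):
        tree = random_tree(SimulationConfig(n_taxa=7, seed=18))
        qs_plain = induced_quartets(tree)
        qs_unit = QuartetSet(
            [Quartet(q.pair1, q.pair2, weight=1.0) for q in qs_plain]
        )
        t1 = qfm_amalgamate(qs_plain, weighted=False)
        t2 = qfm_amalgamate(qs_unit, weighted=True)
        assert rf_distance(t1, t2) == 0


def _rename_newick(tree: CellTree, mapping) -> str:
    adj = tree.adjacency()
    renamed = {}
    for node, nbrs in adj.items():
        key = mapping.get(node, node)
        renamed[key] = [mapping.get(x, x) for x in nbrs]
    from celltreeq.trees import adjacency_to_newick

    return adjacency_to_newick(renamed)


class TestRfDistance:
    def test_identical_trees(self):
        t = CellTree.from_newick(BALANCED6)
        assert rf_distance(t, CellTree.from_newick(BALANCED6)) == 0

    def test_single_nni_differs_by_two(self):
        # NNI across the (a,b)-side internal edge swaps b with the (c,d)
        # subtree: exactly one split is exchanged, so RF = 2
        t1 = CellTree.from_newick("((a,b),(c,d),e);")
        t2 = CellTree.from_newick("((a,(c,d)),b,e);")
        assert rf_distance(t1, t2) == 2

    def test_caterpillar_vs_balanced_by_hand_count(self):
        t1 = CellTree.from_newick(CATERPILLAR6)
        t2 = CellTree.from_newick(BALANCED6)
        # caterpillar splits: {ef}, {def}, {ab}; balanced: {ab}, {cd}, {ef};
        # shared = {ab}, {ef} -> symmetric difference 2
        assert rf_distance(t1, t2) == 2

    def test_leaf_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rf_distance(
                CellTree.from_newick(CATERPILLAR5),
                CellTree.from_newick(BALANCED6),
            )
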