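import numpy as np
import pytest
from hypothesis import given, strategies as st

import dollotrace as dt
from dollotrace.dollo_phylo import (
    bootstrap_support,
    brute_force_dollo_cost,
    dollo_character_cost,
    dollo_score,
    exhaustive_search,
    heuristic_search,
    rf_distance,
)

from conftest import random_matrix


def char(tree, present):
    return {name: int(name in present) for name in tree.leaf_names()}


class TestCharacterCost:
    @pytest.mark.parametrize(
        "present,expected",
        [
            (set(), 0),
            ({"A", "B"}, 1),
            ({"A", "C"}, 3),
            ({"A", "B", "C", "D"}, 1),
            ({"B"}, 1),
        ],
    )
    def test_quartet_examples(self, quartet, present, expected):
        assert dollo_character_cost(quartet, char(quartet, present)) == expected
        assert brute_force_dollo_cost(quartet, char(quartet, present)) == expected

    def test_missing_leaf_rejected(self, quartet):
        with pytest.raises(dt.ValidationError, match="missing leaves"):
            dollo_character_cost(quartet, {"A": 1, "B": 0, "C": 0})

    def test_brute_force_refuses_large_trees(self):
        tree = dt.random_tree(16, seed=0)
        with pytest.raises(dt.ValidationError, match="internal nodes"):
            brute_force_dollo_cost(tree, {n: 0 for n in tree.leaf_names()})

    @given(st.integers(0, 2**6 - 1))
    def test_caterpillar_matches_oracle(self, bits):
        """Fast cost equals exhaustive assignment enumeration on a 6-leaf
        caterpillar for every possible character."""
        topo = (((((0, 1), 2), 3), 4), 5)
        tree = dt.Tree.from_topology(topo, [f"L{i}" for i in range(6)])
        character = {f"L{i}": (bits >> i) & 1 for i in range(6)}
        assert dollo_character_cost(tree, character) == brute_force_dollo_cost(
            tree, character
        )

    def test_random_trees_match_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            tree = dt.random_tree(int(rng.integers(3, 7)), seed=int(rng.integers(1 << 20)))
            character = {n: int(rng.integers(0, 2)) for n in tree.leaf_names()}
            assert dollo_character_cost(tree, character) == brute_force_dollo_cost(
                tree, character
            )


class TestScore:
    def test_decomposition_adds_up(self):
        rng = np.random.default_rng(5)
        matrix = random_matrix(6, 25, rng)
        tree = dt.random_tree(6, seed=1, names=matrix.samples)
        score = dollo_score(tree, matrix)
        assert score.total_length == int(score.gains.sum() + score.losses.sum())
        assert (score.gains == 1).all()  # no all-absent columns allowed

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(6)
        matrix = random_matrix(6, 20, rng)
        tree = dt.random_tree(6, seed=2, names=matrix.samples)
        shuffled = dt.PresenceMatrix(matrix.df.sample(frac=1, axis=1, random_state=0))
        assert dollo_score(tree, matrix).total_length == dollo_score(tree, shuffled).total_length


class TestExhaustiveSearch:
    def test_shared_characters_group_carriers(self):
        # 5 loci shared by exactly {A,B}: grouping the carriers costs one
        # gain per locus; any other topology forces losses
        values = np.array([[1] * 5, [1] * 5, [0] * 5])
        ids = [dt.make_locus_id("chr1", j, j + 1, "+", "copia") for j in range(5)]
        matrix = dt.PresenceMatrix.from_arrays(["A", "B", "C"], ids, values)
        trees, length = exhaustive_search(matrix)
        assert length == 5
        assert all(frozenset({"A", "B"}) in t.clades() for t in trees)

    def test_private_loci_tie_all_topologies(self):
        values = np.eye(4, dtype=int)
        ids = [dt.make_locus_id("chr1", j, j + 1, "+", "copia") for j in range(4)]
        matrix = dt.PresenceMatrix.from_arrays(list("ABCD"), ids, values)
        trees, length = exhaustive_search(matrix)
        assert length == 4
        assert len(trees) == 15  # every rooted topology on 4 taxa is co-optimal

    def test_nested_characters_single_best_tree(self):
        presence = [{"A", "B"}, {"A", "B"}, {"A", "B", "C"}, {"A", "B", "C"}, {"D"}]
        samples = list("ABCD")
        values = np.array([[int(s in p) for p in presence] for s in samples])
        ids = [dt.make_locus_id("chr1", j, j + 1, "+", "copia") for j in range(5)]
        matrix = dt.PresenceMatrix.from_arrays(samples, ids, values)
        trees, length = exhaustive_search(matrix)
        assert length == 5
        expected = {frozenset("AB"), frozenset("ABC"), frozenset("ABCD")}
        assert len(trees) == 1 and trees[0].clades() == expected

    def test_refuses_more_than_eight_taxa(self):
        matrix = random_matrix(9, 5, np.random.default_rng(0))
        with pytest.raises(dt.ValidationError, match="8 taxa"):
            exhaustive_search(matrix)


class TestHeuristicSearch:
    def test_deterministic_given_seed(self):
        matrix = random_matrix(7, 30, np.random.default_rng(9))
        t1, l1 = heuristic_search(matrix, replicates=10, seed=42)
        t2, l2 = heuristic_search(matrix, replicates=10, seed=42)
        assert l1 == l2
        assert dt.newick_string(t1) == dt.newick_string(t2)

    def test_informative_character_forces_clade(self):
        # one character present in {A,B} among 6 samples: any tree lacking
        # the clade pays at least one extra change
        samples = list("ABCDEF")
        values = np.array([[1], [1], [0], [0], [0], [0]])
        # add private loci so every sample appears (not required, but realistic)
        eye = np.eye(6, dtype=int)
        values = np.hstack([values, eye])
        ids = [dt.make_locus_id("chr1", j, j + 1, "+", "copia") for j in range(7)]
        matrix = dt.PresenceMatrix.from_arrays(samples, ids, values)
        tree, _ = heuristic_search(matrix, replicates=10, seed=0)
        assert frozenset({"A", "B"}) in tree.clades()

    def test_replicates_must_be_positive(self):
        matrix = random_matrix(5, 10, np.random.default_rng(1))
        with pytest.raises(dt.ValidationError):
            heuristic_search(matrix, replicates=0, seed=0)

    def test_monotonicity_under_compatible_character(self):
        rng = np.random.default_rng(13)
        matrix = random_matrix(6, 20, rng)
        tree, length = heuristic_search(matrix, replicates=20, seed=3)
        clade = next(c for c in tree.clades() if 1 < len(c) < 6)
        extra = [[int(s in clade)] for s in matrix.samples]
        df = matrix.df.copy()
        df[dt.make_locus_id("chr9", 1, 2, "+", "copia")] = np.array(extra)
        bigger = dt.PresenceMatrix(df)
        _, new_length = heuristic_search(bigger, replicates=20, seed=3)
        assert new_length == length + 1


class TestBootstrap:
    def test_strongly_supported_clade(self):
        # 20 identical characters back (A,B); private loci pad the matrix
        samples = list("ABCDEF")
        shared = np.array([[1], [1], [0], [0], [0], [0]]).repeat(20, axis=1)
        values = np.hstack([shared, np.eye(6, dtype=int)])
        ids = [dt.make_locus_id("chr1", j, j + 1, "+", "copia") for j in range(26)]
        matrix = dt.PresenceMatrix.from_arrays(samples, ids, values)
        tree, _ = heuristic_search(matrix, replicates=10, seed=1)
        assert frozenset({"A", "B"}) in tree.clades()
        annotated = bootstrap_support(matrix, tree, replicates=25, seed=2, search_replicates=5)
        clades = annotated.node_clades()
        supports = {
            clades[id(n)]: n.support for n in annotated.internal_nodes()
        }
        assert supports[frozenset({"A", "B"})] == 1.0
        assert all(0.0 <= s <= 1.0 for s in supports.values())

    def test_row_order_invariance(self):
        rng = np.random.default_rng(21)
        matrix = random_matrix(6, 40, rng)
        tree, _ = heuristic_search(matrix, replicates=10, seed=5)
        permuted = dt.PresenceMatrix(matrix.df.iloc[::-1])
        a = bootstrap_support(matrix, tree, replicates=20, seed=7, search_replicates=5)
        b = bootstrap_support(permuted, tree, replicates=20, seed=7, search_replicates=5)
        ca, cb = a.node_clades(), b.node_clades()
        sa = {ca[id(n)]: n.support for n in a.internal_nodes()}
        sb = {cb[id(n)]: n.support for n in b.internal_nodes()}
        assert sa == sb


class TestRfDistance:
    def test_identity(self, quartet):
        assert rf_distance(quartet, quartet) == 0

    def test_conflicting_quartets(self, quartet):
        other = dt.Tree.from_topology(((0, 2), (1, 3)), ["A", "B", "C", "D"])
        assert rf_distance(quartet, other) == 4
        assert rf_distance(other, quartet) == 4

    def test_leaf_mismatch_rejected(self, quartet):
        other = dt.Tree.from_topology(((0, 1), (2, 3)), ["A", "B", "C", "E"])
        with pytest.raises(dt.ValidationError):
            rf_distance(quartet, other)
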