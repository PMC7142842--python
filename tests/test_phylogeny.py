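"""Parsimony scoring, ratchet search, ACCTRAN rooting, origin report."""

import numpy as np
import pandas as pd
import pytest

import cnatree as ct
from cnatree.phylogeny import UnrootedTree
from cnatree.popseg import EventMatrix

from helpers import min_parsimony_exhaustive


def make_matrix(rows, labels=None, ids=None):
    rows = np.asarray(rows, np.int8)
    n, k = rows.shape
    ids = ids or [f"c{i}" for i in range(n)]
    cells = pd.DataFrame(
        {
            "cell_id": ids,
            "label": labels if labels is not None else ["green"] * n,
            "mouse": "M1",
        }
    )
    segments = pd.DataFrame(
        {
            "chrom": ["chr1"] * k,
            "start_bin": np.arange(k) * 20,
            "end_bin": np.arange(k) * 20 + 19,
            "n_bins": 20,
            "start_bp": 0,
            "end_bp": 1,
        }
    )
    return EventMatrix(states=rows, segments=segments, cells=cells)


def quartet_tree(ids):
    """((A,B),(C,D)) as an unrooted tree."""
    a, b, c, d = range(4)
    adj = {a: {4}, b: {4}, c: {5}, d: {5}, 4: {a, b, 5}, 5: {c, d, 4}}
    return UnrootedTree(adj, dict(zip(range(4), ids)))


class TestParsimonyScore:
    def test_identical_rows_score_zero(self):
        m = make_matrix([[1, 0, -1]] * 4)
        assert ct.parsimony_score(quartet_tree(m.cell_ids), m) == 0

    def test_single_character_split(self):
        m = make_matrix([[1], [1], [0], [0]])
        assert ct.parsimony_score(quartet_tree(m.cell_ids), m) == 1

    def test_incompatible_split_costs_two(self):
        # (+1,0,+1,0) on ((A,B),(C,D)) needs two changes
        m = make_matrix([[1], [0], [1], [0]])
        assert ct.parsimony_score(quartet_tree(m.cell_ids), m) == 2

    def test_leaf_without_row_rejected(self):
        m = make_matrix([[1], [0], [1], [0]])
        tree = quartet_tree(["x0", "x1", "x2", "x3"])
        with pytest.raises(ValueError, match="without a matrix row"):
            ct.parsimony_score(tree, m)


class TestRatchet:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        rows = rng.choice([-1, 0, 1], size=(n, 6), p=[0.2, 0.5, 0.3])
        m = make_matrix(rows)
        trees, score = ct.parsimony_ratchet(m, n_iterations=30, seed=seed)
        assert score == min_parsimony_exhaustive(rows)
        for t in trees:
            assert ct.parsimony_score(t, m) == score

    def test_perfect_phylogeny_score_equals_event_count(self):
        # nested events, no homoplasy: 5 distinct events
        rows = np.array(
            [
                [1, 1, 0, 0, 0],
                [1, 1, 0, 0, 0],
                [1, 0, 1, 0, 0],
                [1, 0, 1, 1, 0],
                [1, 0, 1, 0, 1],
                [0, 0, 0, 0, 0],
            ],
            np.int8,
        )
        m = make_matrix(rows)
        _, score = ct.parsimony_ratchet(m, n_iterations=50, seed=3)
        assert score == 5

    def test_determinism(self):
        rng = np.random.default_rng(11)
        rows = rng.choice([-1, 0, 1], size=(7, 8))
        m = make_matrix(rows)
        a_trees, a = ct.parsimony_ratchet(m, n_iterations=40, seed=5)
        b_trees, b = ct.parsimony_ratchet(m, n_iterations=40, seed=5)
        assert a == b
        assert [t.splits() for t in a_trees] == [t.splits() for t in b_trees]

    def test_star_tree_for_invariant_matrix(self):
        m = make_matrix(np.zeros((5, 3), np.int8))
        with pytest.warns(UserWarning, match="star tree"):
            trees, score = ct.parsimony_ratchet(m, seed=0)
        assert score == 0
        assert len(trees) == 1

    def test_too_few_cells_rejected(self):
        m = make_matrix([[1], [0]])
        with pytest.raises(ValueError):
            ct.parsimony_ratchet(m)


class TestAcctran:
    def test_single_change_placed_rootward_of_pair(self):
        # outgroup O=0, A=+1, B=+1, C=0 on (O,(C,(A,B)))
        rows = np.array([[0], [1], [1], [0]], np.int8)
        m = make_matrix(rows, ids=["O", "A", "B", "C"])
        o, a, b, c = 0, 1, 2, 3
        adj = {o: {4}, c: {4}, 4: {o, c, 5}, 5: {4, a, b}, a: {5}, b: {5}}
        tree = UnrootedTree(adj, {0: "O", 1: "A", 2: "B", 3: "C"})
        cna = ct.root_and_acctran(tree, m, {"O"})
        assert cna.score == 1
        # the one change lies on the stem of the (A,B) clade
        for node in cna.root.walk():
            if node.is_leaf:
                assert node.length == 0
            elif set(node.leaf_names()) == {"A", "B"}:
                assert node.length == 1
                assert node.events == [(0, 0, 1)]

    def test_branch_lengths_sum_to_parsimony_score(self):
        rng = np.random.default_rng(23)
        for seed in range(4):
            rows = rng.choice([-1, 0, 1], size=(6, 5), p=[0.2, 0.5, 0.3])
            rows[0] = 0  # outgroup
            m = make_matrix(rows)
            trees, score = ct.parsimony_ratchet(m, n_iterations=25, seed=seed)
            cna = ct.root_and_acctran(trees[0], m, {"c0"})
            assert cna.total_length == score
            assert cna.total_length == ct.parsimony_score(trees[0], m)

    def test_all_neutral_matrix_zero_lengths(self):
        rows = np.zeros((4, 3), np.int8)
        m = make_matrix(rows)
        tree = quartet_tree(m.cell_ids)
        cna = ct.root_and_acctran(tree, m, {"c0"})
        assert all(n.length == 0 for n in cna.root.walk())

    def test_branch_length_multiset_invariant_to_leaf_order(self):
        rng = np.random.default_rng(31)
        rows = rng.choice([-1, 0, 1], size=(6, 6), p=[0.2, 0.5, 0.3])
        rows[2] = 0
        m1 = make_matrix(rows)
        trees, _ = ct.parsimony_ratchet(m1, n_iterations=25, seed=1)
        lengths1 = sorted(n.length for n in ct.root_and_acctran(trees[0], m1, {"c2"}).root.walk())
        perm = np.random.default_rng(0).permutation(6)
        m2 = make_matrix(rows[perm], ids=[f"c{i}" for i in perm])
        trees2, _ = ct.parsimony_ratchet(m2, n_iterations=25, seed=1)
        lengths2 = sorted(n.length for n in ct.root_and_acctran(trees2[0], m2, {"c2"}).root.walk())
        assert lengths1 == lengths2

    def test_outgroup_must_be_leaf_subset(self):
        m = make_matrix(np.zeros((4, 2), np.int8))
        tree = quartet_tree(m.cell_ids)
        with pytest.raises(ValueError):
            ct.root_and_acctran(tree, m, {"nope"})

    def test_nonneutral_outgroup_warns(self):
        rows = np.array([[1], [1], [0], [0]], np.int8)
        m = make_matrix(rows)
        tree = quartet_tree(m.cell_ids)
        with pytest.warns(UserWarning, match="non-neutral"):
            ct.root_and_acctran(tree, m, {"c0"})


class TestOriginReport:
    def test_single_origin_with_mixed_labels(self):
        rows = np.array(
            [
                [0, 0, 0],  # blood
                [1, 1, 0],
                [1, 1, 0],
                [1, 0, 1],
                [1, 0, 1],
            ],
            np.int8,
        )
        labels = ["blood", "green", "non-green", "green", "green"]
        m = make_matrix(rows, labels=labels)
        trees, _ = ct.parsimony_ratchet(m, n_iterations=30, seed=0)
        cna = ct.root_and_acctran(trees[0], m, {"c0"})
        rep = ct.assess_clonal_origin(cna, m)
        assert rep["n_origins"] == 1
        counts = rep["largest_clade"]["label_counts"]
        assert counts.get("green", 0) >= 1 and counts.get("non-green", 0) >= 1

    def test_two_disjoint_clones_two_origins(self):
        rows = np.array(
            [
                [0, 0, 0, 0],  # blood
                [1, 1, 0, 0],
                [1, 1, 0, 0],
                [0, 0, 1, 1],
                [0, 0, 1, 1],
            ],
            np.int8,
        )
        labels = ["blood", "green", "green", "non-green", "non-green"]
        m = make_matrix(rows, labels=labels)
        trees, _ = ct.parsimony_ratchet(m, n_iterations=30, seed=0)
        cna = ct.root_and_acctran(trees[0], m, {"c0"})
        rep = ct.assess_clonal_origin(cna, m)
        assert rep["n_origins"] == 2

    def test_all_diploid_reports_no_tumor_lineage(self):
        m = make_matrix(np.zeros((4, 2), np.int8), labels=["blood"] * 4)
        tree = quartet_tree(m.cell_ids)
        cna = ct.root_and_acctran(tree, m, {"c0"})
        rep = ct.assess_clonal_origin(cna, m)
        assert rep["status"] == "no tumor lineage detected"
        assert rep["n_origins"] == 0
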