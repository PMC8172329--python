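"""Distance matrices, linkage trees, Newick export, tree cuts and ARI."""

import io
import itertools

import numpy as np
import pytest
from Bio import Phylo
from scipy.special import comb
from sklearn.base import clone

from fegs.phylogeny import (
    HierarchicalPhylogeny,
    adjusted_rand_index,
    cosine_distance_matrix,
    cut_tree,
    linkage_tree,
    to_newick,
)


def brute_force_linkage(D, method):
    """O(N^3) agglomeration: clusters as frozensets, inter-cluster distance
    as min (single) or max (complete) over all cross pairs."""
    n = D.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    agg = min if method == "single" else max
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = agg(D[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return np.array(heights)


def brute_force_ari(labels_a, labels_b):
    """Hubert-Arabie ARI from the pair-count contingency table."""
    cats_a, cats_b = sorted(set(labels_a)), sorted(set(labels_b))
    table = np.zeros((len(cats_a), len(cats_b)))
    for x, y in zip(labels_a, labels_b):
        table[cats_a.index(x), cats_b.index(y)] += 1
    n = len(labels_a)
    index = comb(table, 2).sum()
    row = comb(table.sum(axis=1), 2).sum()
    col = comb(table.sum(axis=0), 2).sum()
    expected = row * col / comb(n, 2)
    max_index = (row + col) / 2
    return (index - expected) / (max_index - expected)


def random_distance_matrix(rng, n):
    a = rng.random((n, n))
    D = (a + a.T) / 2
    np.fill_diagonal(D, 0)
    return D


class TestCosineDistance:
    def test_scale_invariance(self):
        X = np.array([[1.0, 2, 3], [3, 6, 9]])
        assert cosine_distance_matrix(X)[0, 1] == pytest.approx(0, abs=1e-12)

    def test_antipodal_rows(self):
        X = np.array([[1.0, -2, 0.5], [-1, 2, -0.5]])
        assert cosine_distance_matrix(X)[0, 1] == pytest.approx(2.0)

    def test_matches_direct_formula(self, rng):
        X = rng.normal(size=(5, 4))
        D = cosine_distance_matrix(X)
        for i in range(5):
            for j in range(5):
                expected = 1 - X[i] @ X[j] / (
                    np.linalg.norm(X[i]) * np.linalg.norm(X[j])
                )
                assert D[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            cosine_distance_matrix(np.array([[1.0, 1], [0, 0]]))


class TestLinkage:
    def test_three_point_hand_trace(self):
        D = np.array([[0.0, 1, 2], [1, 0, 3], [2, 3, 0]])
        single = linkage_tree(D, "single")
        complete = linkage_tree(D, "complete")
        # both merge the distance-1 pair {0,1} first
        for Z in (single, complete):
            assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
            assert Z[0, 2] == pytest.approx(1.0)
        assert single[1, 2] == pytest.approx(2.0)  # min(2, 3)
        assert complete[1, 2] == pytest.approx(3.0)  # max(2, 3)

    def test_two_points(self):
        D = np.array([[0.0, 0.7], [0.7, 0]])
        for method in ("single", "complete"):
            Z = linkage_tree(D, method)
            assert Z.shape == (1, 4) and Z[0, 2] == pytest.approx(0.7)

    @pytest.mark.parametrize("method", ["single", "complete"])
    def test_matches_brute_force_agglomeration(self, rng, method):
        for _ in range(5):
            D = random_distance_matrix(rng, 8)
            Z = linkage_tree(D, method)
            np.testing.assert_allclose(
                Z[:, 2], brute_force_linkage(D, method), atol=1e-12
            )

    def test_single_heights_below_complete(self, rng):
        D = random_distance_matrix(rng, 10)
        hs = np.sort(linkage_tree(D, "single")[:, 2])
        hc = np.sort(linkage_tree(D, "complete")[:, 2])
        assert np.all(hs <= hc + 1e-12)

    def test_heights_monotone(self, rng):
        D = random_distance_matrix(rng, 12)
        for method in ("single", "complete"):
            h = linkage_tree(D, method)[:, 2]
            assert np.all(np.diff(h) >= -1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="method"):
            linkage_tree(np.zeros((3, 3)), "average")
        with pytest.raises(ValueError, match="at least 2"):
            linkage_tree(np.zeros((1, 1)), "single")


class TestCutTree:
    @pytest.fixture()
    def Z(self, rng):
        return linkage_tree(random_distance_matrix(rng, 9), "complete")

    def test_extremes(self, Z):
        assert len(set(cut_tree(Z, 1))) == 1
        assert len(set(cut_tree(Z, 9))) == 9

    def test_three_point_example(self):
        D = np.array([[0.0, 1, 2], [1, 0, 3], [2, 3, 0]])
        labels = cut_tree(linkage_tree(D, "single"), 2)
        assert labels[0] == labels[1] != labels[2]

    def test_every_k_yields_k_nonempty_clusters(self, Z):
        for k in range(1, 10):
            labels = cut_tree(Z, k)
            assert len(set(labels)) == k

    def test_out_of_range(self, Z):
        with pytest.raises(ValueError):
            cut_tree(Z, 0)
        with pytest.raises(ValueError):
            cut_tree(Z, 10)


class TestNewick:
    def test_two_leaves(self):
        Z = np.array([[0.0, 1, 0.8, 2]])
        tree = Phylo.read(io.StringIO(to_newick(Z, ["A", "B"])), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["A", "B"]
        for leaf in tree.get_terminals():
            assert leaf.branch_length == pytest.approx(0.8)

    def test_roundtrip_topology(self, rng):
        D = random_distance_matrix(rng, 7)
        Z = linkage_tree(D, "single")
        labels = [f"s{i}" for i in range(7)]
        tree = Phylo.read(io.StringIO(to_newick(Z, labels)), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(labels)
        # ultrametric: root-to-leaf depth equals final merge height everywhere
        depths = tree.depths()
        leaf_depths = [d for c, d in depths.items() if c.is_terminal()]
        np.testing.assert_allclose(leaf_depths, Z[-1, 2], rtol=1e-8)

    def test_four_leaf_nesting(self):
        # fixed merges: (0,1)@0.1 -> (2,3)@0.2 -> join@0.5
        Z = np.array([[0, 1, 0.1, 2], [2, 3, 0.2, 2], [4, 5, 0.5, 4]])
        tree = Phylo.read(
            io.StringIO(to_newick(Z, ["a", "b", "c", "d"])), "newick"
        )
        pair = tree.common_ancestor(["a", "b"])
        assert sorted(t.name for t in pair.get_terminals()) == ["a", "b"]

    def test_metacharacter_labels_quoted(self):
        Z = np.array([[0.0, 1, 1.0, 2]])
        nwk = to_newick(Z, ["sp one", "sp(two)"])
        tree = Phylo.read(io.StringIO(nwk), "newick")
        assert len(tree.get_terminals()) == 2

    def test_label_count_mismatch(self):
        with pytest.raises(ValueError, match="labels"):
            to_newick(np.array([[0.0, 1, 1.0, 2]]), ["only-one"])


class TestARI:
    def test_identical_partitions(self):
        p = {"a": 1, "b": 1, "c": 2}
        assert adjusted_rand_index(p, p) == pytest.approx(1.0)

    def test_crossed_partition_worked_example(self):
        p1 = {"w": 1, "x": 1, "y": 2, "z": 2}
        p2 = {"w": 1, "x": 2, "y": 1, "z": 2}
        assert adjusted_rand_index(p1, p2) == pytest.approx(-0.5)
        assert brute_force_ari([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)

    def test_label_renaming_invariance(self):
        p1 = {"a": "x", "b": "x", "c": "y", "d": "z"}
        p2 = {"a": 7, "b": 7, "c": 0, "d": 3}
        assert adjusted_rand_index(p1, p2) == pytest.approx(1.0)

    def test_symmetric_and_matches_brute_force(self, rng):
        ids = [f"s{i}" for i in range(12)]
        p1 = {i: int(c) for i, c in zip(ids, rng.integers(0, 3, 12))}
        p2 = {i: int(c) for i, c in zip(ids, rng.integers(0, 4, 12))}
        v12 = adjusted_rand_index(p1, p2)
        assert v12 == pytest.approx(adjusted_rand_index(p2, p1))
        oracle = brute_force_ari([p1[i] for i in ids], [p2[i] for i in ids])
        assert v12 == pytest.approx(oracle, abs=1e-12)

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValueError, match="different IDs"):
            adjusted_rand_index({"a": 1}, {"b": 1})


class TestEstimator:
    def test_fit_attributes_and_cut(self, rng):
        X = rng.normal(size=(10, 4))
        phylo = HierarchicalPhylogeny(linkage="complete").fit(X)
        assert phylo.distance_matrix_.shape == (10, 10)
        assert phylo.linkage_matrix_.shape == (9, 4)
        assert len(set(phylo.cut(3))) == 3
        assert to_newick(phylo.linkage_matrix_, [str(i) for i in range(10)])

    def test_clone_and_params(self):
        phylo = HierarchicalPhylogeny(linkage="single", metric="cosine")
        assert clone(phylo).get_params() == phylo.get_params()

    def test_unfitted_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            HierarchicalPhylogeny().cut(2)

    def test_precomputed_metric(self, rng):
        D = random_distance_matrix(rng, 6)
        phylo = HierarchicalPhylogeny(metric="precomputed").fit(D)
        np.testing.assert_array_equal(phylo.distance_matrix_, D)
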