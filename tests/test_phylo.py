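import numpy as np
import pytest
import dendropy
from hypothesis import given, settings, strategies as st

from radiascan.io import MISSING, MarkerMatrix, SequenceSet
from radiascan.phylo import (
    DistanceMatrix,
    motu_cluster,
    nei_li_distance,
    neighbor_joining,
    p_distance,
)

from conftest import random_additive_tree


def brute_nei_li(calls: np.ndarray) -> np.ndarray:
    """Naive double loop re-implementation (missing-aware)."""
    n = calls.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            nx = nxy = ny = 0
            for l in range(calls.shape[1]):
                a, b = calls[i, l], calls[j, l]
                if a == MISSING or b == MISSING:
                    continue
                nx += a == 1
                ny += b == 1
                nxy += (a == 1) and (b == 1)
            d[i, j] = 1 - 2 * nxy / (nx + ny) if (nx + ny) else 0.0
    return d


class TestNeiLi:
    def test_formula_example(self):
        mm = MarkerMatrix(["x", "y"], [f"L{i}" for i in range(4)],
                          np.array([[1, 1, 0, 1], [1, 0, 0, 1]], np.int8))
        dm = nei_li_distance(mm)
        assert dm.values[0, 1] == pytest.approx(0.2)

    def test_identical_and_disjoint(self):
        mm = MarkerMatrix(["a", "b", "c"], ["L1", "L2"],
                          np.array([[1, 0], [1, 0], [0, 1]], np.int8))
        dm = nei_li_distance(mm)
        assert dm.values[0, 1] == 0.0
        assert dm.values[0, 2] == 1.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        calls = rng.choice([0, 1, MISSING], size=(20, 200),
                           p=[0.5, 0.45, 0.05]).astype(np.int8)
        mm = MarkerMatrix([f"s{i}" for i in range(20)],
                          [f"L{j}" for j in range(200)], calls)
        dm = nei_li_distance(mm)
        assert np.allclose(dm.values, brute_nei_li(calls), atol=1e-12)

    def test_replicates_excluded_by_default(self, rep_matrix):
        dm = nei_li_distance(rep_matrix)
        assert "a_rep1" not in dm.ids

    def test_all_missing_overlap_raises(self):
        calls = np.array([[1, MISSING], [MISSING, 1]], np.int8)
        mm = MarkerMatrix(["a", "b"], ["L1", "L2"], calls)
        with pytest.raises(ValueError, match="'a'.*'b'"):
            nei_li_distance(mm)


def _leaf_dist_matrix(tree: dendropy.Tree, ids: list[str]) -> np.ndarray:
    pdm = tree.phylogenetic_distance_matrix()
    tax = {t.label: t for t in tree.taxon_namespace}
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = pdm.distance(tax[ids[i]], tax[ids[j]])
    return out


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        # AB|CD with leaf lengths 1,2,3,4 and internal 5
        ids = ["A", "B", "C", "D"]
        d = np.array([
            [0, 3, 9, 10],
            [3, 0, 10, 11],
            [9, 10, 0, 7],
            [10, 11, 7, 0],
        ], float)
        tree = neighbor_joining(DistanceMatrix(ids, d))
        assert np.allclose(_leaf_dist_matrix(tree, ids), d, atol=1e-9)
        splits = {frozenset(l.taxon.label for l in e.head_node.leaf_iter())
                  for e in tree.preorder_edge_iter() if not e.head_node.is_leaf()}
        assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits

    def test_three_taxa_closed_form(self):
        ids = ["a", "b", "c"]
        d = np.array([[0, 5, 9], [5, 0, 8], [9, 8, 0]], float)
        tree = neighbor_joining(DistanceMatrix(ids, d))
        lengths = {e.head_node.taxon.label: e.length
                   for e in tree.preorder_edge_iter()
                   if e.head_node.is_leaf()}
        assert lengths["a"] == pytest.approx((5 + 9 - 8) / 2)
        assert lengths["b"] == pytest.approx((5 + 8 - 9) / 2)
        assert lengths["c"] == pytest.approx((9 + 8 - 5) / 2)

    def test_random_additive_trees_recovered(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = int(rng.integers(4, 13))
            dist, _ = random_additive_tree(n, rng)
            ids = [f"t{i}" for i in range(n)]
            tree = neighbor_joining(DistanceMatrix(ids, dist))
            assert np.allclose(_leaf_dist_matrix(tree, ids), dist, atol=1e-8)

    def test_bootstrap_clean_split_full_support(self):
        calls = np.zeros((6, 20), np.int8)
        calls[:3, :10] = 1
        calls[3:, 10:] = 1
        mm = MarkerMatrix([f"s{i}" for i in range(6)],
                          [f"L{j}" for j in range(20)], calls)
        dm = nei_li_distance(mm)
        tree = neighbor_joining(dm, bootstrap=(mm, 50, 0))
        labels = [nd.label for nd in tree.preorder_node_iter()
                  if not nd.is_leaf() and nd.label is not None]
        assert labels and all(l == "100" for l in labels)

    def test_non_finite_rejected(self):
        dm = DistanceMatrix(["a", "b", "c"], np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0.]]))
        dm.values[0, 1] = dm.values[1, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            neighbor_joining(dm)


class TestPDistance:
    def test_simple(self):
        ss = SequenceSet(["a", "b"], ["ACGT", "ACGA"], aligned=True)
        assert p_distance(ss).values[0, 1] == pytest.approx(0.25)

    def test_gap_pairwise_deletion(self):
        ss = SequenceSet(["a", "b"], ["AC-T", "ACGT"], aligned=True)
        assert p_distance(ss).values[0, 1] == 0.0

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(2)
        alphabet = list("ACGT-N")
        seqs = ["".join(rng.choice(alphabet, 80, p=[.22, .22, .22, .22, .06, .06]))
                for _ in range(10)]
        ss = SequenceSet([f"s{i}" for i in range(10)], seqs, aligned=True)
        dm = p_distance(ss)
        for i in range(10):
            for j in range(i + 1, 10):
                comp = diff = 0
                for a, b in zip(seqs[i], seqs[j]):
                    if a in "ACGT" and b in "ACGT":
                        comp += 1
                        diff += a != b
                assert dm.values[i, j] == pytest.approx(diff / comp)

    def test_no_comparable_sites(self):
        ss = SequenceSet(["a", "b"], ["A---", "-CGT"], aligned=True)
        with pytest.raises(ValueError, match="comparable"):
            p_distance(ss)


class TestMotuCluster:
    def _dm(self, pairs: dict[tuple[str, str], float], ids: list[str]):
        n = len(ids)
        v = np.full((n, n), 1.0)
        np.fill_diagonal(v, 0)
        for (a, b), d in pairs.items():
            i, j = ids.index(a), ids.index(b)
            v[i, j] = v[j, i] = d
        return DistanceMatrix(ids, v, kind="p_distance")

    def test_chaining(self):
        dm = self._dm({("A", "B"): 0.02, ("B", "C"): 0.02, ("A", "C"): 0.05},
                      ["A", "B", "C"])
        part = motu_cluster(dm, 0.03)
        assert part.n_clusters() == 1

    def test_threshold_zero_singletons(self):
        dm = self._dm({("A", "B"): 0.01}, ["A", "B", "C"])
        assert motu_cluster(dm, 0.0).n_clusters() == 3

    def test_inclusive_boundary(self):
        dm = self._dm({("A", "B"): 0.03}, ["A", "B", "C"])
        part = motu_cluster(dm, 0.03)
        assert part.labels["A"] == part.labels["B"]

    def test_negative_threshold(self):
        dm = self._dm({}, ["A", "B", "C"])
        with pytest.raises(ValueError):
            motu_cluster(dm, -0.1)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        v = rng.uniform(0, 0.1, (n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        ids = [f"s{i}" for i in range(n)]
        dm = DistanceMatrix(ids, v, kind="p_distance")
        base = motu_cluster(dm, 0.03).clusters()
        perm = rng.permutation(n)
        dm2 = DistanceMatrix([ids[i] for i in perm],
                             v[np.ix_(perm, perm)], kind="p_distance")
        assert motu_cluster(dm2, 0.03).clusters() == base

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        v = rng.uniform(0, 0.2, (n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        dm = DistanceMatrix([f"s{i}" for i in range(n)], v, kind="p_distance")
        counts = [motu_cluster(dm, t).n_clusters()
                  for t in (0.0, 0.02, 0.05, 0.1, 0.2)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
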