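import numpy as np
import pytest
from skbio import TreeNode

from puckertools import (
    StructureDistanceMatrix,
    distance_matrix,
    maxsub_score,
    nj_tree,
    random_ca_structure,
    structure_pair,
    to_newick,
)


def random_additive_matrix(labels, rng):
    """Distance matrix of a random binary tree with positive branch lengths."""
    nodes = [f"{l}:{rng.uniform(0.5, 2.0):.6f}" for l in labels]
    while len(nodes) > 2:
        j, i = sorted(rng.choice(len(nodes), size=2, replace=False),
                      reverse=True)
        b, a = nodes.pop(j), nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.5, 2.0):.6f}")
    tree = TreeNode.read([f"({nodes[0]},{nodes[1]});"])
    dm = tree.tip_tip_distances()
    return dm, tree


def patristic(tree, ids):
    dm = tree.tip_tip_distances()
    return np.array([[0.0 if a == b else dm[a, b] for b in ids] for a in ids])


class TestMaxSub:
    def test_self_comparison_scores_one(self):
        s = random_ca_structure(60, seed=4)
        assert maxsub_score(s, s.copy()) == pytest.approx(1.0, abs=1e-12)

    def test_half_displaced_copy_scores_half(self):
        s = random_ca_structure(20, seed=5)
        b = s.copy()
        b[10:] += 50.0
        # brute-force view: no subset can mix the two coherent halves, so
        # the maximal superimposable subset is one half (10 of 20 residues)
        assert maxsub_score(s, b) == pytest.approx(0.5, abs=0.02)

    def test_disjoint_random_clouds_score_near_zero(self, rng):
        a = rng.normal(0, 30, size=(50, 3))
        b = rng.normal(0, 30, size=(50, 3))
        assert maxsub_score(a, b) < 0.15

    def test_monotone_in_threshold(self, rng):
        a = random_ca_structure(40, seed=6)
        b = a + rng.normal(0, 0.8, size=a.shape)
        scores = [maxsub_score(a, b, d_threshold=d)
                  for d in (1.0, 2.0, 3.5, 5.0)]
        assert all(s1 <= s2 + 1e-12 for s1, s2 in zip(scores, scores[1:]))

    def test_asymmetric_normalization(self):
        # query length normalization: comparing a sub-structure against its
        # parent scores higher than the reverse direction
        s = random_ca_structure(40, seed=7)
        sub = s[:25]
        corr = [(i, i) for i in range(25)]
        forward = maxsub_score(sub, s, corr)
        backward = maxsub_score(s, sub, [(j, i) for i, j in corr])
        assert forward > backward

    def test_too_few_correspondences_rejected(self):
        s = random_ca_structure(10, seed=8)
        with pytest.raises(ValueError, match="at least 4"):
            maxsub_score(s, s, correspondence=[(0, 0), (1, 1), (2, 2)])

    def test_unequal_lengths_need_explicit_correspondence(self):
        with pytest.raises(ValueError, match="identity correspondence"):
            maxsub_score(random_ca_structure(10, seed=1),
                         random_ca_structure(12, seed=2))


class TestDistanceMatrix:
    def test_identical_triplet_gives_zero_matrix(self):
        s = random_ca_structure(30, seed=9)
        m = distance_matrix({"a": s, "b": s.copy(), "c": s.copy()})
        assert np.allclose(m.D, 0.0, atol=1e-12)

    def test_symmetric_with_zero_diagonal(self, rng):
        structs = {f"s{i}": random_ca_structure(30, seed=10 + i)
                   for i in range(4)}
        m = distance_matrix(structs)
        assert np.allclose(m.D, m.D.T)
        assert np.allclose(np.diag(m.D), 0.0)
        assert m.D.max() <= 1.0

    def test_pair_distance_is_one_minus_average(self):
        a = random_ca_structure(30, seed=11)
        b = a + 0.4
        b[15:] += 30.0  # make the comparison imperfect and asymmetric-prone
        pair = structure_pair("a", a, "b", b)
        assert pair.distance == pytest.approx(
            1.0 - 0.5 * (pair.maxsub_ab + pair.maxsub_ba), abs=1e-12)
        assert 0.0 <= pair.distance <= 1.0

    def test_two_noise_groups_cluster(self, rng):
        base1 = random_ca_structure(40, seed=12)
        base2 = random_ca_structure(40, seed=13)
        structs = {}
        for i in range(3):
            structs[f"g1_{i}"] = base1 + rng.normal(0, 0.2, base1.shape)
            structs[f"g2_{i}"] = base2 + rng.normal(0, 0.2, base2.shape)
        m = distance_matrix(structs)
        idx = {name: i for i, name in enumerate(m.ids)}
        within = [m.D[idx[f"g{g}_{i}"], idx[f"g{g}_{j}"]]
                  for g in (1, 2) for i in range(3) for j in range(i + 1, 3)]
        between = [m.D[idx[f"g1_{i}"], idx[f"g2_{j}"]]
                   for i in range(3) for j in range(3)]
        assert max(within) < min(between)


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:4))
        ids = ("A", "B", "C", "D")
        D = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float) / 10.0  # scale into [0, 1]
        tree = nj_tree(StructureDistanceMatrix(ids=ids, D=D))
        assert np.allclose(patristic(tree, ids), D, atol=1e-9)
        # the generating split {A,B} | {C,D} is present
        subsets = [frozenset(t.name for t in n.tips())
                   for n in tree.non_tips()]
        assert frozenset({"A", "B"}) in subsets \
            or frozenset({"C", "D"}) in subsets

    def test_three_leaves_closed_form(self):
        ids = ("a", "b", "c")
        D = np.array([[0, 0.3, 0.4], [0.3, 0, 0.5], [0.4, 0.5, 0]])
        tree = nj_tree(StructureDistanceMatrix(ids=ids, D=D))
        assert np.allclose(patristic(tree, ids), D, atol=1e-9)

    def test_random_additive_matrices_recovered(self, rng):
        for trial in range(20):
            n = int(rng.integers(5, 10))
            labels = [f"L{i}" for i in range(n)]
            dm, _ = random_additive_matrix(labels, rng)
            D = np.array([[0.0 if a == b else dm[a, b] for b in labels]
                          for a in labels])
            D /= D.max() * 1.01  # scale into [0, 1]
            tree = nj_tree(StructureDistanceMatrix(ids=tuple(labels), D=D))
            assert np.allclose(patristic(tree, labels), D, atol=1e-9)

    def test_permuted_ids_give_isomorphic_tree(self, rng):
        labels = [f"L{i}" for i in range(8)]
        dm, _ = random_additive_matrix(labels, rng)
        D = np.array([[0.0 if a == b else dm[a, b] for b in labels]
                      for a in labels])
        D /= D.max() * 1.01
        tree1 = nj_tree(StructureDistanceMatrix(ids=tuple(labels), D=D))
        perm = list(rng.permutation(len(labels)))
        plabels = [labels[i] for i in perm]
        tree2 = nj_tree(StructureDistanceMatrix(
            ids=tuple(plabels), D=D[np.ix_(perm, perm)]))
        assert np.allclose(patristic(tree1, labels),
                           patristic(tree2, labels), atol=1e-9)

    def test_newick_round_trip(self):
        ids = ("A", "B", "C", "D")
        D = np.array([
            [0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0],
        ], dtype=float) / 10.0
        tree = nj_tree(StructureDistanceMatrix(ids=ids, D=D))
        newick = to_newick(tree)
        reread = TreeNode.read([newick])
        assert {t.name for t in reread.tips()} == set(ids)

    def test_fewer_than_three_leaves_rejected(self):
        m = StructureDistanceMatrix(ids=("a", "b"),
                                    D=np.array([[0.0, 0.5], [0.5, 0.0]]))
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(m)

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 0.2, 0.3], [0.25, 0, 0.4], [0.3, 0.4, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            StructureDistanceMatrix(ids=("a", "b", "c"), D=D)

    def test_nonsquare_matrix_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            StructureDistanceMatrix(ids=("a", "b"), D=np.zeros((2, 3)))
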