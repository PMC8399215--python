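"""Kimura distances, neighbor joining, and rooting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nifphylo.align_concat import Alignment
from nifphylo.distance_tree import (
    DistanceMatrix,
    DistanceParams,
    distance_matrix,
    kimura_correct,
    neighbor_joining,
    p_distance,
    poisson_correct,
    root_tree,
)
from nifphylo.synthetic_data import simulate_yule_tree
from nifphylo.tree import (
    leaf_path_lengths,
    parse_newick,
    tree_splits,
    unroot,
    write_newick,
)
from nifphylo.tree_compare import rf_distance


class TestPDistance:
    def test_identical(self):
        assert p_distance("M" * 100, "M" * 100) == (0.0, 100)

    def test_pairwise_deletion(self):
        assert p_distance("MKT-A", "MRT-A") == (0.25, 4)

    def test_x_excluded(self):
        assert p_distance("MXTA", "MKTA") == (0.0, 3)

    def test_no_overlap(self):
        p, ov = p_distance("----", "MKTA")
        assert ov == 0 and math.isnan(p)


class TestKimura:
    def test_zero(self):
        assert kimura_correct(0.0) == 0.0

    def test_worked_value(self):
        # independent evaluation of -ln(1 - 0.1 - 0.2*0.01) = -ln(0.898)
        from sympy import Float, log

        expected = float(-log(Float("0.898", 40)))
        assert kimura_correct(0.1) == pytest.approx(expected, abs=1e-15)

    def test_saturation_beyond_domain_edge(self):
        # p=0.9: 1 - 0.9 - 0.162 < 0 -> capped
        assert kimura_correct(0.9) == DistanceParams().d_max
        assert kimura_correct(0.9, DistanceParams(d_max=5.0)) == 5.0

    @settings(max_examples=60, derandomize=True)
    @given(st.floats(0.0, 0.8), st.floats(0.0, 0.8))
    def test_strictly_increasing_on_domain(self, p1, p2):
        lo, hi = sorted((p1, p2))
        if hi - lo > 1e-9:  # separated beyond float round-off
            assert kimura_correct(lo) < kimura_correct(hi)

    def test_poisson_inverts_model_identity(self):
        # p_same(d) = 1/20 + 19/20 exp(-20d/19); correction must invert it
        for d in (0.05, 0.3, 1.0, 2.5):
            p_diff = (19 / 20) * (1 - math.exp(-(20 / 19) * d))
            assert poisson_correct(p_diff) == pytest.approx(d, rel=1e-12)


class TestDistanceMatrix:
    def test_identical_rows(self):
        dm = distance_matrix(
            Alignment("r", {"a": "M" * 60, "b": "M" * 60}),
            DistanceParams(min_overlap=10),
        )
        assert dm.D.tolist() == [[0, 0], [0, 0]]

    def test_hand_computed_entries(self):
        rows = {"a": "A" * 50 + "C" * 10, "b": "A" * 60, "c": "A" * 55 + "W" * 5}
        dm = distance_matrix(Alignment("r", rows), DistanceParams(min_overlap=10))
        for x, y, mism in (("a", "b", 10), ("a", "c", 10), ("b", "c", 5)):
            p = mism / 60
            assert dm.get(x, y) == pytest.approx(-math.log(1 - p - 0.2 * p * p))

    def test_symmetry_and_low_overlap_cap(self):
        rows = {"a": "MKTA" + "-" * 60, "b": "-" * 60 + "MKTA"}
        dm = distance_matrix(Alignment("r", rows))
        assert dm.get("a", "b") == DistanceParams().d_max
        assert np.array_equal(dm.D, dm.D.T)


def _additive_matrix(tree):
    dists = leaf_path_lengths(tree)
    taxa = sorted(tree.leaf_labels())
    n = len(taxa)
    D = np.zeros((n, n))
    for i, a in enumerate(taxa):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dists[(a, taxa[j]) if a < taxa[j] else (taxa[j], a)]
    return DistanceMatrix(taxa=taxa, D=D)


class TestNeighborJoining:
    def test_four_taxon_worked_example(self):
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        t = neighbor_joining(DistanceMatrix(taxa=list("ABCD"), D=D))
        assert tree_splits(t) == {frozenset("AB")}
        # edge lengths (A,B,C,D, internal) = (1,2,3,4,1)
        lengths = {n.label: n.length for n in t.nodes() if n.is_leaf}
        assert lengths == {"A": 1, "B": 2, "C": 3, "D": 4}
        internal = [n.length for n in t.nodes() if not n.is_leaf and n.length]
        assert internal == [1.0]

    def test_two_taxa_single_edge(self):
        t = neighbor_joining(
            DistanceMatrix(taxa=["A", "B"], D=np.array([[0, 5], [5, 0]], float))
        )
        assert leaf_path_lengths(t)[("A", "B")] == 5.0

    def test_three_taxa_three_point_formula(self):
        D = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], float)
        t = neighbor_joining(DistanceMatrix(taxa=list("ABC"), D=D))
        lengths = {n.label: n.length for n in t.leaves()}
        assert lengths == {"A": 1.0, "B": 3.0, "C": 5.0}

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_recovers_additive_topologies(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 21))
        true = simulate_yule_tree(n, seed=seed)
        for node in true.nodes():  # random non-ultrametric branch lengths
            if node.length is not None:
                node.length = float(rng.uniform(0.05, 1.0))
        t = neighbor_joining(_additive_matrix(true))
        assert rf_distance(t, unroot(true))[0] == 0

    def test_total_length_matches_additive_input(self):
        true = simulate_yule_tree(10, seed=3)
        rng = np.random.default_rng(3)
        for node in true.nodes():
            if node.length is not None:
                node.length = float(rng.uniform(0.05, 1.0))
        t = neighbor_joining(_additive_matrix(true))
        total_true = sum(n.length or 0 for n in unroot(true).nodes())
        total_nj = sum(n.length or 0 for n in t.nodes())
        assert total_nj == pytest.approx(total_true, abs=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        true = simulate_yule_tree(9, seed=8)
        dm = _additive_matrix(true)
        perm = rng.permutation(len(dm.taxa))
        dm2 = DistanceMatrix(
            taxa=[dm.taxa[i] for i in perm], D=dm.D[np.ix_(perm, perm)]
        )
        assert write_newick(neighbor_joining(dm)) == write_newick(
            neighbor_joining(dm2)
        )

    def test_matches_skbio_on_random_matrices(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(4)
        for seed in range(5):
            true = simulate_yule_tree(8, seed=seed)
            for node in true.nodes():
                if node.length is not None:
                    node.length = float(rng.uniform(0.05, 1.0))
            dm = _additive_matrix(true)
            ours = neighbor_joining(dm)
            sk = skbio_nj(SkbioDM(dm.D, ids=dm.taxa))
            from .oracles import dendropy_rf

            assert dendropy_rf(write_newick(ours), str(sk)) == 0

    def test_single_taxon_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(
                DistanceMatrix(taxa=["A"], D=np.zeros((1, 1)))
            )


class TestRooting:
    def test_outgroup_basic(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1));")
        rooted = root_tree(unroot(t), outgroup={"C", "D"})
        assert rooted.rooted
        sides = [
            frozenset(l.label for l in c.traverse() if l.is_leaf)
            for c in rooted.root.children
        ]
        assert frozenset("CD") in sides and frozenset("AB") in sides

    def test_incompatible_outgroup_rejected(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1));")
        with pytest.raises(ValueError, match="monophyletic"):
            root_tree(unroot(t), outgroup={"A", "C"})

    def test_midpoint_halves_longest_path(self):
        t = parse_newick("((A:4,B:1):1,(C:5,D:1):1);")  # A<->C = 11
        rooted = root_tree(t, midpoint=True)
        depths = leaf_path_lengths(rooted)
        dists = {}
        for leaf in rooted.leaves():
            d, node = 0.0, leaf
            while node.parent is not None:
                d += node.length or 0.0
                node = node.parent
            dists[leaf.label] = d
        assert max(dists.values()) == pytest.approx(5.5)
        assert dists["A"] == pytest.approx(5.5) or dists["C"] == pytest.approx(5.5)

    def test_root_then_unroot_roundtrip(self):
        for seed in range(5):
            t = unroot(simulate_yule_tree(8, seed=seed))
            rooted = root_tree(t, midpoint=True)
            assert rf_distance(unroot(rooted), t)[0] == 0

    def test_branch_lengths_conserved(self):
        t = unroot(simulate_yule_tree(8, seed=2))
        total = sum(n.length or 0 for n in t.nodes())
        rooted = root_tree(t, outgroup={"g0001"})
        assert sum(n.length or 0 for n in rooted.nodes()) == pytest.approx(total)
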