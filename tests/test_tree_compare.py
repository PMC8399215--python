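"""RF distance, consensus, quartet supertree, HGT detection, clusters."""

import itertools

import numpy as np
import pytest

from nifphylo.distance_tree import DistanceMatrix
from nifphylo.synthetic_data import apply_spr_transfers, simulate_yule_tree
from nifphylo.tree import parse_newick, unroot, write_newick
from nifphylo.tree_compare import (
    ClusterReference,
    assign_cluster,
    bipartitions,
    enumerate_topologies,
    hgt_candidates,
    majority_consensus,
    quartet_score,
    quartet_supertree,
    rf_distance,
    tanglegram_pairs,
)

from .oracles import dendropy_rf, quartet_score_oracle, supertree_oracle

T_AB_CD = "((A,B),(C,D));"
T_AC_BD = "((A,C),(B,D));"


class TestBipartitions:
    def test_four_leaf_single_split(self):
        assert bipartitions(parse_newick(T_AB_CD)) == {frozenset("AB")}

    def test_caterpillar_six(self):
        splits = bipartitions(parse_newick("(((((A,B),C),D),E),F);"))
        # ABCD|EF is canonically stored by its smaller side EF
        assert splits == {frozenset("AB"), frozenset("ABC"), frozenset("EF")}

    def test_star_empty(self):
        assert bipartitions(parse_newick("(A,B,C,D,E);")) == set()


class TestRF:
    def test_self_zero(self):
        t = parse_newick(T_AB_CD)
        assert rf_distance(t, t) == (0, 0.0)

    def test_four_leaf_maximal(self):
        assert rf_distance(parse_newick(T_AB_CD), parse_newick(T_AC_BD)) == (2, 1.0)

    def test_caterpillar_vs_balanced_six(self):
        # shared splits: AB and ABCD|EF -> symmetric difference {ABC, CD}
        cat = parse_newick("(((((A,B),C),D),E),F);")
        bal = parse_newick("((A,B),(C,D),(E,F));")
        rf, norm = rf_distance(cat, bal)
        assert rf == 2 == dendropy_rf(write_newick(cat), write_newick(bal))
        assert norm == pytest.approx(2 / 6)

    def test_leafset_mismatch_instructs_restrict(self):
        with pytest.raises(ValueError, match="restrict"):
            rf_distance(parse_newick(T_AB_CD), parse_newick("((A,B),(C,E));"))

    def test_matches_dendropy_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for seed in range(25):
            t1 = unroot(simulate_yule_tree(int(rng.integers(5, 14)), seed=seed))
            t2, _ = apply_spr_transfers(
                simulate_yule_tree(t1.n_leaves(), seed=seed),
                int(rng.integers(0, 3)), seed=seed + 1,
            )
            rf, _ = rf_distance(t1, unroot(t2))
            assert rf == dendropy_rf(write_newick(t1), write_newick(unroot(t2)))

    def test_metric_properties(self):
        trees = [
            unroot(apply_spr_transfers(simulate_yule_tree(8, seed=5), k, seed=k)[0])
            for k in range(4)
        ]
        for a, b in itertools.combinations(trees, 2):
            assert rf_distance(a, b)[0] == rf_distance(b, a)[0]
        for a, b, c in itertools.combinations(trees, 3):
            assert rf_distance(a, c)[0] <= rf_distance(a, b)[0] + rf_distance(b, c)[0]


class TestConsensus:
    def test_identical_copies_returned_with_full_support(self):
        for k in (1, 2, 5):
            t = parse_newick("(((A,B),C),((D,E),F));")
            cons = majority_consensus([t] * k)
            assert rf_distance(cons, t)[0] == 0
            supports = [n.support for n in cons.nodes() if n.support is not None]
            assert supports and all(s == 1.0 for s in supports)

    def test_two_thirds_majority(self):
        trees = [parse_newick(T_AB_CD), parse_newick(T_AB_CD), parse_newick(T_AC_BD)]
        cons = majority_consensus(trees)
        assert bipartitions(cons) == {frozenset("AB")}
        (support,) = [n.support for n in cons.nodes() if n.support is not None]
        assert support == pytest.approx(2 / 3)

    def test_three_way_tie_gives_star(self):
        trees = [parse_newick(T_AB_CD), parse_newick(T_AC_BD),
                 parse_newick("((A,D),(B,C));")]
        assert bipartitions(majority_consensus(trees)) == set()

    def test_retained_splits_pairwise_compatible(self):
        rng = np.random.default_rng(1)
        for seed in range(5):
            base = simulate_yule_tree(10, seed=seed)
            trees = [
                unroot(apply_spr_transfers(base, int(rng.integers(0, 2)),
                                           seed=seed * 10 + i)[0])
                for i in range(3)
            ]
            cons = majority_consensus(trees)
            universe = frozenset(cons.leaf_labels())
            for s1, s2 in itertools.combinations(bipartitions(cons), 2):
                compatible = (
                    not (s1 & s2)
                    or s1 <= s2 or s2 <= s1
                    or s1 | s2 == universe
                )
                assert compatible

    def test_leafset_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shared leaf set"):
            majority_consensus(
                [parse_newick(T_AB_CD), parse_newick("((A,B),(C,E));")]
            )


class TestQuartets:
    def test_identical_gene_trees_full_score(self):
        t = parse_newick("((A,B),((C,D),E));")
        assert quartet_score(t, [t] * 3) == 3 * 5  # 3 x C(5,4)

    def test_single_quartet_case(self):
        cand = parse_newick(T_AB_CD)
        genes = [parse_newick(T_AB_CD)] * 2 + [parse_newick(T_AC_BD)]
        assert quartet_score(cand, genes) == 2

    def test_star_gene_tree_contributes_zero(self):
        cand = parse_newick(T_AB_CD)
        assert quartet_score(cand, [parse_newick("(A,B,C,D);")]) == 0

    def test_matches_fourpoint_oracle(self):
        rng = np.random.default_rng(2)
        for seed in range(8):
            cand = unroot(simulate_yule_tree(7, seed=seed))
            genes = [
                unroot(apply_spr_transfers(simulate_yule_tree(7, seed=seed),
                                           int(rng.integers(0, 3)),
                                           seed=seed * 7 + i)[0])
                for i in range(3)
            ]
            assert quartet_score(cand, genes) == quartet_score_oracle(
                write_newick(cand), [write_newick(g) for g in genes]
            )

    def test_topology_count(self):
        for n, count in ((4, 3), (5, 15), (6, 105)):
            labels = [f"L{i}" for i in range(n)]
            topos = {write_newick(t) for t in enumerate_topologies(labels)}
            assert len(topos) == count


class TestSupertree:
    def test_unanimous_gene_trees_recovered(self):
        t = parse_newick("(((A,B),C),((D,E),F));")
        best, score = quartet_supertree([t] * 3)
        assert rf_distance(best, t)[0] == 0
        assert score == 3 * 15  # 3 x C(6,4)

    def test_majority_of_conflicting_quartets(self):
        genes = [parse_newick(T_AB_CD)] * 2 + [parse_newick(T_AC_BD)]
        best, score = quartet_supertree(genes)
        assert bipartitions(best) == {frozenset("AB")} and score == 2

    def test_single_gene_tree_returned(self):
        t = parse_newick("((A,B),((C,D),E));")
        best, _ = quartet_supertree([t])
        assert rf_distance(best, t)[0] == 0

    def test_exact_mode_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for seed in range(6):
            n = int(rng.integers(4, 8))
            genes = [
                unroot(apply_spr_transfers(simulate_yule_tree(n, seed=seed),
                                           int(rng.integers(0, 2)),
                                           seed=seed * 5 + i)[0])
                for i in range(3)
            ]
            best, score = quartet_supertree(genes, exact_max_n=8)
            oracle_score, oracle_trees = supertree_oracle(
                [write_newick(g) for g in genes]
            )
            assert score == oracle_score
            if len(oracle_trees) == 1:
                assert dendropy_rf(write_newick(best), oracle_trees[0]) == 0

    def test_greedy_mode_on_agreeing_trees(self):
        t = unroot(simulate_yule_tree(12, seed=9))
        best, score = quartet_supertree([t] * 4, exact_max_n=8, seed=1)
        assert rf_distance(best, t)[0] == 0
        assert score == 4 * 495  # 4 x C(12,4)


class TestHGT:
    def test_identical_trees_no_candidates(self):
        t = unroot(simulate_yule_tree(8, seed=0))
        rep = hgt_candidates(t, t)
        assert rep.candidates == [] and rep.initial_rf == 0

    def test_single_planted_transfer_recovered(self):
        # distant-clade transfers (the identifiable regime): recall must be 1.0
        rng = np.random.default_rng(7)
        for seed in range(20):
            n = int(rng.integers(8, 17))
            sp = simulate_yule_tree(n, seed=seed)
            gene, log = apply_spr_transfers(
                sp, 1, seed=seed + 100, leaf_only=True, min_regraft_distance=4
            )
            rep = hgt_candidates(gene, sp)
            (moved,) = log[0].moved
            assert moved in rep.candidates and rep.residual_rf == 0

    def test_two_planted_transfers_recovered(self):
        hits = 0
        for seed in range(10):
            sp = simulate_yule_tree(12, seed=seed)
            gene, log = apply_spr_transfers(sp, 2, seed=seed + 50, leaf_only=True)
            moved = {leaf for e in log for leaf in e.moved}
            rep = hgt_candidates(gene, sp)
            if moved <= set(rep.candidates):
                hits += 1
        assert hits >= 8  # a second SPR can be maskable by a cheaper pruning

    def test_rf_non_increasing_along_removals(self):
        sp = simulate_yule_tree(14, seed=4)
        gene, _ = apply_spr_transfers(sp, 3, seed=9, leaf_only=True)
        rep = hgt_candidates(gene, sp, max_removals=5)
        path = [rep.initial_rf] + [after for _, _, after in rep.removals]
        assert all(a >= b for a, b in zip(path, path[1:]))

    def test_nonshared_leaves_reported_dropped(self):
        sp = unroot(simulate_yule_tree(8, seed=1))
        gene = unroot(simulate_yule_tree(8, seed=1))
        from nifphylo.tree import restrict

        gene_small = restrict(gene, set(gene.leaf_labels()) - {"g0001"})
        rep = hgt_candidates(gene_small, sp)
        assert rep.dropped_leaves == ("g0001",)


class TestClusterAssignment:
    def _dm(self):
        taxa = ["q", "refI", "refII"]
        D = np.array([[0, 0.4, 1.2], [0.4, 0, 1.5], [1.2, 1.5, 0]])
        return DistanceMatrix(taxa=taxa, D=D)

    def test_argmin_reference(self):
        refs = ClusterReference({"refI": "I", "refII": "II"})
        assert assign_cluster("q", self._dm(), refs) == ("I", "refI", 0.4)

    def test_zero_distance_reference(self):
        taxa = ["q", "ric"]
        dm = DistanceMatrix(taxa=taxa, D=np.zeros((2, 2)))
        refs = ClusterReference({"ric": "IC"})
        assert assign_cluster("q", dm, refs)[0] == "IC"

    def test_no_reference_errors(self):
        with pytest.raises(ValueError, match="no cluster references"):
            assign_cluster("q", self._dm(), ClusterReference({}))

    def test_vocabulary_enforced(self):
        with pytest.raises(ValueError, match="unknown cluster"):
            ClusterReference({"r": "IV"})

    def test_planted_subtree_members_assigned_together(self):
        # two clades evolved apart: members of each match their own reference
        tree = parse_newick(
            "((a1:0.05,(a2:0.05,refI:0.05):0.02):0.6,"
            "(b1:0.05,(b2:0.05,refII:0.05):0.02):0.6);"
        )
        from nifphylo.tree import leaf_path_lengths

        dists = leaf_path_lengths(tree)
        taxa = sorted(tree.leaf_labels())
        D = np.zeros((len(taxa), len(taxa)))
        for i, a in enumerate(taxa):
            for j in range(i + 1, len(taxa)):
                key = (a, taxa[j]) if a < taxa[j] else (taxa[j], a)
                D[i, j] = D[j, i] = dists[key]
        dm = DistanceMatrix(taxa=taxa, D=D)
        refs = ClusterReference({"refI": "I", "refII": "II"})
        assert assign_cluster("a1", dm, refs)[0] == "I"
        assert assign_cluster("a2", dm, refs)[0] == "I"
        assert assign_cluster("b1", dm, refs)[0] == "II"
        assert assign_cluster("b2", dm, refs)[0] == "II"

    def test_tanglegram_export_lists_shared_leaves(self):
        t = unroot(simulate_yule_tree(6, seed=2))
        out = tanglegram_pairs(t, t)
        assert len(out.strip().splitlines()) == 7
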