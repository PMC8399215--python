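"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's own dynamic programming / search
code paths: alignments are scored by exhaustive enumeration of alignment
paths, quartet topologies are read off four-point path-length sums computed
with dendropy, and tree topologies are compared through dendropy's
bipartition machinery.
"""

from __future__ import annotations

import itertools

import dendropy


def brute_force_alignment_score(a: str, b: str, score, gap_open: float,
                                gap_extend: float) -> float:
    """Max global alignment score by exhaustive recursive enumeration of
    every alignment path (no dynamic programming; lengths <= ~7 only).

    A gap run of length L costs open + (L-1)*extend; terminal gaps are
    penalized like internal ones.  ``score(x, y)`` scores a residue pair.
    """

    def best(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(score(a[i], b[j]) + best(i + 1, j + 1, "M"))
        if i < len(a):  # gap in b
            cost = gap_extend if prev == "X" else gap_open
            options.append(-cost + best(i + 1, j, "X"))
        if j < len(b):  # gap in a
            cost = gap_extend if prev == "Y" else gap_open
            options.append(-cost + best(i, j + 1, "Y"))
        return max(options)

    return best(0, 0, "-")


def dendropy_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             taxon_namespace=dendropy.TaxonNamespace())


def dendropy_rf(newick1: str, newick2: str) -> int:
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick1, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=newick2, schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(t1, t2)


class FourPointTree:
    """Unit-branch-length topological distances of one tree (via dendropy),
    exposing induced quartet topologies by the four-point condition —
    independent of the package's bipartition-based quartet extraction."""

    def __init__(self, newick: str):
        tree = dendropy_tree(newick)
        for edge in tree.edges():
            edge.length = 1.0
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        self.leaves = frozenset(taxa)
        self.dist = {
            (a, b): pdm.distance(taxa[a], taxa[b])
            for a in taxa
            for b in taxa
            if a < b
        }

    def _d(self, a: str, b: str) -> float:
        return self.dist[(a, b) if a < b else (b, a)]

    def quartet(self, quartet: tuple[str, ...]):
        a, b, c, d = quartet
        sums = {
            frozenset([frozenset([a, b]), frozenset([c, d])]):
                self._d(a, b) + self._d(c, d),
            frozenset([frozenset([a, c]), frozenset([b, d])]):
                self._d(a, c) + self._d(b, d),
            frozenset([frozenset([a, d]), frozenset([b, c])]):
                self._d(a, d) + self._d(b, c),
        }
        ranked = sorted(sums.items(), key=lambda kv: kv[1])
        if ranked[0][1] == ranked[1][1]:
            return None
        return ranked[0][0]


def quartet_score_oracle(candidate_newick: str, gene_newicks: list[str]) -> int:
    """Quartet agreement count computed entirely through path distances."""
    cand = FourPointTree(candidate_newick)
    total = 0
    for gn in gene_newicks:
        gene = FourPointTree(gn)
        leaves = sorted(gene.leaves & cand.leaves)
        for quartet in itertools.combinations(leaves, 4):
            tg = gene.quartet(quartet)
            if tg is not None and tg == cand.quartet(quartet):
                total += 1
    return total


def supertree_oracle(gene_newicks: list[str]) -> tuple[int, list[str]]:
    """Exhaustive quartet-score maximization over all unrooted binary
    topologies; returns (best score, list of optimal Newick strings)."""
    leaves = sorted(set().union(*(FourPointTree(g).leaves for g in gene_newicks)))
    genes = [FourPointTree(g) for g in gene_newicks]
    best_score, best_trees = -1, []
    for newick in enumerate_unrooted_newicks(leaves):
        cand = FourPointTree(newick)
        score = 0
        for gene in genes:
            shared = sorted(gene.leaves & cand.leaves)
            for quartet in itertools.combinations(shared, 4):
                tg = gene.quartet(quartet)
                if tg is not None and tg == cand.quartet(quartet):
                    score += 1
        if score > best_score:
            best_score, best_trees = score, [newick]
        elif score == best_score:
            best_trees.append(newick)
    return best_score, best_trees


def enumerate_unrooted_newicks(leaves: list[str]) -> list[str]:
    """All (2n-5)!! unrooted binary topologies as Newick strings, built by a
    nested-parentheses recursion independent of the package's enumerator."""
    leaves = sorted(leaves)
    if len(leaves) == 3:
        return ["({},{},{});".format(*leaves)]

    def grow(struct, leaf):
        # struct: nested tuples; insert leaf on every edge
        out = []
        if isinstance(struct, tuple):
            for i, sub in enumerate(struct):
                for replaced in grow(sub, leaf):
                    out.append(tuple(replaced if k == i else s
                                     for k, s in enumerate(struct)))
        out.append((struct, leaf))
        return out

    def edges_grow(tri, leaf):
        # tri is the top-level trifurcation (3 subtrees); edges inside subtrees
        out = []
        for i, sub in enumerate(tri):
            for replaced in grow(sub, leaf):
                out.append(tuple(replaced if k == i else s
                                 for k, s in enumerate(tri)))
        return out

    tris = [tuple(leaves[:3])]
    for leaf in leaves[3:]:
        tris = [t for tri in tris for t in edges_grow(tri, leaf)]

    def fmt(s):
        if isinstance(s, tuple):
            return "(" + ",".join(fmt(x) for x in s) + ")"
        return s

    return [fmt(t) + ";" for t in tris]
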