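"""Tree comparison, combination and discordance analysis.

Robinson–Foulds distances over nontrivial bipartitions, strict-majority
consensus, quartet-score supertree estimation (the ASTRAL objective, solved
exactly for small leaf sets and by greedy insertion plus NNI hill-climbing
for larger ones), greedy leaf-prune detection of horizontal-transfer
candidates from gene-tree/species-tree discordance, and nearest-reference
assignment of Raymond nitrogenase clusters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .distance_tree import DistanceMatrix
from .tree import (
    Node,
    PhyloTree,
    canonical_split,
    restrict,
    tree_splits,
    write_newick,
)

CLUSTER_VOCABULARY = frozenset(
    ["I", "IA", "IB", "IC", "ID", "II", "IIA", "IIB", "IIC", "III"]
)


@dataclass(frozen=True)
class ClusterReference:
    """Reference exemplar -> Raymond cluster label."""

    labels: dict[str, str]

    def __post_init__(self):
        bad = {v for v in self.labels.values() if v not in CLUSTER_VOCABULARY}
        if bad:
            raise ValueError(f"unknown cluster label(s): {sorted(bad)}")


@dataclass
class HGTReport:
    """Greedy RF-reduction pruning trace between a gene and a species tree."""

    initial_rf: int
    initial_normalized: float
    removals: list[tuple[str, int, int]] = field(default_factory=list)
    residual_rf: int = 0
    dropped_leaves: tuple[str, ...] = ()

    @property
    def candidates(self) -> list[str]:
        return [leaf for leaf, _, _ in self.removals]

    def to_tsv(self) -> str:
        lines = ["leaf\trf_before\trf_after"]
        for leaf, before, after in self.removals:
            lines.append(f"{leaf}\t{before}\t{after}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Bipartitions and RF
# ---------------------------------------------------------------------------

def bipartitions(tree: PhyloTree) -> set[frozenset]:
    """Nontrivial bipartitions of the unrooted topology, one per internal
    edge, each represented by its canonical (smaller) side."""
    return tree_splits(tree)


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> tuple[int, float]:
    """Robinson–Foulds distance and its normalization by 2(n-3)."""
    l1, l2 = set(t1.leaf_labels()), set(t2.leaf_labels())
    if l1 != l2:
        raise ValueError(
            "trees have different leaf sets; restrict both to the shared "
            f"leaves first (only in first: {sorted(l1 - l2)[:5]}, "
            f"only in second: {sorted(l2 - l1)[:5]})"
        )
    rf = len(bipartitions(t1) ^ bipartitions(t2))
    n = len(l1)
    norm = rf / (2.0 * (n - 3)) if n > 3 else 0.0
    return rf, norm


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

def _tree_from_clades(
    universe: frozenset, clades: dict[frozenset, float | None]
) -> PhyloTree:
    """Build a (possibly multifurcating) tree from a nested clade family.

    Clades are given relative to a reference leaf (the smallest label) held
    outside every clade; supports are attached to the clade nodes.
    """
    order = sorted(clades, key=lambda c: (-len(c), tuple(sorted(c))))
    root = Node()
    node_of: dict[frozenset, Node] = {}
    parent_of: dict[frozenset, Node] = {}
    for clade in order:
        parent = root
        for bigger in order:
            if len(bigger) > len(clade) and clade < bigger:
                parent = node_of[bigger]  # nested family: last (smallest) wins
        node = Node(support=clades[clade])
        parent.add_child(node)
        node_of[clade] = node
        parent_of[clade] = parent
    for leaf in sorted(universe):
        parent = root
        best: frozenset | None = None
        for clade in order:
            if leaf in clade and (best is None or len(clade) < len(best)):
                best = clade
        if best is not None:
            parent = node_of[best]
        parent.add_child(Node(label=leaf))
    return PhyloTree(root, rooted=False)


def majority_consensus(trees: list[PhyloTree]) -> PhyloTree:
    """Strict-majority (>50%) consensus; support = occurrence frequency,
    unresolved regions left polytomous."""
    if not trees:
        raise ValueError("no trees")
    universe = frozenset(trees[0].leaf_labels())
    for t in trees[1:]:
        if frozenset(t.leaf_labels()) != universe:
            raise ValueError("consensus requires a shared leaf set")
    k = len(trees)
    counts: dict[frozenset, int] = {}
    for t in trees:
        for split in tree_splits(t):
            counts[split] = counts.get(split, 0) + 1
    kept = {s: c / k for s, c in counts.items() if c * 2 > k}
    ref = min(universe)
    clades = {
        (side if ref not in side else universe - side): support
        for side, support in kept.items()
    }
    return _tree_from_clades(universe, clades)


# ---------------------------------------------------------------------------
# Quartets
# ---------------------------------------------------------------------------

def _restricted_splits(splits: set[frozenset], universe: frozenset,
                       subset: frozenset) -> set[frozenset]:
    out = set()
    for s in splits:
        side = s & subset
        if 2 <= len(side) <= len(subset) - 2:
            out.add(canonical_split(side, subset))
    return out


def _quartet_map(splits: set[frozenset], universe: frozenset,
                 leaves: tuple[str, ...]) -> dict[frozenset, frozenset | None]:
    """For every 4-subset of ``leaves``: the resolved pair-split, or None."""
    out: dict[frozenset, frozenset | None] = {}
    quartets = [frozenset(q) for q in itertools.combinations(sorted(leaves), 4)]
    for q in quartets:
        out[q] = None
    for s in splits:
        inside = s & frozenset(leaves)
        outside = frozenset(leaves) - s
        if len(inside) < 2 or len(outside) < 2:
            continue
        for pair_in in itertools.combinations(sorted(inside), 2):
            for pair_out in itertools.combinations(sorted(outside), 2):
                q = frozenset(pair_in + pair_out)
                out[q] = frozenset([frozenset(pair_in), frozenset(pair_out)])
    return out


def quartet_score(candidate: PhyloTree, gene_trees: list[PhyloTree]) -> int:
    """Total number of 4-leaf subsets whose induced unrooted topology agrees
    between the candidate and each gene tree.  Unresolved quartets (in
    either tree) count as non-matching."""
    cand_universe = frozenset(candidate.leaf_labels())
    cand_splits = tree_splits(candidate)
    total = 0
    for gt in gene_trees:
        gt_leaves = tuple(sorted(frozenset(gt.leaf_labels()) & cand_universe))
        if len(gt_leaves) < 4:
            continue
        gt_map = _quartet_map(tree_splits(gt), frozenset(gt_leaves), gt_leaves)
        cand_map = _quartet_map(cand_splits, cand_universe, gt_leaves)
        for q, topo in gt_map.items():
            if topo is not None and cand_map.get(q) == topo:
                total += 1
    return total


def _star(leaves: list[str]) -> PhyloTree:
    root = Node()
    for leaf in leaves:
        root.add_child(Node(label=leaf))
    return PhyloTree(root, rooted=False)


def _insert_on_edge(tree: PhyloTree, edge_child_index: int, leaf: str) -> PhyloTree:
    """Copy of ``tree`` with ``leaf`` attached in the middle of the edge
    above the ``edge_child_index``-th non-root node (pre-order)."""
    work = tree.copy()
    targets = [n for n in work.nodes() if n is not work.root]
    child = targets[edge_child_index]
    parent = child.parent
    assert parent is not None
    idx = parent.children.index(child)
    mid = Node()
    parent.children[idx] = mid
    mid.parent = parent
    mid.add_child(child)
    mid.add_child(Node(label=leaf))
    return work


def enumerate_topologies(leaves: list[str]):
    """Yield all (2n-5)!! unrooted binary topologies on ``leaves``."""
    leaves = sorted(leaves)
    if len(leaves) < 3:
        yield _star(leaves)
        return

    def rec(k: int):
        if k == 3:
            yield _star(leaves[:3])
            return
        for smaller in rec(k - 1):
            n_edges = sum(1 for n in smaller.nodes() if n is not smaller.root)
            for e in range(n_edges):
                yield _insert_on_edge(smaller, e, leaves[k - 1])

    yield from rec(len(leaves))


def _nni_neighbors(tree: PhyloTree):
    """All trees one nearest-neighbor interchange away (unrooted)."""
    seen: set[str] = set()
    base_nodes = list(tree.nodes())
    for vi, v in enumerate(base_nodes):
        if v.is_leaf or v is tree.root or v.parent is None:
            continue
        p = v.parent
        for si, s in enumerate(p.children):
            if s is v:
                continue
            for ci in range(len(v.children)):
                work = tree.copy()
                wnodes = list(work.nodes())
                wv = wnodes[vi]
                wp = wv.parent
                ws = wp.children[si]
                wc = wv.children[ci]
                wv.children[ci] = ws
                ws.parent = wv
                wp.children[si] = wc
                wc.parent = wp
                key = write_newick(PhyloTree(work.root, rooted=False))
                if key not in seen:
                    seen.add(key)
                    yield PhyloTree(work.root, rooted=False)


def quartet_supertree(
    gene_trees: list[PhyloTree],
    exact_max_n: int = 8,
    seed: int = 0,
) -> tuple[PhyloTree, int]:
    """Combine gene trees into the quartet-score-maximizing species tree.

    For n <= exact_max_n the search is exhaustive over all unrooted binary
    topologies (global optimum; ties broken by canonically smallest Newick).
    For larger n: greedy stepwise leaf insertion in a seed-shuffled order,
    then NNI hill-climbing to a local optimum.  Returns (tree, score).
    """
    if not gene_trees:
        raise ValueError("no gene trees")
    leaves = sorted(set().union(*(set(t.leaf_labels()) for t in gene_trees)))
    if len(leaves) <= 3:
        star = _star(leaves)
        return star, quartet_score(star, gene_trees)

    def better(challenger, champion):
        # (higher score, then canonically smaller newick) wins
        if champion is None:
            return True
        if challenger[1] != champion[1]:
            return challenger[1] > champion[1]
        return write_newick(challenger[0]) < write_newick(champion[0])

    if len(leaves) <= exact_max_n:
        best = None
        for topo in enumerate_topologies(leaves):
            cand = (topo, quartet_score(topo, gene_trees))
            if better(cand, best):
                best = cand
        assert best is not None
        return best

    rng = np.random.default_rng(seed)
    order = list(leaves)
    rng.shuffle(order)
    current = _star(order[:3])
    for leaf in order[3:]:
        best = None
        n_edges = sum(1 for n in current.nodes() if n is not current.root)
        for e in range(n_edges):
            topo = _insert_on_edge(current, e, leaf)
            cand = (topo, quartet_score(topo, gene_trees))
            if better(cand, best):
                best = cand
        current = best[0]
    score = quartet_score(current, gene_trees)
    improved = True
    while improved:
        improved = False
        for neighbor in _nni_neighbors(current):
            s = quartet_score(neighbor, gene_trees)
            if s > score:
                current, score = neighbor, s
                improved = True
                break
    return current, score


# ---------------------------------------------------------------------------
# HGT candidates
# ---------------------------------------------------------------------------

def hgt_candidates(
    gene_tree: PhyloTree,
    species_tree: PhyloTree,
    max_removals: int = 5,
) -> HGTReport:
    """Greedy RF-reduction leaf pruning.

    Both trees are restricted to their shared leaves; the leaf whose removal
    (from both trees) maximally reduces the RF distance is pruned
    iteratively (ties alphabetical) until RF reaches zero, no removal helps,
    or ``max_removals`` is hit.  Removed leaves, in order, are the
    horizontal-transfer candidates.
    """
    shared = set(gene_tree.leaf_labels()) & set(species_tree.leaf_labels())
    dropped = tuple(
        sorted(
            (set(gene_tree.leaf_labels()) | set(species_tree.leaf_labels())) - shared
        )
    )
    if len(shared) < 4:
        raise ValueError("need >= 4 shared leaves")
    gt = restrict(gene_tree, shared)
    st = restrict(species_tree, shared)
    rf, norm = rf_distance(gt, st)
    report = HGTReport(initial_rf=rf, initial_normalized=norm, dropped_leaves=dropped)
    current = rf
    while current > 0 and len(report.removals) < max_removals:
        leaves = sorted(gt.leaf_labels())
        if len(leaves) <= 4:
            break
        best_leaf, best_rf = None, current
        for leaf in leaves:
            keep = set(leaves) - {leaf}
            r, _ = rf_distance(restrict(gt, keep), restrict(st, keep))
            if r < best_rf:
                best_leaf, best_rf = leaf, r
        if best_leaf is None:
            break
        keep = set(leaves) - {best_leaf}
        gt = restrict(gt, keep)
        st = restrict(st, keep)
        report.removals.append((best_leaf, current, best_rf))
        current = best_rf
    report.residual_rf = current
    return report


# ---------------------------------------------------------------------------
# Cluster assignment & tanglegram export
# ---------------------------------------------------------------------------

def assign_cluster(
    query_id: str, dm: DistanceMatrix, refs: ClusterReference
) -> tuple[str, str, float]:
    """Nearest-reference cluster label for one query taxon.

    Returns (cluster label, nearest reference id, distance); ties broken by
    alphabetical reference id.
    """
    present = sorted(r for r in refs.labels if r in dm.taxa and r != query_id)
    if not present:
        raise ValueError("no cluster references present in the distance matrix")
    if query_id not in dm.taxa:
        raise ValueError(f"query {query_id!r} not in the distance matrix")
    best = min(present, key=lambda r: (dm.get(query_id, r), r))
    return refs.labels[best], best, dm.get(query_id, best)


def tanglegram_pairs(t1: PhyloTree, t2: PhyloTree) -> str:
    """TSV pairing of shared leaves with their ladder positions in the
    canonical ordering of each tree (for external tanglegram plotting)."""
    order1 = {leaf: i for i, leaf in enumerate(t1.copy().canonicalize().leaf_labels())}
    order2 = {leaf: i for i, leaf in enumerate(t2.copy().canonicalize().leaf_labels())}
    shared = sorted(set(order1) & set(order2))
    lines = ["leaf\tposition_tree1\tposition_tree2"]
    for leaf in shared:
        lines.append(f"{leaf}\t{order1[leaf]}\t{order2[leaf]}")
    return "\n".join(lines) + "\n"
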