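"""Kimura-corrected protein distances and neighbor-joining trees.

The observed proportion of differing residues p (pairwise-deletion: columns
with a gap or X in either row are skipped) is corrected for multiple hits
with Kimura's protein distance

    d = -ln(1 - p - 0.2 p**2)

saturating at a configurable cap where the argument leaves the domain.  A
Poisson-model correction d = -(19/20) ln(1 - (20/19) p) is also provided;
it is exact for the equal-exchangeability simulation model and is used by
the parameter-recovery tests.  Trees are built by canonical neighbor
joining and can be rooted by outgroup or midpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .align_concat import Alignment, ConcatenatedAlignment
from .tree import (
    Node,
    PhyloTree,
    canonical_split,
    clades_below,
    leaf_path_lengths,
    suppress_unifurcations,
    tree_splits,
    unroot,
)

_EXCLUDED = {"-", "X"}


@dataclass(frozen=True)
class DistanceParams:
    """Saturation cap (substitutions/site) and minimum column overlap."""

    d_max: float = 10.0
    min_overlap: int = 50

    def __post_init__(self):
        if self.d_max <= 0:
            raise ValueError("d_max must be > 0")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances over named taxa."""

    taxa: list[str]
    D: np.ndarray
    overlap: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.taxa)
        if self.D.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.D, self.D.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.D) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.D < 0):
            raise ValueError("distances must be non-negative")

    def get(self, a: str, b: str) -> float:
        return float(self.D[self.taxa.index(a), self.taxa.index(b)])

    def to_tsv(self, precision: int = 6) -> str:
        """PHYLIP-style square matrix as TSV."""
        lines = ["\t".join([""] + self.taxa)]
        for i, t in enumerate(self.taxa):
            lines.append(
                "\t".join([t] + [f"{self.D[i, j]:.{precision}f}" for j in range(len(self.taxa))])
            )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def p_distance(row_a: str, row_b: str) -> tuple[float, int]:
    """Observed difference proportion with pairwise deletion.

    Columns where either row carries a gap or X are excluded.  Returns
    (p, overlap); p is NaN when no columns overlap.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    overlap = 0
    mismatches = 0
    for a, b in zip(row_a, row_b):
        if a in _EXCLUDED or b in _EXCLUDED:
            continue
        overlap += 1
        if a != b:
            mismatches += 1
    return (mismatches / overlap if overlap else float("nan")), overlap


def kimura_correct(p: float, params: DistanceParams | None = None) -> float:
    """Kimura's protein distance d = -ln(1 - p - 0.2 p^2), capped at d_max."""
    params = params or DistanceParams()
    if not (0 <= p <= 1):
        raise ValueError("p must be in [0, 1]")
    arg = 1.0 - p - 0.2 * p * p
    if arg > math.exp(-params.d_max):
        return -math.log(arg)
    return params.d_max


def poisson_correct(p: float, params: DistanceParams | None = None) -> float:
    """Equal-exchangeability (20-state Poisson) inversion, capped at d_max."""
    params = params or DistanceParams()
    if not (0 <= p <= 1):
        raise ValueError("p must be in [0, 1]")
    arg = 1.0 - (20.0 / 19.0) * p
    if arg > math.exp(-params.d_max * 20.0 / 19.0):
        return -(19.0 / 20.0) * math.log(arg)
    return params.d_max


_CORRECTIONS = {"kimura": kimura_correct, "poisson": poisson_correct}


def distance_matrix(
    aln: Alignment | ConcatenatedAlignment,
    params: DistanceParams | None = None,
    model: str = "kimura",
) -> DistanceMatrix:
    """All-pairs corrected distances from a (concatenated) alignment."""
    params = params or DistanceParams()
    correct = _CORRECTIONS[model]
    taxa = sorted(aln.rows)
    if len(taxa) < 2:
        raise ValueError("need >= 2 rows")
    codes = {"-": 0, "X": 1}
    for i, aa in enumerate("ACDEFGHIKLMNPQRSTVWY"):
        codes[aa] = i + 2
    mat = np.array(
        [[codes.get(c, 1) for c in aln.rows[t]] for t in taxa], dtype=np.int8
    )
    valid = mat >= 2
    n = len(taxa)
    D = np.zeros((n, n))
    overlap = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            joint = valid[i] & valid[j]
            ov = int(joint.sum())
            overlap[i, j] = overlap[j, i] = ov
            if ov < params.min_overlap:
                d = params.d_max
            else:
                p = float(((mat[i] != mat[j]) & joint).sum()) / ov
                d = correct(p, params)
            D[i, j] = D[j, i] = d
    return DistanceMatrix(taxa=taxa, D=D, overlap=overlap)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Canonical (Saitou–Nei/Studier–Keppler) neighbor joining.

    Ties in the Q criterion are broken by the lexicographically smallest
    pair of cluster representative labels; negative branch lengths are
    clamped to zero.  Returns an unrooted tree (degree-3 junction for n>=3).
    """
    n = len(dm.taxa)
    if n < 2:
        raise ValueError("neighbor joining needs >= 2 taxa")
    if n == 2:
        root = Node()
        a, b = sorted(dm.taxa)
        d = dm.get(a, b)
        root.add_child(Node(label=a, length=d / 2.0))
        root.add_child(Node(label=b, length=d / 2.0))
        return PhyloTree(root, rooted=False)

    labels = sorted(dm.taxa)
    index = {t: i for i, t in enumerate(dm.taxa)}
    D: dict[frozenset, float] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            D[frozenset((a, b))] = float(dm.D[index[a], index[b]])
    nodes: dict[str, Node] = {t: Node(label=t) for t in labels}
    active = list(labels)  # representative = min leaf label in cluster

    while len(active) > 3:
        m = len(active)
        R = {a: sum(D[frozenset((a, b))] for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (m - 2) * D[frozenset((a, b))] - R[a] - R[b]
                key = (q, min(a, b), max(a, b))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        d_ab = D[frozenset((a, b))]
        va = d_ab / 2.0 + (R[a] - R[b]) / (2.0 * (m - 2))
        vb = d_ab - va
        parent = Node()
        na, nb = nodes[a], nodes[b]
        na.length = max(va, 0.0)
        nb.length = max(vb, 0.0)
        parent.add_child(na)
        parent.add_child(nb)
        rep = min(a, b)
        for other in active:
            if other in (a, b):
                continue
            d_new = 0.5 * (
                D[frozenset((a, other))] + D[frozenset((b, other))] - d_ab
            )
            D[frozenset((rep, other))] = d_new
        nodes[rep] = parent
        active = sorted(x for x in active if x not in (a, b)) + [rep]
        active = sorted(set(active))

    root = Node()
    if len(active) == 3:
        a, b, c = active
        dab = D[frozenset((a, b))]
        dac = D[frozenset((a, c))]
        dbc = D[frozenset((b, c))]
        lengths = {
            a: (dab + dac - dbc) / 2.0,
            b: (dab + dbc - dac) / 2.0,
            c: (dac + dbc - dab) / 2.0,
        }
        for t in active:
            nodes[t].length = max(lengths[t], 0.0)
            root.add_child(nodes[t])
    return PhyloTree(root, rooted=False)


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------

def _reroot_at_edge(tree: PhyloTree, child: Node, dist_from_child: float) -> PhyloTree:
    """New root placed on the edge above ``child``, at the given distance
    below the former parent side.  Branch lengths are conserved."""
    edge_len = child.length if child.length is not None else 0.0
    parent = child.parent
    if parent is None:
        raise ValueError("cannot reroot at the root edge")
    # collect path from parent up to old root
    path = [parent]
    while path[-1].parent is not None:
        path.append(path[-1].parent)
    parent.children.remove(child)
    # invert parent links along the path
    for i in range(len(path) - 1):
        node, up = path[i], path[i + 1]
        up.children.remove(node)
    for i in range(len(path) - 1, 0, -1):
        up, node = path[i], path[i - 1]
        # edge formerly (node -> up) becomes (up as child of node)
        up.parent = None
        up.length = node.length
        node.add_child(up)
    new_root = Node()
    child.parent = None
    child.length = dist_from_child
    parent.length = max(edge_len - dist_from_child, 0.0)
    parent.parent = None
    new_root.add_child(child)
    new_root.add_child(parent)
    out = PhyloTree(new_root, rooted=True)
    suppress_unifurcations(out)
    return out


def root_tree(
    tree: PhyloTree,
    outgroup: set[str] | None = None,
    midpoint: bool = False,
) -> PhyloTree:
    """Root an unrooted tree by outgroup or at the midpoint of the longest
    leaf-to-leaf path."""
    if (outgroup is None) == (not midpoint):
        raise ValueError("specify exactly one of outgroup or midpoint")
    work = unroot(tree)
    if outgroup is not None:
        universe = frozenset(work.leaf_labels())
        og = frozenset(outgroup)
        missing = og - universe
        if missing:
            raise ValueError(f"outgroup leaves not in tree: {sorted(missing)}")
        below = clades_below(work)
        target = None
        for node in work.nodes():
            if node is work.root:
                continue
            side = below[id(node)]
            if side == og or side == universe - og:
                target = node
                break
        if target is None:
            if len(og) >= 2:
                want = canonical_split(og, universe)
                conflicting = [
                    s for s in tree_splits(work)
                    if s & og and s - og and (universe - s) & og
                ]
                raise ValueError(
                    f"outgroup {sorted(og)} is not monophyletic under any rooting; "
                    f"conflicting bipartition(s): "
                    f"{[sorted(c) for c in conflicting[:3]] or [sorted(want)]}"
                )
            raise ValueError(f"outgroup {sorted(og)} not found")
        half = (target.length or 0.0) / 2.0
        rooted = _reroot_at_edge(work, target, half)
        return rooted
    # midpoint
    dists = leaf_path_lengths(work)
    if not dists:
        raise ValueError("midpoint rooting needs >= 2 leaves")
    (la, lb), total = max(dists.items(), key=lambda kv: (kv[1], kv[0]))
    # walk the a->b path accumulating branch lengths
    a = work.find_leaf(la)
    b = work.find_leaf(lb)
    anc_a = []
    node = a
    while node is not None:
        anc_a.append(node)
        node = node.parent
    anc_ids = {id(n): i for i, n in enumerate(anc_a)}
    node = b
    path_b = []
    while id(node) not in anc_ids:
        path_b.append(node)
        node = node.parent
    lca = node
    path = anc_a[: anc_ids[id(lca)]] + list(reversed(path_b))
    # path: nodes whose parent-edges compose the a->b path, ordered from a
    half = total / 2.0
    cum = 0.0
    for i, node in enumerate(path):
        ln = node.length or 0.0
        if cum + ln >= half or i == len(path) - 1:
            # distance from the child end of this edge:
            if node in anc_a:
                dist_from_child = half - cum
            else:
                dist_from_child = ln - (half - cum)
            dist_from_child = min(max(dist_from_child, 0.0), ln)
            return _reroot_at_edge(work, node, dist_from_child)
        cum += ln
    raise RuntimeError("midpoint not located")  # pragma: no cover
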