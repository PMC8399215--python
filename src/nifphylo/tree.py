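"""Lightweight phylogenetic tree container with canonical Newick serialization.

The tree type used across the package: nodes carry parent links, optional
branch lengths (``None`` means *absent*, which is distinct from 0.0), and
optional clade support on internal nodes.  Unrooted trees are stored with a
trifurcating (or higher-degree) pseudo-root and ``rooted=False``.

Serialization is canonical: children are ordered by the smallest leaf label
in their subtree, so any two trees with the same (rooted) topology, labels,
lengths and supports produce byte-identical Newick.
"""

from __future__ import annotations

from typing import Callable, Iterator, Optional


class NewickError(ValueError):
    """Malformed Newick input; carries the character offset of the problem."""

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (at character {offset})"
        super().__init__(message)
        self.offset = offset


class Node:
    __slots__ = ("label", "length", "support", "children", "parent")

    def __init__(
        self,
        label: str | None = None,
        length: float | None = None,
        support: float | None = None,
    ):
        self.label = label
        self.length = length
        self.support = support
        self.children: list[Node] = []
        self.parent: Optional[Node] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def traverse(self) -> Iterator["Node"]:
        """Pre-order traversal of the subtree rooted here."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        out: list[Node] = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))


class PhyloTree:
    """A rooted or unrooted tree over uniquely labeled leaves."""

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted
        self._check_unique_leaves()

    # -- basic accessors -------------------------------------------------

    def _check_unique_leaves(self) -> None:
        seen: set[str] = set()
        for leaf in self.leaves():
            if leaf.label is None:
                raise ValueError("unlabeled leaf")
            if leaf.label in seen:
                raise ValueError(f"duplicate leaf label: {leaf.label!r}")
            seen.add(leaf.label)

    def nodes(self) -> Iterator[Node]:
        return self.root.traverse()

    def leaves(self) -> list[Node]:
        return [n for n in self.root.traverse() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]  # type: ignore[misc]

    def n_leaves(self) -> int:
        return len(self.leaves())

    def is_binary(self) -> bool:
        """Binary as an unrooted tree: internal degree 3 (root degree 3 if
        unrooted, 2 if rooted)."""
        for node in self.nodes():
            if node.is_leaf:
                continue
            k = len(node.children)
            if node is self.root:
                want = 2 if self.rooted else 3
                if self.n_leaves() <= 3:
                    continue
                if k != want:
                    return False
            elif k != 2:
                return False
        return True

    def copy(self) -> "PhyloTree":
        def _copy(node: Node) -> Node:
            clone = Node(node.label, node.length, node.support)
            for child in node.children:
                clone.add_child(_copy(child))
            return clone

        return PhyloTree(_copy(self.root), rooted=self.rooted)

    def find_leaf(self, label: str) -> Node:
        for leaf in self.leaves():
            if leaf.label == label:
                return leaf
        raise KeyError(label)

    # -- canonical form --------------------------------------------------

    def canonicalize(self) -> "PhyloTree":
        """Sort children in place by smallest leaf label in their subtree."""
        min_leaf: dict[int, str] = {}
        for node in self.root.postorder():
            if node.is_leaf:
                min_leaf[id(node)] = node.label or ""
            else:
                node.children.sort(key=lambda c: min_leaf[id(c)])
                min_leaf[id(node)] = min_leaf[id(node.children[0])]
        return self

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"PhyloTree({write_newick(self)!r}, rooted={self.rooted})"


# ---------------------------------------------------------------------------
# Newick parsing / writing
# ---------------------------------------------------------------------------

_LABEL_FORBIDDEN = set("(),:;[]'\" \t\n\r")


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Branch lengths that are absent in the input stay ``None``.  Internal
    labels that parse as floats are stored as clade support, other internal
    labels are kept as node labels.  Errors carry the character offset.
    """
    s = text.strip()
    if not s:
        raise NewickError("empty Newick string", 0)
    pos = 0

    def peek() -> str:
        return s[pos] if pos < len(s) else ""

    def parse_label() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in _LABEL_FORBIDDEN:
            pos += 1
        return s[start:pos]

    def parse_length(node: Node) -> None:
        nonlocal pos
        if peek() == ":":
            pos += 1
            start = pos
            while pos < len(s) and (s[pos].isdigit() or s[pos] in ".eE+-"):
                pos += 1
            try:
                node.length = float(s[start:pos])
            except ValueError:
                raise NewickError("invalid branch length", start) from None

    def parse_clade() -> Node:
        nonlocal pos
        node = Node()
        if peek() == "(":
            open_at = pos
            pos += 1
            while True:
                node.add_child(parse_clade())
                if peek() == ",":
                    pos += 1
                    continue
                if peek() == ")":
                    pos += 1
                    break
                raise NewickError("unbalanced parentheses", open_at)
            label = parse_label()
            if label:
                try:
                    node.support = float(label)
                except ValueError:
                    node.label = label
        else:
            label = parse_label()
            if not label:
                raise NewickError("expected leaf label", pos)
            node.label = label
        parse_length(node)
        return node

    root = parse_clade()
    if peek() != ";":
        raise NewickError("expected ';' at end of tree", pos)
    pos += 1
    if s[pos:].strip():
        raise NewickError("trailing characters after ';'", pos)
    rooted = len(root.children) == 2
    return PhyloTree(root, rooted=rooted)


def format_length(x: float, precision: int = 6) -> str:
    """Fixed-point with trailing zeros stripped: 1.0 -> '1', 0.5 -> '0.5'."""
    out = f"{x:.{precision}f}".rstrip("0").rstrip(".")
    return out if out and out != "-0" else "0"


def write_newick(tree: PhyloTree, precision: int = 6) -> str:
    """Serialize canonically (children ordered by smallest leaf label)."""
    work = tree.copy().canonicalize()

    def fmt(node: Node) -> str:
        if node.is_leaf:
            body = node.label or ""
        else:
            inner = ",".join(fmt(c) for c in node.children)
            tag = ""
            if node.support is not None:
                tag = format_length(node.support, precision)
            elif node.label:
                tag = node.label
            body = f"({inner}){tag}"
        if node.length is not None:
            body += f":{format_length(node.length, precision)}"
        return body

    return fmt(work.root) + ";"


# ---------------------------------------------------------------------------
# Split (bipartition) machinery shared by the comparison/consensus code
# ---------------------------------------------------------------------------

def canonical_split(side: frozenset, universe: frozenset) -> frozenset:
    """Canonical representative of the bipartition {side | universe - side}:
    the smaller side, ties broken by lexicographically smaller sorted tuple."""
    other = universe - side
    if len(side) < len(other):
        return frozenset(side)
    if len(other) < len(side):
        return frozenset(other)
    return frozenset(min(tuple(sorted(side)), tuple(sorted(other))))


def tree_splits(tree: PhyloTree) -> set[frozenset]:
    """Nontrivial bipartitions of the *unrooted* topology, canonical form."""
    universe = frozenset(tree.leaf_labels())
    n = len(universe)
    splits: set[frozenset] = set()
    below: dict[int, frozenset] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.label])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
            if node is tree.root:
                continue
            side = below[id(node)]
            if 2 <= len(side) <= n - 2:
                splits.add(canonical_split(side, universe))
    return splits


def clades_below(tree: PhyloTree) -> dict[int, frozenset]:
    """Map id(node) -> leaf-label set below that node."""
    below: dict[int, frozenset] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.label])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
    return below


def suppress_unifurcations(tree: PhyloTree) -> PhyloTree:
    """Collapse degree-2 internal nodes in place, summing branch lengths."""
    changed = True
    while changed:
        changed = False
        for node in list(tree.nodes()):
            if node.is_leaf or node is tree.root:
                continue
            if len(node.children) == 1:
                child = node.children[0]
                if node.length is not None or child.length is not None:
                    child.length = (node.length or 0.0) + (child.length or 0.0)
                parent = node.parent
                assert parent is not None
                idx = parent.children.index(node)
                parent.children[idx] = child
                child.parent = parent
                changed = True
        if not tree.root.is_leaf and len(tree.root.children) == 1:
            new_root = tree.root.children[0]
            if new_root.is_leaf:
                break
            new_root.parent = None
            new_root.length = None
            tree.root = new_root
            changed = True
    return tree


def restrict(tree: PhyloTree, keep: set[str] | frozenset) -> PhyloTree:
    """Tree induced on the leaf subset ``keep`` (unifurcations suppressed)."""
    keep = frozenset(keep)
    missing = keep - set(tree.leaf_labels())
    if missing:
        raise KeyError(f"leaves not in tree: {sorted(missing)}")
    work = tree.copy()

    def prune(node: Node) -> Optional[Node]:
        if node.is_leaf:
            return node if node.label in keep else None
        kept = [c for c in node.children if prune_result[id(c)] is not None]
        node.children = [prune_result[id(c)] for c in node.children
                         if prune_result[id(c)] is not None]
        for c in node.children:
            c.parent = node
        return node if node.children else None

    prune_result: dict[int, Optional[Node]] = {}
    for node in work.root.postorder():
        prune_result[id(node)] = prune(node)
    new_root = prune_result[id(work.root)]
    if new_root is None:
        raise ValueError("restriction removes every leaf")
    new_root.parent = None
    out = PhyloTree(new_root, rooted=work.rooted)
    suppress_unifurcations(out)
    if not out.root.is_leaf and len(out.root.children) == 1:
        child = out.root.children[0]
        child.parent = None
        child.length = None
        out.root = child
    out.rooted = len(out.root.children) == 2
    return out


def unroot(tree: PhyloTree) -> PhyloTree:
    """Return an unrooted copy (pseudo-root of degree >= 3 when possible)."""
    work = tree.copy()
    root = work.root
    if len(root.children) == 2 and work.n_leaves() > 2:
        a, b = root.children
        keep, absorb = (a, b) if not a.is_leaf else (b, a)
        if keep.is_leaf:  # two-leaf tree: nothing to unroot
            work.rooted = False
            return work
        # merge the two root edges into one
        absorb.length = (
            None
            if absorb.length is None and keep.length is None
            else (absorb.length or 0.0) + (keep.length or 0.0)
        )
        new_root = Node()
        for child in keep.children:
            new_root.add_child(child)
        new_root.add_child(absorb)
        new_root.support = keep.support
        out = PhyloTree(new_root, rooted=False)
        return out
    work.rooted = False
    return work


def leaf_path_lengths(tree: PhyloTree) -> dict[tuple[str, str], float]:
    """Patristic distances between all leaf pairs (absent lengths count 0)."""
    dists: dict[tuple[str, str], float] = {}
    # leaf distances propagated up the tree
    below: dict[int, dict[str, float]] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            below[id(node)] = {node.label: 0.0}  # type: ignore[dict-item]
        else:
            merged: dict[str, float] = {}
            child_maps = []
            for child in node.children:
                cm = {k: v + (child.length or 0.0) for k, v in below[id(child)].items()}
                child_maps.append(cm)
                merged.update(cm)
            for i in range(len(child_maps)):
                for j in range(i + 1, len(child_maps)):
                    for la, da in child_maps[i].items():
                        for lb, db in child_maps[j].items():
                            key = (la, lb) if la < lb else (lb, la)
                            dists[key] = da + db
            below[id(node)] = merged
    return dists
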