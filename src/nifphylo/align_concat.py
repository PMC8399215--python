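"""Progressive multiple alignment and supermatrix concatenation.

The aligner follows the classic progressive architecture: a k-mer-distance
UPGMA guide tree, then post-order profile–profile merges scored by
mean-of-pairs BLOSUM62 with affine gaps (Needleman–Wunsch/Gotoh kernel).
Per-role alignments are concatenated row-matched into one partitioned
supermatrix in fixed role order.

Gap cost convention: a gap of length L costs ``open + (L-1)*extend`` (the
opening residue carries the open penalty).  Terminal gaps are penalized like
internal ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .io_formats import AMINO_ACIDS, SequenceRecord, PartitionMap
from .tree import Node, PhyloTree

_NEG = -1e30  # effectively -inf but arithmetic-safe

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def _default_matrix() -> np.ndarray:
    """BLOSUM62 over the 20 canonical residues plus an X row/column of 0."""
    blosum = substitution_matrices.load("BLOSUM62")
    m = np.zeros((21, 21))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            m[i, j] = blosum[a][b]
    return m


@dataclass
class ScoringScheme:
    """Substitution matrix plus affine gap penalties (both positive costs)."""

    matrix: np.ndarray = field(default_factory=_default_matrix)
    gap_open: float = 10.0
    gap_extend: float = 1.0

    def __post_init__(self):
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")
        if not (self.gap_open >= self.gap_extend > 0):
            raise ValueError("require gap_open >= gap_extend > 0")

    def score(self, a: str, b: str) -> float:
        ia = _AA_INDEX.get(a, 20)
        ib = _AA_INDEX.get(b, 20)
        return float(self.matrix[ia, ib])


@dataclass
class Alignment:
    """One role's multiple alignment: genome_id -> gapped row."""

    role: str
    rows: dict[str, str]

    def __post_init__(self):
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"alignment {self.role}: unequal row lengths {lengths}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def ids(self) -> list[str]:
        return list(self.rows)


@dataclass
class ConcatenatedAlignment:
    """Row-matched supermatrix with a partition map in role order."""

    rows: dict[str, str]
    partitions: PartitionMap

    def __post_init__(self):
        total = self.partitions.total_length
        for gid, row in self.rows.items():
            if len(row) != total:
                raise ValueError(
                    f"row {gid} length {len(row)} != partition total {total}"
                )

    @property
    def length(self) -> int:
        return self.partitions.total_length

    def deconcatenate(self) -> list[Alignment]:
        out = []
        for name, start, end in self.partitions.entries:
            out.append(
                Alignment(role=name, rows={g: r[start:end] for g, r in self.rows.items()})
            )
        return out


# ---------------------------------------------------------------------------
# Affine-gap dynamic programming kernel (shared by sequence and profile paths)
# ---------------------------------------------------------------------------

def _affine_dp(S: np.ndarray, open_: float, extend: float):
    """Global affine-gap DP over a precomputed column-score matrix S (n x m).

    Returns (score, ops) where ops is the alignment path as a string over
    {'M' consume both, 'X' consume a row (gap in b), 'Y' consume a column
    (gap in a)}.  Tie-break order everywhere: M > Y (gap in a) > X (gap in b).
    """
    n, m = S.shape
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        Y[0, j] = -(open_ + (j - 1) * extend)
    js = np.arange(m + 1)
    for i in range(1, n + 1):
        X[i, 0] = -(open_ + (i - 1) * extend)
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = S[i - 1] + prev_best[:-1]
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) - open_, X[i - 1, 1:] - extend
        )
        # gap-in-a run ending at column j started after some column k < j:
        # Y[j] = max_k (Z[k] - open - (j-1-k) extend), via a running max
        Z = np.maximum(M[i], X[i])
        u = Z + js * extend
        run = np.maximum.accumulate(u)
        Y[i, 1:] = run[:-1] - open_ - (js[1:] - 1) * extend

    end_vals = (M[n, m], Y[n, m], X[n, m])  # preference order M, Y, X
    score = max(end_vals)
    state = "MYX"[int(np.argmax(end_vals))]

    ops = []
    i, j = n, m
    eps = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            ops.append("M")
            target = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            cands = [("M", M[i, j]), ("Y", Y[i, j]), ("X", X[i, j])]
        elif state == "X":
            ops.append("X")
            target = X[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            cands = [
                ("M", M[i, j] - open_),
                ("Y", Y[i, j] - open_),
                ("X", X[i, j] - extend),
            ]
        else:
            ops.append("Y")
            target = Y[i, j]
            j -= 1
            if i == 0 and j == 0:
                break
            cands = [
                ("M", M[i, j] - open_),
                ("X", X[i, j] - open_),
                ("Y", Y[i, j] - extend),
            ]
        state = min(cands, key=lambda sv: (abs(sv[1] - target), "MYX".index(sv[0])))[0]
        if abs(dict(cands)[state] - target) > eps:  # pragma: no cover - sanity
            raise RuntimeError("affine DP traceback inconsistency")
    return float(score), "".join(reversed(ops))


def _encode(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(c, 20) for c in seq], dtype=np.intp)


def pairwise_align(a: str, b: str, scheme: ScoringScheme | None = None):
    """Optimal global alignment of two ungapped protein sequences.

    Returns (aligned_a, aligned_b, score).  Deterministic tie-breaking:
    match/mismatch preferred over a gap in ``a``, preferred over a gap in
    ``b``.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequence")
    scheme = scheme or ScoringScheme()
    S = scheme.matrix[np.ix_(_encode(a), _encode(b))]
    score, ops = _affine_dp(S, scheme.gap_open, scheme.gap_extend)
    out_a, out_b = [], []
    i = j = 0
    for op in ops:
        if op == "M":
            out_a.append(a[i]); out_b.append(b[j]); i += 1; j += 1
        elif op == "X":
            out_a.append(a[i]); out_b.append("-"); i += 1
        else:
            out_a.append("-"); out_b.append(b[j]); j += 1
    return "".join(out_a), "".join(out_b), score


# ---------------------------------------------------------------------------
# Guide tree (k-mer distance UPGMA)
# ---------------------------------------------------------------------------

def kmer_distance(a: str, b: str, k: int = 3) -> float:
    """1 - shared k-mers / min(#k-mers); identical short sequences get 0."""
    ka = {a[i:i + k] for i in range(len(a) - k + 1)}
    kb = {b[i:i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 0.0 if a == b else 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def build_guide_tree(seqs: list[SequenceRecord]) -> PhyloTree:
    """UPGMA tree on pairwise k-mer distances; deterministic tie-breaking by
    smallest representative label pair."""
    if len(seqs) < 2:
        raise ValueError("guide tree needs >= 2 sequences")
    items = sorted(seqs, key=lambda s: s.id)
    nodes = {s.id: Node(label=s.id) for s in items}
    heights = {s.id: 0.0 for s in items}
    sizes = {s.id: 1 for s in items}
    dist: dict[frozenset, float] = {}
    for i, si in enumerate(items):
        for sj in items[i + 1:]:
            dist[frozenset((si.id, sj.id))] = kmer_distance(si.sequence, sj.sequence)
    active = [s.id for s in items]
    while len(active) > 1:
        best = min(
            (
                (dist[frozenset((a, b))], a, b)
                for idx, a in enumerate(active)
                for b in active[idx + 1:]
            ),
            key=lambda t: (t[0], t[1], t[2]),
        )
        d, a, b = best
        h = d / 2.0
        parent = Node(label=None)
        na, nb = nodes[a], nodes[b]
        na.length = max(h - heights[a], 0.0)
        nb.length = max(h - heights[b], 0.0)
        parent.add_child(na)
        parent.add_child(nb)
        rep = min(a, b)
        for other in active:
            if other in (a, b):
                continue
            key = frozenset((rep, other))
            dist[key] = (
                sizes[a] * dist[frozenset((a, other))]
                + sizes[b] * dist[frozenset((b, other))]
            ) / (sizes[a] + sizes[b])
        nodes[rep] = parent
        heights[rep] = h
        sizes[rep] = sizes[a] + sizes[b]
        active = [x for x in active if x not in (a, b)] + [rep]
        active.sort()
    root = nodes[active[0]]
    return PhyloTree(root, rooted=True)


# ---------------------------------------------------------------------------
# Progressive alignment
# ---------------------------------------------------------------------------

class _Profile:
    """Rows (parallel gapped strings) plus a residue-count matrix (L x 21)."""

    __slots__ = ("ids", "rows", "counts")

    def __init__(self, ids: list[str], rows: list[str], counts: np.ndarray):
        self.ids = ids
        self.rows = rows
        self.counts = counts

    @classmethod
    def from_sequence(cls, sid: str, seq: str) -> "_Profile":
        counts = np.zeros((len(seq), 21))
        for i, c in enumerate(seq):
            if c != "-":
                counts[i, _AA_INDEX.get(c, 20)] = 1.0
        return cls([sid], [seq], counts)


def _merge_profiles(p: _Profile, q: _Profile, scheme: ScoringScheme) -> _Profile:
    # mean-of-pairs column score; gap characters score 0 against everything
    S = (p.counts @ scheme.matrix @ q.counts.T) / (len(p.ids) * len(q.ids))
    _, ops = _affine_dp(S, scheme.gap_open, scheme.gap_extend)
    rows_p = ["" for _ in p.ids]
    rows_q = ["" for _ in q.ids]
    i = j = 0
    for op in ops:
        if op == "M":
            for r in range(len(p.ids)):
                rows_p[r] += p.rows[r][i]
            for r in range(len(q.ids)):
                rows_q[r] += q.rows[r][j]
            i += 1; j += 1
        elif op == "X":
            for r in range(len(p.ids)):
                rows_p[r] += p.rows[r][i]
            for r in range(len(q.ids)):
                rows_q[r] += "-"
            i += 1
        else:
            for r in range(len(p.ids)):
                rows_p[r] += "-"
            for r in range(len(q.ids)):
                rows_q[r] += q.rows[r][j]
            j += 1
    ids = p.ids + q.ids
    rows = rows_p + rows_q
    counts = np.zeros((len(rows[0]), 21))
    for row in rows:
        for col, c in enumerate(row):
            if c != "-":
                counts[col, _AA_INDEX.get(c, 20)] += 1.0
    return _Profile(ids, rows, counts)


def progressive_align(
    seqs: list[SequenceRecord],
    guide: PhyloTree | None = None,
    scheme: ScoringScheme | None = None,
    role: str = "aln",
) -> Alignment:
    """Guide-tree progressive alignment; output row order = input order."""
    scheme = scheme or ScoringScheme()
    if not seqs:
        raise ValueError("no sequences to align")
    if len(seqs) == 1:
        return Alignment(role=role, rows={seqs[0].id: seqs[0].sequence})
    guide = guide or build_guide_tree(seqs)
    if set(guide.leaf_labels()) != {s.id for s in seqs}:
        raise ValueError("guide tree leaves do not match sequence ids")
    by_id = {s.id: s.sequence for s in seqs}
    profiles: dict[int, _Profile] = {}
    for node in guide.root.postorder():
        if node.is_leaf:
            profiles[id(node)] = _Profile.from_sequence(node.label, by_id[node.label])
        else:
            merged = profiles[id(node.children[0])]
            for child in node.children[1:]:
                merged = _merge_profiles(merged, profiles[id(child)], scheme)
            profiles[id(node)] = merged
    final = profiles[id(guide.root)]
    rows = dict(zip(final.ids, final.rows))
    aln = Alignment(role=role, rows={s.id: rows[s.id] for s in seqs})
    # drop any all-gap columns (cannot normally arise from profile merges)
    gap_cols = [
        c
        for c in range(aln.length)
        if all(row[c] == "-" for row in aln.rows.values())
    ]
    if gap_cols:
        keep = [c for c in range(aln.length) if c not in set(gap_cols)]
        aln = Alignment(
            role=role,
            rows={g: "".join(r[c] for c in keep) for g, r in aln.rows.items()},
        )
    return aln



def validate_alignment(aln: Alignment) -> list[str]:
    """Report-only validation: row lengths, alphabet, all-gap rows/columns."""
    violations: list[str] = []
    lengths = {len(r) for r in aln.rows.values()}
    if len(lengths) > 1:
        violations.append("unequal length")
        return violations
    for gid, row in aln.rows.items():
        bad = sorted({c for c in row if c not in set(AMINO_ACIDS + "X-")})
        if bad:
            violations.append(f"row {gid}: invalid characters {bad}")
        if row and set(row) == {"-"}:
            violations.append(f"row {gid}: all gaps")
    for col in range(aln.length):
        if all(row[col] == "-" for row in aln.rows.values()):
            violations.append(f"column {col}: all gaps")
    return violations


def concatenate(alns: list[Alignment], role_order: tuple[str, ...] | None = None) -> ConcatenatedAlignment:
    """Join per-role alignments row-matched into a partitioned supermatrix.

    Every genome must be present in every role alignment (the six-gene
    selection guarantees this for complete complements).
    """
    if not alns:
        raise ValueError("nothing to concatenate")
    if role_order is not None:
        by_role = {a.role: a for a in alns}
        missing_roles = [r for r in role_order if r not in by_role]
        if missing_roles:
            raise ValueError(f"missing role alignment(s): {missing_roles}")
        alns = [by_role[r] for r in role_order]
    genomes = sorted(alns[0].rows)
    for aln in alns:
        missing = sorted(set(genomes) ^ set(aln.rows))
        if missing:
            raise ValueError(
                f"genome/role mismatch in {aln.role}: {missing} "
                "(only complete complements can be concatenated)"
            )
    entries = []
    offset = 0
    for aln in alns:
        entries.append((aln.role, offset, offset + aln.length))
        offset += aln.length
    rows = {g: "".join(aln.rows[g] for aln in alns) for g in genomes}
    return ConcatenatedAlignment(rows=rows, partitions=PartitionMap(entries))
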