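"""Ground-truth fixture generation: species trees, planted transfers,
sequence evolution, and genome annotations with planted nif operons.

Everything the pipeline consumes can be generated here with a known truth
log: Yule species trees, gene trees derived by subtree-prune-regraft (SPR)
moves that emulate horizontal transfer, protein sequences evolved under a
20-state equal-exchangeability Poisson model (closed-form identity
P(same) = 1/20 + (19/20) e^{-(20/19) d}), and per-genome annotation tables
carrying co-located six-gene operons, distal decoy paralogs, fused EN/NB
open reading frames, and incomplete complements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .complement_screen import DEFAULT_ROLE_LENGTHS
from .io_formats import (
    GeneRecord,
    GenomeAnnotation,
    SequenceRecord,
    write_annotation_table,
    write_fasta,
    write_newick,
)
from .tree import Node, PhyloTree, clades_below, suppress_unifurcations
from .tree_compare import rf_distance

AA = "ACDEFGHIKLMNPQRSTVWY"

ROLE_SYMBOLS = {"H": "nifH", "D": "nifD", "K": "nifK",
                "E": "nifE", "N": "nifN", "B": "nifB"}
FUSED_SYMBOLS = {"EN": "nifEN", "NB": "nifNB"}

_PHYLA = ("Proteobacteria", "Firmicutes", "Cyanobacteria", "Actinobacteria")


@dataclass(frozen=True)
class EvolutionModel:
    """20-state equal-exchangeability Poisson process; branch lengths are
    expected substitutions/site.  Optional discrete-gamma site rates."""

    rate: float = 1.0
    gamma_shape: float | None = None
    gamma_categories: int = 4

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("rate must be > 0")


@dataclass(frozen=True)
class TransferEvent:
    role: str
    moved: tuple[str, ...]
    donor_edge: tuple[str, ...]
    recipient_edge: tuple[str, ...]


@dataclass
class PlantedComplement:
    status: str
    chosen_protein_ids: dict[str, str]
    fusion_flags: tuple[str, ...] = ()
    missing_roles: tuple[str, ...] = ()
    decoy_ids: tuple[str, ...] = ()


@dataclass
class SimulationTruth:
    """Everything planted by the generator, reproducible from the seed."""

    seed: int
    species_tree: PhyloTree | None = None
    gene_trees: dict[str, PhyloTree] = field(default_factory=dict)
    transfer_log: list[TransferEvent] = field(default_factory=list)
    complements: dict[str, PlantedComplement] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "species_tree": (
                write_newick(self.species_tree) if self.species_tree else None
            ),
            "gene_trees": {r: write_newick(t) for r, t in self.gene_trees.items()},
            "transfer_log": [
                {
                    "role": e.role,
                    "moved": list(e.moved),
                    "donor_edge": list(e.donor_edge),
                    "recipient_edge": list(e.recipient_edge),
                }
                for e in self.transfer_log
            ],
            "complements": {
                g: {
                    "status": c.status,
                    "chosen_protein_ids": c.chosen_protein_ids,
                    "fusion_flags": list(c.fusion_flags),
                    "missing_roles": list(c.missing_roles),
                    "decoy_ids": list(c.decoy_ids),
                }
                for g, c in sorted(self.complements.items())
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def simulate_yule_tree(
    n: int, birth_rate: float = 1.0, seed: int = 0, height: float = 0.5
) -> PhyloTree:
    """Pure-birth (Yule) ultrametric tree with ``n`` leaves, scaled so the
    root-to-tip height equals ``height`` expected substitutions/site.
    Leaves are labeled g0001… in traversal order."""
    if n < 2 or birth_rate <= 0:
        raise ValueError("need n >= 2 and birth_rate > 0")
    rng = np.random.default_rng(seed)
    root = Node()
    first, second = Node(), Node()
    root.add_child(first)
    root.add_child(second)
    active = [first, second]
    birth = {id(first): 0.0, id(second): 0.0}
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = int(rng.integers(len(active)))
        node = active.pop(idx)
        node.length = t - birth[id(node)]
        for _ in range(2):
            child = Node()
            node.add_child(child)
            birth[id(child)] = t
            active.append(child)
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for node in active:
        node.length = t - birth[id(node)]
    scale = height / t
    for node in root.traverse():
        if node.length is not None:
            node.length *= scale
    idx = 0
    for node in root.traverse():
        if node.is_leaf:
            idx += 1
            node.label = f"g{idx:04d}"
    return PhyloTree(root, rooted=True)


def clamp_branch_lengths(tree: PhyloTree, lo: float, hi: float) -> PhyloTree:
    """Copy with branch lengths clipped into [lo, hi] (moderate-rate regime
    used by the recovery tests; the result is no longer ultrametric)."""
    out = tree.copy()
    for node in out.nodes():
        if node.length is not None:
            node.length = min(max(node.length, lo), hi)
    return out


def _edge_path_length(tree: PhyloTree, a: Node, b: Node) -> int:
    """Number of edges between two nodes (via parent links)."""
    anc = {}
    node, d = a, 0
    while node is not None:
        anc[id(node)] = d
        node, d = node.parent, d + 1
    node, d = b, 0
    while id(node) not in anc:
        node, d = node.parent, d + 1
    return d + anc[id(node)]


def apply_spr_transfers(
    tree: PhyloTree,
    k: int,
    seed: int = 0,
    leaf_only: bool = False,
    role: str = "",
    min_regraft_distance: int = 0,
) -> tuple[PhyloTree, list[TransferEvent]]:
    """Apply ``k`` sequential SPR moves (each a planted transfer).

    Moves whose result is topologically identical to the pre-move tree are
    rejected and redrawn; each accepted move is logged with the moved clade
    and the donor/recipient edges (as the leaf sets below them).  With
    ``min_regraft_distance`` > 0 only long-range moves are drawn (at least
    that many edges between the pruned position and the regraft edge) — the
    "distant clade" transfers whose discordance signal is unambiguous.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if tree.n_leaves() < 4:
        raise ValueError("SPR needs >= 4 leaves")
    rng = np.random.default_rng(seed)
    current = tree.copy()
    log: list[TransferEvent] = []
    for _ in range(k):
        accepted = False
        for _attempt in range(200):
            cand = current.copy()
            nodes = [
                n for n in cand.nodes()
                if n is not cand.root and (not leaf_only or n.is_leaf)
            ]
            below = clades_below(cand)
            prune = nodes[int(rng.integers(len(nodes)))]
            parent = prune.parent
            if parent is None or len(parent.children) < 2:
                continue
            subtree_ids = {id(n) for n in prune.traverse()}
            targets = [
                n for n in cand.nodes()
                if n is not cand.root and id(n) not in subtree_ids
                and n is not parent
            ]
            if not targets:
                continue
            target = targets[int(rng.integers(len(targets)))]
            if (
                min_regraft_distance > 0
                and _edge_path_length(cand, parent, target) < min_regraft_distance
            ):
                continue
            siblings = [c for c in parent.children if c is not prune]
            donor = tuple(sorted(set().union(*(below[id(s)] for s in siblings))))
            parent.children.remove(prune)
            prune.parent = None
            if parent.parent is None and len(parent.children) == 1:
                new_root = parent.children[0]
                new_root.parent = None
                new_root.length = None
                cand.root = new_root
            else:
                suppress_unifurcations(cand)
            if target.parent is None:  # target got promoted to root by detach
                continue
            tparent = target.parent
            idx = tparent.children.index(target)
            mid = Node()
            half = (target.length / 2.0) if target.length is not None else None
            mid.length = half
            tparent.children[idx] = mid
            mid.parent = tparent
            target.length = half
            mid.add_child(target)
            if prune.length is None:
                prune.length = half if half is not None else 0.0
            mid.add_child(prune)
            cand_tree = PhyloTree(cand.root, rooted=True)
            rf, _ = rf_distance(
                _as_unrooted_copy(cand_tree), _as_unrooted_copy(current)
            )
            if rf == 0:
                continue
            recipient = tuple(sorted(clades_below(cand_tree)[id(target)]))
            log.append(
                TransferEvent(
                    role=role,
                    moved=tuple(sorted(clades_below(cand_tree)[id(prune)])),
                    donor_edge=donor,
                    recipient_edge=recipient,
                )
            )
            current = cand_tree
            accepted = True
            break
        if not accepted:
            raise ValueError("no distinct SPR move available")
    return current, log


def _as_unrooted_copy(tree: PhyloTree) -> PhyloTree:
    from .tree import unroot

    return unroot(tree)


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def p_same(d: float) -> float:
    """Closed-form probability a site is identical across a branch of
    length d under the 20-state Poisson model."""
    return 1.0 / 20.0 + (19.0 / 20.0) * np.exp(-(20.0 / 19.0) * d)


def evolve_sequences(
    tree: PhyloTree,
    L: int,
    model: EvolutionModel | None = None,
    seed: int = 0,
) -> dict[str, str]:
    """Evolve an L-site protein along the tree; returns leaf label -> sequence."""
    model = model or EvolutionModel()
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = np.random.default_rng(seed)
    for node in tree.nodes():
        if node is not tree.root and node.length is None:
            raise ValueError("missing branch length")
    if model.gamma_shape is not None:
        # discrete-gamma site rate multipliers (category means, mean 1)
        from scipy.stats import gamma as _gamma

        k = model.gamma_categories
        quantiles = (np.arange(k) + 0.5) / k
        cats = _gamma.ppf(quantiles, a=model.gamma_shape,
                          scale=1.0 / model.gamma_shape)
        cats = cats / cats.mean()
        site_rates = cats[rng.integers(0, k, size=L)]
    else:
        site_rates = np.ones(L)

    seqs: dict[int, np.ndarray] = {id(tree.root): rng.integers(0, 20, size=L)}
    out: dict[str, str] = {}
    for node in tree.nodes():
        if node is tree.root:
            pass
        else:
            parent_seq = seqs[id(node.parent)]
            d = node.length * model.rate * site_rates
            q = (19.0 / 20.0) * (1.0 - np.exp(-(20.0 / 19.0) * d))
            child = parent_seq.copy()
            hit = rng.random(L) < q
            n_hit = int(hit.sum())
            if n_hit:
                child[hit] = (child[hit] + rng.integers(1, 20, size=n_hit)) % 20
            seqs[id(node)] = child
        if node.is_leaf:
            out[node.label] = "".join(AA[i] for i in seqs[id(node)])
    return out


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA[i] for i in rng.integers(0, 20, size=length))


# ---------------------------------------------------------------------------
# Genome fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureParams:
    """Study conditions for screening fixtures."""

    n_genomes: int = 20
    operon_span_bp: int = 12_000
    decoy_distance_bp: int = 500_000
    decoy_probability: float = 0.5
    fraction_incomplete: float = 0.3
    fraction_fused: float = 0.2
    role_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_ROLE_LENGTHS)
    )

    def __post_init__(self):
        if self.decoy_distance_bp <= self.operon_span_bp:
            raise ValueError("decoy distance must exceed the operon span")


def generate_genome_fixtures(
    params: FixtureParams | None = None,
    seed: int = 0,
    species_tree: PhyloTree | None = None,
) -> tuple[list[GenomeAnnotation], SimulationTruth]:
    """Genomes with planted operons, decoys, fusions and incomplete
    complements, plus the truth log.

    When a species tree is supplied, genome ids are its leaf labels and the
    per-role proteins are evolved along it; otherwise proteins are random
    and ids are g0001…  Counts of incomplete / fused genomes are exact:
    round(fraction * n).
    """
    params = params or FixtureParams()
    rng = np.random.default_rng(seed)
    roles = tuple("HDKENB")

    if species_tree is not None:
        genome_ids = sorted(species_tree.leaf_labels())
        if len(genome_ids) != params.n_genomes:
            raise ValueError("species tree leaf count != n_genomes")
        role_seqs = {
            role: evolve_sequences(
                species_tree,
                params.role_lengths[role],
                seed=int(rng.integers(2**31 - 1)),
            )
            for role in roles
        }
    else:
        genome_ids = [f"g{i:04d}" for i in range(1, params.n_genomes + 1)]
        role_seqs = {
            role: {
                gid: random_protein(rng, params.role_lengths[role])
                for gid in genome_ids
            }
            for role in roles
        }

    n = params.n_genomes
    k_inc = int(round(params.fraction_incomplete * n))
    k_fus = int(round(params.fraction_fused * n))
    if k_inc + k_fus > n:
        raise ValueError("incomplete + fused fractions exceed 1")
    perm = list(rng.permutation(n))
    incomplete_set = {genome_ids[i] for i in perm[:k_inc]}
    fused_set = {genome_ids[i] for i in perm[k_inc:k_inc + k_fus]}

    genomes: list[GenomeAnnotation] = []
    truth = SimulationTruth(seed=seed, species_tree=species_tree)
    for gi, gid in enumerate(genome_ids):
        plan_roles: list[tuple[str, str, int, str]] = []  # (symbol, pid, aa_len, seq)
        fusion_flags: tuple[str, ...] = ()
        missing: tuple[str, ...] = ()
        if gid in fused_set:
            pair = "EN" if rng.random() < 0.5 else "NB"
            fusion_flags = (pair,)
            fused_seq = role_seqs[pair[0]][gid] + role_seqs[pair[1]][gid]
            for role in roles:
                if role == pair[0]:
                    plan_roles.append(
                        (FUSED_SYMBOLS[pair], f"{gid}_{pair}", len(fused_seq), fused_seq)
                    )
                elif role == pair[1]:
                    continue
                else:
                    seq = role_seqs[role][gid]
                    plan_roles.append((ROLE_SYMBOLS[role], f"{gid}_{role}", len(seq), seq))
        elif gid in incomplete_set:
            n_drop = int(rng.integers(1, 3))
            dropped = sorted(
                np.array(roles)[rng.choice(len(roles), size=n_drop, replace=False)]
            )
            missing = tuple(dropped)
            for role in roles:
                if role in dropped:
                    continue
                seq = role_seqs[role][gid]
                plan_roles.append((ROLE_SYMBOLS[role], f"{gid}_{role}", len(seq), seq))
        else:
            for role in roles:
                seq = role_seqs[role][gid]
                plan_roles.append((ROLE_SYMBOLS[role], f"{gid}_{role}", len(seq), seq))

        # lay the operon out on one contig inside the stated span
        genes: list[GeneRecord] = []
        total_bp = sum(3 * aa for _, _, aa, _ in plan_roles)
        gaps = max(len(plan_roles) - 1, 1)
        intergenic = max((params.operon_span_bp - total_bp) // gaps, 10)
        pos = 100_000
        for symbol, pid, aa_len, seq in plan_roles:
            end = pos + 3 * aa_len - 1
            genes.append(
                GeneRecord(
                    symbol=symbol, contig="ctg1", start=pos, end=end,
                    strand="+", protein_id=pid,
                    protein=SequenceRecord(id=pid, sequence=seq),
                )
            )
            pos = end + 1 + intergenic

        decoy_ids: list[str] = []
        if rng.random() < params.decoy_probability and plan_roles:
            role = roles[int(rng.integers(len(roles)))]
            if not (gid in incomplete_set and role in missing):
                pid = f"{gid}_{role}_decoy"
                length = params.role_lengths[role]
                start = 100_000 + params.decoy_distance_bp
                genes.append(
                    GeneRecord(
                        symbol=ROLE_SYMBOLS[role], contig="ctg1",
                        start=start, end=start + 3 * length - 1, strand="+",
                        protein_id=pid,
                        protein=SequenceRecord(
                            id=pid, sequence=random_protein(rng, length)
                        ),
                    )
                )
                decoy_ids.append(pid)

        taxon = {"phylum": _PHYLA[gi % len(_PHYLA)], "genus": f"Genus{gi % 7}"}
        genomes.append(GenomeAnnotation(genome_id=gid, genes=genes, taxon=taxon))

        chosen = {}
        if not missing:
            for role in roles:
                if fusion_flags and role in fusion_flags[0]:
                    chosen[role] = f"{gid}_{fusion_flags[0]}"
                else:
                    chosen[role] = f"{gid}_{role}"
        truth.complements[gid] = PlantedComplement(
            status="incomplete" if missing else "complete",
            chosen_protein_ids=chosen,
            fusion_flags=fusion_flags,
            missing_roles=missing,
            decoy_ids=tuple(decoy_ids),
        )
    return genomes, truth


def hgt_scenario(
    n_leaves: int = 16,
    n_transfers: int = 1,
    L: int = 2000,
    seed: int = 0,
    branch_range: tuple[float, float] = (0.02, 0.3),
    min_regraft_distance: int = 4,
) -> tuple[PhyloTree, PhyloTree, list[TransferEvent], dict[str, str]]:
    """Species tree + gene tree with planted distant-clade leaf transfers +
    sequences evolved along the *gene* tree (the signal an HGT scan must
    detect).  Short-range moves are excluded by ``min_regraft_distance``:
    an NNI-scale move is explainable by more than one leaf, so its source
    is not identifiable even in principle.

    Returns (species_tree, gene_tree, transfer_log, leaf sequences).
    """
    rng = np.random.default_rng(seed)
    species = simulate_yule_tree(
        n_leaves, seed=int(rng.integers(2**31 - 1)), height=1.0
    )
    species = clamp_branch_lengths(species, *branch_range)
    gene, log = apply_spr_transfers(
        species,
        n_transfers,
        seed=int(rng.integers(2**31 - 1)),
        leaf_only=True,
        min_regraft_distance=min_regraft_distance,
    )
    seqs = evolve_sequences(gene, L, seed=int(rng.integers(2**31 - 1)))
    return species, gene, log, seqs


# ---------------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------------

def write_fixtures(
    genomes: list[GenomeAnnotation],
    truth: SimulationTruth,
    out_dir: str | Path,
) -> None:
    """Emit the annotation TSVs, protein FASTAs, Newick trees and the
    truth.json the pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for genome in genomes:
        write_annotation_table(genome, out / f"{genome.genome_id}.tsv")
        write_fasta(
            [g.protein for g in genome.genes], out / f"{genome.genome_id}.faa"
        )
    if truth.species_tree is not None:
        (out / "species_tree.nwk").write_text(
            write_newick(truth.species_tree) + "\n"
        )
    for role, gt in truth.gene_trees.items():
        (out / f"gene_tree_{role}.nwk").write_text(write_newick(gt) + "\n")
    (out / "truth.json").write_text(truth.to_json() + "\n")
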