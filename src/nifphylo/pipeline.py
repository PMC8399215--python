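"""End-to-end orchestration: screen -> align -> concatenate -> trees ->
consensus/supertree -> cluster assignment -> HGT report.

Only genomes with a complete six-gene complement proceed past screening.
Every artifact carries the configuration hash in its header where the
format permits comments; a rerun with an identical configuration produces a
byte-identical bundle (stage wall times go to stderr, not into the bundle).
"""

from __future__ import annotations

import hashlib
import shutil
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .align_concat import (
    Alignment,
    ConcatenatedAlignment,
    ScoringScheme,
    concatenate,
    progressive_align,
)
from .complement_screen import (
    ComplementTable,
    RoleSet,
    ScreenParams,
    screen_genomes,
)
from .distance_tree import (
    DistanceMatrix,
    DistanceParams,
    distance_matrix,
    neighbor_joining,
)
from .io_formats import (
    GenomeAnnotation,
    SequenceRecord,
    fasta_string,
    write_newick,
    write_partitions,
)
from .tree import PhyloTree
from .tree_compare import (
    ClusterReference,
    HGTReport,
    assign_cluster,
    hgt_candidates,
    majority_consensus,
    quartet_supertree,
)


@dataclass
class RunConfig:
    """Inputs and parameters for one pipeline run."""

    genomes: list[GenomeAnnotation]
    roles: RoleSet = field(default_factory=RoleSet)
    screen_params: ScreenParams = field(default_factory=ScreenParams)
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    dist_params: DistanceParams = field(default_factory=DistanceParams)
    distance_model: str = "kimura"
    exact_max_n: int = 8
    max_removals: int = 5
    seed: int = 0
    species_tree: PhyloTree | None = None
    cluster_refs: ClusterReference | None = None
    imported_trees: list[PhyloTree] = field(default_factory=list)
    imported_alignments: dict[str, Alignment] = field(default_factory=dict)
    out_dir: Path | None = None

    def config_hash(self) -> str:
        parts = [
            ",".join(sorted(g.genome_id for g in self.genomes)),
            ",".join(self.roles.roles),
            repr(
                (
                    self.screen_params.window_max_bp,
                    self.screen_params.fusion_length_fraction,
                    self.screen_params.combination_cap,
                    self.screen_params.require_same_contig,
                    self.scoring.gap_open,
                    self.scoring.gap_extend,
                    self.dist_params.d_max,
                    self.dist_params.min_overlap,
                    self.distance_model,
                    self.exact_max_n,
                    self.max_removals,
                    self.seed,
                )
            ),
            write_newick(self.species_tree) if self.species_tree else "",
        ]
        return hashlib.sha256("|".join(parts).encode()).hexdigest()[:12]


@dataclass
class RunResult:
    """Artifacts of one run (also materialized on disk when out_dir set)."""

    config_hash: str
    complements: ComplementTable
    alignments: dict[str, Alignment] = field(default_factory=dict)
    concat: ConcatenatedAlignment | None = None
    distances: DistanceMatrix | None = None
    concat_tree: PhyloTree | None = None
    consensus_tree: PhyloTree | None = None
    gene_trees: dict[str, PhyloTree] = field(default_factory=dict)
    supertree: PhyloTree | None = None
    supertree_score: int = 0
    assignments: pd.DataFrame | None = None
    hgt_report: HGTReport | None = None
    log: list[str] = field(default_factory=list)
    output_dir: Path | None = None


def _role_sequences(table: ComplementTable, roles: RoleSet) -> dict[str, list[SequenceRecord]]:
    """Per-role protein sets over complete genomes; a fused record
    contributes its full sequence to both of its roles."""
    out: dict[str, list[SequenceRecord]] = {r: [] for r in roles.roles}
    for comp in sorted(table.rows, key=lambda c: c.genome_id):
        if not comp.complete:
            continue
        for role in roles.roles:
            rec = comp.chosen[role]
            out[role].append(
                SequenceRecord(id=comp.genome_id, sequence=rec.protein.sequence)
            )
    return out


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_full_analysis(cfg: RunConfig) -> RunResult:
    """Run every stage in order; see the module docstring for the contract.

    A failing stage raises :class:`PipelineStageError` naming the stage;
    artifacts produced by the stages that did complete are retained under a
    ``.partial``-suffixed bundle directory when an output directory is set.
    """
    chash = cfg.config_hash()
    result = RunResult(config_hash=chash, complements=None)  # type: ignore[arg-type]
    try:
        _run_stages(cfg, result)
    except Exception as exc:
        current = result.log[-1].split()[0].split("=")[1] if result.log else ""
        failed = f"after:{current}" if current else "screen"
        if cfg.out_dir is not None and result.complements is not None:
            partial = _write_bundle(cfg, result)
            target = partial.with_name(partial.name + ".partial")
            if target.exists():
                shutil.rmtree(target)
            partial.rename(target)
        raise PipelineStageError(failed, exc) from exc
    if cfg.out_dir is not None:
        result.output_dir = _write_bundle(cfg, result)
    return result


def _run_stages(cfg: RunConfig, result: RunResult) -> None:
    t0 = time.perf_counter()
    log = result.log

    def stage(name: str, n_in: int, n_out: int) -> None:
        log.append(f"stage={name} n_in={n_in} n_out={n_out}")
        print(
            f"[nifphylo] {name}: {n_in} -> {n_out} "
            f"({time.perf_counter() - t0:.1f}s elapsed)",
            file=sys.stderr,
        )

    table = screen_genomes(cfg.genomes, cfg.roles, cfg.screen_params)
    result.complements = table
    complete = [c for c in table.rows if c.complete]
    stage("screen", len(cfg.genomes), len(complete))

    if len(complete) >= 2:
        role_seqs = _role_sequences(table, cfg.roles)
        for role in cfg.roles.roles:
            if role in cfg.imported_alignments:
                result.alignments[role] = cfg.imported_alignments[role]
            else:
                result.alignments[role] = progressive_align(
                    role_seqs[role], scheme=cfg.scoring, role=role
                )
        stage("align", len(complete), len(result.alignments))

        result.concat = concatenate(
            [result.alignments[r] for r in cfg.roles.roles]
        )
        stage("concatenate", len(result.alignments), result.concat.length)

        result.distances = distance_matrix(
            result.concat, cfg.dist_params, model=cfg.distance_model
        )
        result.concat_tree = neighbor_joining(result.distances)
        stage("concat_tree", len(result.distances.taxa), 1)

        concat_trees = [result.concat_tree] + list(cfg.imported_trees)
        result.consensus_tree = majority_consensus(concat_trees)
        stage("consensus", len(concat_trees), 1)

        for role in cfg.roles.roles:
            dm = distance_matrix(
                result.alignments[role], cfg.dist_params, model=cfg.distance_model
            )
            result.gene_trees[role] = neighbor_joining(dm)
        result.supertree, result.supertree_score = quartet_supertree(
            list(result.gene_trees.values()),
            exact_max_n=cfg.exact_max_n,
            seed=cfg.seed,
        )
        stage("supertree", len(result.gene_trees), result.supertree_score)

        if cfg.cluster_refs is not None:
            rows = []
            for taxon in result.distances.taxa:
                if taxon in cfg.cluster_refs.labels:
                    continue
                cluster, ref, dist = assign_cluster(
                    taxon, result.distances, cfg.cluster_refs
                )
                rows.append(
                    {"genome_id": taxon, "cluster": cluster,
                     "nearest_reference": ref, "distance": round(dist, 6)}
                )
            result.assignments = pd.DataFrame(rows)
            stage("classify", len(result.distances.taxa), len(rows))

        if cfg.species_tree is not None:
            result.hgt_report = hgt_candidates(
                result.concat_tree, cfg.species_tree, cfg.max_removals
            )
            stage("hgt", len(result.concat_tree.leaf_labels()),
                  len(result.hgt_report.candidates))


def _write_bundle(cfg: RunConfig, result: RunResult) -> Path:
    out = Path(cfg.out_dir) / f"run-{result.config_hash}"
    out.mkdir(parents=True, exist_ok=True)
    header = f"# nifphylo config_hash={result.config_hash} seed={cfg.seed}\n"
    (out / "complements.tsv").write_text(header + result.complements.to_tsv())
    if result.concat is not None:
        aln_dir = out / "aln"
        aln_dir.mkdir(exist_ok=True)
        for role, aln in result.alignments.items():
            records = [SequenceRecord(id=g, sequence=s) for g, s in aln.rows.items()]
            (aln_dir / f"{role}.fasta").write_text(fasta_string(records))
        records = [
            SequenceRecord(id=g, sequence=s) for g, s in result.concat.rows.items()
        ]
        (out / "concat.fasta").write_text(fasta_string(records))
        (out / "concat.partitions").write_text(
            write_partitions(result.concat.partitions) + "\n"
        )
        (out / "distances.tsv").write_text(header + result.distances.to_tsv())
        (out / "concat_nj.nwk").write_text(write_newick(result.concat_tree) + "\n")
        (out / "consensus.nwk").write_text(write_newick(result.consensus_tree) + "\n")
        gt_dir = out / "gene_trees"
        gt_dir.mkdir(exist_ok=True)
        for role, gt in result.gene_trees.items():
            (gt_dir / f"{role}.nwk").write_text(write_newick(gt) + "\n")
        (out / "supertree.nwk").write_text(write_newick(result.supertree) + "\n")
    if result.assignments is not None:
        (out / "assignments.tsv").write_text(
            header + result.assignments.to_csv(sep="\t", index=False)
        )
    if result.hgt_report is not None:
        (out / "hgt.tsv").write_text(header + result.hgt_report.to_tsv())
    (out / "run.log").write_text(header + "\n".join(result.log) + "\n")
    return out
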