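"""Minimal nitrogenase gene-set screening.

Decides per genome whether a complete one-copy-per-role NifHDKENB complement
exists.  Multi-copy genes are resolved by genomic co-location: the chosen set
minimizes the genomic window span, automating the usual manual "same
neighborhood" judgement.  Fused EN and NB open reading frames are recognized
by sequence length (a fused record must reach a configurable fraction of the
summed single-role reference lengths) and fill both of their roles.

The same machinery screens alternative nitrogenase systems (AnfHDK, VnfHDK)
by supplying a different :class:`RoleSet`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import pandas as pd

from .io_formats import GeneRecord, GenomeAnnotation

#: Default per-role reference median protein lengths (aa) for Mo-nitrogenase.
DEFAULT_ROLE_LENGTHS = {"H": 290, "D": 490, "K": 520, "E": 460, "N": 430, "B": 470}

DEFAULT_SYNONYMS = {
    "H": ("nifH",),
    "D": ("nifD",),
    "K": ("nifK",),
    "E": ("nifE", "nifEN"),
    "N": ("nifN", "nifEN", "nifNB"),
    "B": ("nifB", "nifNB"),
}

#: Adjacent role pairs that occur as natural gene fusions.
FUSABLE_PAIRS = (("E", "N"), ("N", "B"))


class FusionAmbiguityError(ValueError):
    """A record satisfies the fusion length rule for both EN and NB."""


@dataclass(frozen=True)
class RoleSet:
    """Ordered role names with symbol synonyms and reference lengths."""

    roles: tuple[str, ...] = ("H", "D", "K", "E", "N", "B")
    synonyms: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SYNONYMS)
    )
    reference_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_ROLE_LENGTHS)
    )

    def __post_init__(self):
        if len(set(self.roles)) != len(self.roles):
            raise ValueError("duplicate roles")
        for role in self.roles:
            if self.reference_lengths.get(role, 1) <= 0:
                raise ValueError(f"reference length for {role} must be > 0")

    def role_of_symbol(self, symbol: str) -> list[str]:
        sym = symbol.lower()
        return [
            role
            for role in self.roles
            if sym in (s.lower() for s in self.synonyms.get(role, ()))
        ]

    def fusable_pairs(self) -> tuple[tuple[str, str], ...]:
        return tuple(
            (x, y) for x, y in FUSABLE_PAIRS if x in self.roles and y in self.roles
        )


@dataclass(frozen=True)
class ScreenParams:
    """Neighborhood window, fusion length fraction, and search caps."""

    window_max_bp: int = 25_000
    fusion_length_fraction: float = 0.7
    combination_cap: int = 100_000
    require_same_contig: bool = True

    def __post_init__(self):
        if self.window_max_bp <= 0 or self.combination_cap < 1:
            raise ValueError("window_max_bp > 0 and combination_cap >= 1 required")
        if not (0 < self.fusion_length_fraction <= 1):
            raise ValueError("fusion_length_fraction must be in (0, 1]")


@dataclass(frozen=True)
class FusionCall:
    record: GeneRecord
    pair: str  # "EN" or "NB"

    @property
    def roles(self) -> tuple[str, str]:
        return (self.pair[0], self.pair[1])


@dataclass
class NifComplement:
    """Resolution result for one genome."""

    genome_id: str
    status: str  # complete | incomplete | ambiguous
    chosen: dict[str, GeneRecord] = field(default_factory=dict)
    fusion_flags: frozenset = frozenset()
    missing_roles: tuple[str, ...] = ()
    span_bp: int = 0
    reason: str = ""
    resolution: str = "exhaustive"  # or "greedy"

    @property
    def complete(self) -> bool:
        return self.status == "complete"


# ---------------------------------------------------------------------------
# Role hits and fusions
# ---------------------------------------------------------------------------

def find_role_hits(
    genome: GenomeAnnotation, roles: RoleSet
) -> dict[str, list[GeneRecord]]:
    """All annotated candidates per role, case-insensitive symbol match,
    sorted by (contig, start)."""
    hits: dict[str, list[GeneRecord]] = {role: [] for role in roles.roles}
    for gene in genome.genes:
        for role in roles.role_of_symbol(gene.symbol):
            hits[role].append(gene)
    for role in hits:
        hits[role].sort(key=lambda g: (g.contig, g.start, g.protein_id))
    return hits


def _gap_bp(a: GeneRecord, b: GeneRecord) -> float:
    """Genomic gap between two records; inf across contigs."""
    if a.contig != b.contig:
        return float("inf")
    if a.end < b.start:
        return b.start - a.end
    if b.end < a.start:
        return a.start - b.end
    return 0.0


def detect_fusions(
    hits: dict[str, list[GeneRecord]],
    roles: RoleSet,
    params: ScreenParams,
) -> list[FusionCall]:
    """Call fused EN / NB records by the length rule.

    A record is fused for adjacent pair (X, Y) iff it is annotated to X or Y
    (or a combined symbol), its length reaches ``fusion_length_fraction`` of
    the summed reference lengths, and no separate partner-role hit lies
    within the neighborhood window.
    """
    calls: list[FusionCall] = []
    by_record: dict[str, set[str]] = {}
    for x, y in roles.fusable_pairs():
        pair_name = x + y
        need = params.fusion_length_fraction * (
            roles.reference_lengths[x] + roles.reference_lengths[y]
        )
        candidates: dict[str, GeneRecord] = {}
        for rec in hits.get(x, []) + hits.get(y, []):
            candidates.setdefault(rec.protein_id, rec)
        for rec in candidates.values():
            if rec.aa_length < need:
                continue
            partner_ok = True
            for role in (x, y):
                for other in hits.get(role, []):
                    if other.protein_id == rec.protein_id:
                        continue
                    if _gap_bp(rec, other) <= params.window_max_bp:
                        partner_ok = False
                        break
                if not partner_ok:
                    break
            if partner_ok:
                calls.append(FusionCall(record=rec, pair=pair_name))
                by_record.setdefault(rec.protein_id, set()).add(pair_name)
    ambiguous = sorted(pid for pid, pairs in by_record.items() if len(pairs) > 1)
    if ambiguous:
        raise FusionAmbiguityError(
            f"record(s) satisfy the fusion length rule for both EN and NB: {ambiguous}"
        )
    return calls


def _substitute_fusions(
    hits: dict[str, list[GeneRecord]], fusions: list[FusionCall]
) -> dict[str, list[GeneRecord]]:
    """Ensure each fused record appears as a candidate for both of its roles."""
    out = {role: list(records) for role, records in hits.items()}
    for call in fusions:
        for role in call.roles:
            if all(r.protein_id != call.record.protein_id for r in out.get(role, [])):
                out.setdefault(role, []).append(call.record)
    for role in out:
        out[role].sort(key=lambda g: (g.contig, g.start, g.protein_id))
    return out


# ---------------------------------------------------------------------------
# Complement resolution
# ---------------------------------------------------------------------------

def _combo_span(records: list[GeneRecord], same_contig: bool) -> float:
    """Window span of a chosen record set; inf if it violates the contig rule."""
    contigs = {r.contig for r in records}
    if same_contig:
        if len(contigs) > 1:
            return float("inf")
        return max(r.end for r in records) - min(r.start for r in records)
    span = 0.0
    for contig in contigs:
        sub = [r for r in records if r.contig == contig]
        span += max(r.end for r in sub) - min(r.start for r in sub)
    return span


def _combo_valid(combo: dict[str, GeneRecord], fusions: list[FusionCall]) -> bool:
    """A fused record chosen for one of its pair roles must fill both."""
    for call in fusions:
        x, y = call.roles
        pid = call.record.protein_id
        in_x = combo.get(x) is not None and combo[x].protein_id == pid
        in_y = combo.get(y) is not None and combo[y].protein_id == pid
        if in_x != in_y:
            return False
    return True


def _tie_vector(combo: dict[str, GeneRecord], roles: RoleSet) -> tuple:
    return tuple((combo[r].contig, combo[r].start) for r in roles.roles)


def resolve_complement(
    genome: GenomeAnnotation,
    hits: dict[str, list[GeneRecord]],
    fusions: list[FusionCall],
    params: ScreenParams,
    roles: RoleSet | None = None,
) -> NifComplement:
    """Choose one record per role minimizing the genomic window span.

    Exhaustive over all per-role combinations up to ``combination_cap``;
    beyond the cap a greedy anchor-based fallback is used (anchor = medoid of
    the single-copy roles, nearest copy chosen for each multi-copy role).
    """
    roles = roles or RoleSet()
    eff = _substitute_fusions(hits, fusions)
    missing = tuple(r for r in roles.roles if not eff.get(r))
    if missing:
        return NifComplement(
            genome_id=genome.genome_id,
            status="incomplete",
            missing_roles=missing,
            reason="missing_roles",
        )

    counts = 1
    for r in roles.roles:
        counts *= len(eff[r])

    best: dict[str, GeneRecord] | None = None
    best_span = float("inf")
    resolution = "exhaustive"

    if counts <= params.combination_cap:
        for picks in itertools.product(*(eff[r] for r in roles.roles)):
            combo = dict(zip(roles.roles, picks))
            if not _combo_valid(combo, fusions):
                continue
            distinct = {p.protein_id: p for p in picks}
            span = _combo_span(list(distinct.values()), params.require_same_contig)
            if span == float("inf"):
                continue
            if span < best_span or (
                span == best_span
                and best is not None
                and _tie_vector(combo, roles) < _tie_vector(best, roles)
            ):
                best, best_span = combo, span
    else:
        resolution = "greedy"
        best, best_span = _greedy_resolve(eff, fusions, params, roles)

    if best is None:
        return NifComplement(
            genome_id=genome.genome_id,
            status="incomplete",
            missing_roles=(),
            reason="cross_contig",
            resolution=resolution,
        )
    flags = frozenset(
        call.pair
        for call in fusions
        if best[call.roles[0]].protein_id == call.record.protein_id
    )
    return NifComplement(
        genome_id=genome.genome_id,
        status="complete",
        chosen=best,
        fusion_flags=flags,
        span_bp=int(best_span),
        resolution=resolution,
    )


def _greedy_resolve(
    eff: dict[str, list[GeneRecord]],
    fusions: list[FusionCall],
    params: ScreenParams,
    roles: RoleSet,
) -> tuple[dict[str, GeneRecord] | None, float]:
    single = [eff[r][0] for r in roles.roles if len(eff[r]) == 1]

    def greedy_from(anchor: GeneRecord):
        combo: dict[str, GeneRecord] = {}
        for r in roles.roles:
            options = [g for g in eff[r] if g.contig == anchor.contig]
            if not options:
                if params.require_same_contig:
                    return None, float("inf")
                options = eff[r]
            combo[r] = min(
                options, key=lambda g: (abs(g.midpoint - anchor.midpoint), g.start)
            )
        if not _combo_valid(combo, fusions):
            return None, float("inf")
        distinct = {p.protein_id: p for p in combo.values()}
        return combo, _combo_span(list(distinct.values()), params.require_same_contig)

    if single:
        # medoid of the single-copy roles: minimizes summed distance to the rest
        anchor = min(
            single,
            key=lambda g: (
                sum(abs(g.midpoint - h.midpoint) for h in single if h.contig == g.contig)
                + sum(1e12 for h in single if h.contig != g.contig),
                g.contig,
                g.start,
            ),
        )
        return greedy_from(anchor)
    # no single-copy role: anchor on each candidate of the first role
    best, best_span = None, float("inf")
    for anchor in eff[roles.roles[0]]:
        combo, span = greedy_from(anchor)
        if combo is not None and span < best_span:
            best, best_span = combo, span
    return best, best_span


# ---------------------------------------------------------------------------
# Batch screening
# ---------------------------------------------------------------------------

@dataclass
class ComplementTable:
    """Per-genome complement calls plus per-phylum / per-genus summaries."""

    rows: list[NifComplement]
    summary_phylum: pd.Series
    summary_genus: pd.Series
    roles: RoleSet = field(default_factory=RoleSet)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for c in sorted(self.rows, key=lambda r: r.genome_id):
            rec = {
                "genome_id": c.genome_id,
                "status": c.status,
                "missing_roles": ",".join(c.missing_roles),
                "fusion_flags": ",".join(sorted(c.fusion_flags)),
                "span_bp": c.span_bp,
            }
            for role in self.roles.roles:
                rec[f"protein_{role}"] = (
                    c.chosen[role].protein_id if role in c.chosen else ""
                )
            recs.append(rec)
        return pd.DataFrame(recs)

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index=False)


def screen_genome(
    genome: GenomeAnnotation,
    roles: RoleSet | None = None,
    params: ScreenParams | None = None,
) -> NifComplement:
    roles = roles or RoleSet()
    params = params or ScreenParams()
    hits = find_role_hits(genome, roles)
    try:
        fusions = detect_fusions(hits, roles, params)
    except FusionAmbiguityError as exc:
        return NifComplement(
            genome_id=genome.genome_id, status="ambiguous", reason=str(exc)
        )
    return resolve_complement(genome, hits, fusions, params, roles)


def screen_genomes(
    genomes: list[GenomeAnnotation],
    roles: RoleSet | None = None,
    params: ScreenParams | None = None,
) -> ComplementTable:
    """Screen a genome batch; deterministic row order by genome_id."""
    roles = roles or RoleSet()
    params = params or ScreenParams()
    ids = [g.genome_id for g in genomes]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate genome_id(s): {dupes}")
    rows = [
        screen_genome(g, roles, params)
        for g in sorted(genomes, key=lambda g: g.genome_id)
    ]
    complete = {r.genome_id for r in rows if r.complete}
    by_id = {g.genome_id: g for g in genomes}
    phyla = pd.Series(
        [by_id[i].taxon.get("phylum", "unknown") for i in sorted(complete)],
        dtype="object",
    )
    genera = pd.Series(
        [by_id[i].taxon.get("genus", "unknown") for i in sorted(complete)],
        dtype="object",
    )
    return ComplementTable(
        rows=rows,
        summary_phylum=phyla.value_counts().sort_index(),
        summary_genus=genera.value_counts().sort_index(),
        roles=roles,
    )
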