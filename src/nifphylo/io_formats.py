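"""Readers and writers for every external format the pipeline touches.

FASTA (via Biopython, 60-column wrap on output), plain-TSV and GFF3-subset
gene annotation tables, Newick trees (see :mod:`nifphylo.tree`), and
RAxML-style partition files.  Coordinates are 1-based inclusive at the I/O
boundary (GFF3 convention) and converted to 0-based half-open only inside
algorithms.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .tree import PhyloTree, parse_newick, write_newick  # noqa: F401  (re-export)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS + "X-")

PathLike = Union[str, Path]


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence: id (no whitespace), free-text description,
    amino-acid string over the 20 canonical residues plus X and gap."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid record id: {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneRecord:
    """A gene call on a contig; 1-based inclusive coordinates."""

    symbol: str
    contig: str
    start: int
    end: int
    strand: str
    protein_id: str
    protein: SequenceRecord

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(
                f"gene {self.protein_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.protein_id}: bad strand {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    @property
    def aa_length(self) -> int:
        return len(self.protein.sequence.replace("-", ""))


@dataclass
class GenomeAnnotation:
    """One genome's gene records plus taxon labels (at least genus, phylum)."""

    genome_id: str
    genes: list[GeneRecord] = field(default_factory=list)
    taxon: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        ids = [g.protein_id for g in self.genes]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(
                f"genome {self.genome_id}: duplicate protein_id(s): {dupes}"
            )


@dataclass
class PartitionMap:
    """Ordered (role, start, end) column intervals, 0-based half-open,
    contiguous and covering [0, total_length)."""

    entries: list[tuple[str, int, int]]

    def __post_init__(self):
        expected = 0
        for name, start, end in self.entries:
            if start != expected or end <= start:
                raise ValueError(
                    f"partition {name}: interval [{start},{end}) not contiguous"
                )
            expected = end

    @property
    def total_length(self) -> int:
        return self.entries[-1][2] if self.entries else 0

    def slice(self, row: str, role: str) -> str:
        for name, start, end in self.entries:
            if name == role:
                return row[start:end]
        raise KeyError(role)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _validate_sequence(rec_id: str, seq: str, allow_gaps: bool) -> None:
    allowed = ALPHABET if allow_gaps else ALPHABET - {"-"}
    for ch in seq:
        if ch not in allowed:
            raise ValueError(
                f"record {rec_id!r}: invalid sequence character {ch!r}"
            )


def read_fasta(path: PathLike, allow_gaps: bool = True) -> list[SequenceRecord]:
    """Read a protein FASTA file; sequences are upper-cased and validated
    against the amino-acid alphabet (plus X and, optionally, gaps)."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio in SeqIO.parse(str(path), "fasta"):
        seq = str(bio.seq).upper()
        _validate_sequence(bio.id, seq, allow_gaps)
        if bio.id in seen:
            raise ValueError(f"duplicate record id {bio.id!r} in {path}")
        seen.add(bio.id)
        desc = bio.description[len(bio.id):].strip() if bio.description else ""
        records.append(SequenceRecord(id=bio.id, sequence=seq, description=desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: PathLike) -> None:
    """Write records wrapped at 60 columns."""
    bio_records = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(bio_records, handle, "fasta")


def fasta_string(records: Iterable[SequenceRecord]) -> str:
    buf = io.StringIO()
    bio_records = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio_records, buf, "fasta")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

def _protein_index(proteins: Iterable[SequenceRecord]) -> dict[str, SequenceRecord]:
    return {p.id: p for p in proteins}


def read_annotation_table(
    path: PathLike,
    proteins: Union[PathLike, Iterable[SequenceRecord]],
    dialect: str = "tsv",
    genome_id: str | None = None,
    taxon: dict[str, str] | None = None,
) -> GenomeAnnotation:
    """Read a gene-annotation table (``tsv`` or ``gff3`` dialect) plus the
    companion protein FASTA that supplies sequences keyed by protein_id.

    TSV columns: gene symbol, contig, start, end, strand, protein_id
    (1-based inclusive coordinates, preserved bit-exactly).
    """
    if isinstance(proteins, (str, Path)):
        proteins = read_fasta(proteins, allow_gaps=False)
    index = _protein_index(proteins)
    if genome_id is None:
        genome_id = Path(path).stem

    rows: list[tuple[str, str, int, int, str, str]] = []
    text = Path(path).read_text()
    if dialect == "tsv":
        for lineno, line in enumerate(text.splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            symbol, contig, start, end, strand, pid = parts
            rows.append((symbol, contig, int(start), int(end), strand, pid))
    elif dialect == "gff3":
        for lineno, line in enumerate(text.splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype not in ("CDS", "gene"):
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            symbol = attr.get("gene")
            pid = attr.get("protein_id")
            if symbol is None or pid is None:
                continue
            rows.append((symbol, seqid, int(start), int(end), strand, pid))
    else:
        raise ValueError(f"unknown annotation dialect: {dialect!r}")

    missing = sorted({pid for *_, pid in rows} - set(index))
    if missing:
        raise ValueError(
            f"genome {genome_id}: protein_id(s) missing from FASTA: {missing}"
        )
    genes = [
        GeneRecord(symbol=s, contig=c, start=a, end=b, strand=st,
                   protein_id=pid, protein=index[pid])
        for (s, c, a, b, st, pid) in rows
    ]
    return GenomeAnnotation(genome_id=genome_id, genes=genes, taxon=taxon or {})


def write_annotation_table(genome: GenomeAnnotation, path: PathLike) -> None:
    """Write the 6-column TSV annotation dialect."""
    lines = [
        "\t".join([g.symbol, g.contig, str(g.start), str(g.end), g.strand, g.protein_id])
        for g in genome.genes
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Partition files
# ---------------------------------------------------------------------------

def write_partitions(pm: PartitionMap) -> str:
    """RAxML-style partition lines, 1-based inclusive on output."""
    return "\n".join(
        f"PROT, {name} = {start + 1}-{end}" for name, start, end in pm.entries
    )


def read_newick_file(path: PathLike) -> PhyloTree:
    return parse_newick(Path(path).read_text())


def write_newick_file(tree: PhyloTree, path: PathLike, precision: int = 6) -> None:
    Path(path).write_text(write_newick(tree, precision) + "\n")
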