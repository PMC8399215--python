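import numpy as np
import pytest

from nifphylo.io_formats import GeneRecord, GenomeAnnotation, SequenceRecord
from nifphylo.synthetic_data import random_protein


def make_gene(symbol, start, aa_len=300, contig="ctg1", pid=None, seq=None,
              rng=None):
    pid = pid or f"{symbol}_{start}"
    if seq is None:
        rng = rng or np.random.default_rng(abs(hash((symbol, start))) % 2**31)
        seq = random_protein(rng, aa_len)
    return GeneRecord(
        symbol=symbol, contig=contig, start=start, end=start + 3 * aa_len - 1,
        strand="+", protein_id=pid,
        protein=SequenceRecord(id=pid, sequence=seq),
    )


@pytest.fixture
def operon_genome():
    """One genome with a clean single-copy six-gene operon in ~9.5 kb."""
    lengths = {"nifH": 290, "nifD": 490, "nifK": 520,
               "nifE": 460, "nifN": 430, "nifB": 470}
    genes = []
    pos = 1000
    for symbol, aa in lengths.items():
        genes.append(make_gene(symbol, pos, aa))
        pos += 3 * aa + 120
    return GenomeAnnotation(genome_id="gA", genes=genes,
                            taxon={"phylum": "Proteobacteria", "genus": "Azotobacter"})
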