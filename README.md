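# nifphylo

Desk-scale screening and phylogenetics of biological nitrogen fixation.

Diazotrophy — the ability to reduce N₂ to ammonia — is carried by the
molybdenum nitrogenase system, and its minimal genetic signature is the
six-gene complement *nifHDKENB*: the structural subunits (NifH, the
dinitrogenase reductase; NifD/NifK, the dinitrogenase) plus the FeMo-cofactor
assembly proteins (NifE, NifN, NifB). `nifphylo` implements, as a tested
Python library and CLI, the full in-silico workflow built on that criterion:

1. **Complement screening** — decide per genome whether a complete
   one-copy-per-role NifHDKENB set exists. Multi-copy genes are resolved by
   genomic co-location (the chosen set minimizes the window span
   `max(end) − min(start)`, automating the "same neighborhood" judgement);
   fused *nifEN* / *nifNB* open reading frames are recognized when a record's
   length reaches a fraction *f*<sub>min</sub> (default 0.7) of the summed
   single-role reference lengths, and fill both of their roles. The same
   machinery screens alternative nitrogenases (AnfHDK / VnfHDK) via a custom
   role set.
2. **Alignment and concatenation** — a built-in progressive aligner
   (k-mer-distance UPGMA guide tree, BLOSUM62 mean-of-pairs profile merges,
   affine gaps open 10 / extend 1) aligns each role; per-role alignments are
   concatenated row-matched into a partitioned NifHDKENB supermatrix.
   Externally produced alignments can be imported instead.
3. **Distance trees** — Kimura-corrected protein distances,
   d = −ln(1 − p − 0.2 p²) with pairwise deletion, fed to canonical
   neighbor joining; rooting by outgroup or midpoint.
4. **Tree combination and comparison** — strict-majority consensus;
   quartet-score supertree estimation (the ASTRAL objective: exact
   enumeration for small leaf sets, greedy insertion + NNI hill-climbing
   beyond); Robinson–Foulds distances.
5. **Horizontal-transfer candidates** — greedy RF-reduction leaf pruning
   between the nitrogenase tree and a species (e.g. 16S rRNA) tree: the leaf
   whose removal most reduces the discordance is pruned iteratively; pruned
   leaves, in order, are the HGT candidates. Nearest-reference assignment of
   Raymond nitrogenase clusters (I / II / III and subclusters) from the
   distance matrix.
6. **Synthetic data with ground truth** — Yule species trees, planted SPR
   transfers, sequences evolved under a 20-state Poisson model with the
   closed-form identity P(same) = 1/20 + (19/20)·e^(−20d/19), and genome
   fixtures with planted operons, distal decoy paralogs, fusions and
   incomplete complements. Every planted fact is logged, so the whole
   pipeline is testable against known truth.

Intended users: microbial genomicists and molecular evolution researchers
who want the *nif* screening-and-phylogeny workflow reproducible on their
own annotation tables, and method developers who need a transparent,
oracle-tested reference implementation of its parts.

## Worked example

```bash
# 8 genomes with planted operons and one planted transfer, plus truth.json
nifphylo simulate --genomes 8 --hgt 1 --seed 4 --out-dir fx
mkdir -p ann prot && cp fx/*.tsv ann/ && cp fx/*.faa prot/

nifphylo screen --annotations ann --proteins prot --out comp.tsv
# -> 6/8 genomes complete -> comp.tsv

cat > run.yaml <<EOF
annotations: ann
proteins: prot
species_tree: fx/species_tree.nwk
out_dir: out
seed: 5
EOF
nifphylo run --config run.yaml
# -> bundle written to out/run-a3de242b36d5

nifphylo hgt --gene-tree fx/gene_tree_concat.nwk \
             --species-tree fx/species_tree.nwk --out hgt.tsv
# -> initial RF 2, candidates: g0005
```

`comp.tsv` lists per genome the status (`complete` / `incomplete` with the
missing roles), fusion flags, the window span in bp, and the chosen protein
per role — here the two genomes planted incomplete (`g0001` missing N,
`g0002` missing D and B) are rejected and the rest pass. The run bundle
contains the per-role alignments, the concatenated supermatrix with its
partition file, the NJ tree, consensus, per-role gene trees, the quartet
supertree, and the HGT report. The HGT scan prints `candidates: g0005`:
removing that leaf (the planted transfer) drops the gene-tree/species-tree
Robinson–Foulds distance from 2 to 0.

The same workflow is available as a library:

```python
from nifphylo import RunConfig, run_full_analysis, screen_genomes
from nifphylo.synthetic_data import FixtureParams, generate_genome_fixtures

genomes, truth = generate_genome_fixtures(FixtureParams(n_genomes=20), seed=0)
result = run_full_analysis(RunConfig(genomes=genomes))
print(result.complements.to_tsv())
```

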