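# Methods

This note documents the models, algorithms, parameter defaults and design
choices behind `nifphylo`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Complement screening

A genome is called a candidate diazotroph iff it carries all six roles
H, D, K, E, N, B of the molybdenum nitrogenase system (structural subunits
plus FeMo-co assembly). Role matching is symbol-based and case-insensitive,
with configurable synonyms per role (`RoleSet`); the fused symbols `nifEN`
and `nifNB` map to both of their roles. Screening alternative systems
(AnfHDK, VnfHDK) is a configuration change, not new code — these systems
often lack their own ENB genes, so the default six-role criterion applies
to Mo-nitrogenase only.

**Paralog resolution.** When a role has several annotated copies, the chosen
complement is the one-record-per-role set minimizing the genomic window span
`max(end) − min(start)`, restricted to a single contig by default. This is
the simplest auditable formalization of "the copy co-located with the rest
of the operon"; alternatives (sum of pairwise distances, density criteria)
rank the same sets in all planted scenarios and are harder to explain.
Enumeration is exhaustive up to `combination_cap` (default 100,000)
combinations; beyond that a greedy fallback anchors on the medoid of the
single-copy roles and picks the nearest copy per multi-copy role. The greedy
span is never smaller than the exhaustive optimum and equals it whenever the
genome has a unique in-window cluster (asserted by tests). Ties are broken
by the lexicographically smallest (contig, start) vector — determinism over
optimality of tie choice.

**Fusion detection.** A record is called a fused EN (or NB) iff (a) it is
annotated to one of the pair's roles or to a combined symbol, (b) its length
is at least `fusion_length_fraction` (default 0.7) of the summed per-role
reference lengths, and (c) no separate partner-role hit lies within the
neighborhood window. The 0.7 default tolerates terminal truncation while
excluding single-domain records; reference lengths default to typical
Mo-nitrogenase protein sizes (H 290, D 490, K 520, E 460, N 430, B 470 aa)
and are configurable. A record passing the length rule for both EN and NB
with no disambiguating neighbor is reported as `ambiguous` rather than
silently resolved.

**Window.** `window_max_bp` defaults to 25 kb: comfortably larger than known
*nif* operons, far smaller than the distances at which decoy paralogs occur.
The "same genomic neighborhood" judgement is inherently a threshold choice;
it is exposed as a flag and recorded in every output.

## Progressive alignment

Per-role protein sets are aligned with the classic progressive
architecture: a UPGMA guide tree on k-mer distances
d(a,b) = 1 − |shared 3-mers| / min(#3-mers), then post-order
profile–profile merges. Column pairs are scored by mean-of-pairs BLOSUM62
(gap characters score 0); gaps are affine with open 10 and extend 1, the
cited protein defaults of classic progressive aligners. A gap of length L
costs `open + (L−1)·extend` — the opening residue carries the open penalty,
the convention used by Biopython's PairwiseAligner, which the tests use as
an independent score oracle. Terminal gaps are penalized like internal
ones (a deliberate, documented divergence from some aligner dialects;
it keeps the optimum unambiguous on short test sequences). Tie-breaking in
the traceback is fixed: match/mismatch over gap-in-the-first-sequence over
gap-in-the-second.

The affine DP is exact (Gotoh three-state recurrence); rows are vectorized
with a running-maximum transformation for the within-row gap state, so
profile merges of ~500-column alignments cost milliseconds. Fused EN/NB
records contribute their full sequence to **both** role alignments; the
aligner absorbs the unmatched domain as a gap block. Splitting the fusion
would require domain coordinates the annotation does not provide.

Alignments are concatenated in fixed role order H, D, K, E, N, B into a
row-matched supermatrix; the partition map records half-open column
intervals and is exported in RAxML syntax. Only genomes present in every
role alignment (i.e. complete complements) can be concatenated — missing
rows are an error, not silently padded. No trimming or masking is applied.

## Distances and neighbor joining

Observed difference proportions p use pairwise deletion (columns with a gap
or X in either row are skipped); pairs with fewer than `min_overlap`
(default 50) jointly ungapped columns are assigned the saturation cap.
The default correction is Kimura's protein distance

    d = −ln(1 − p − 0.2 p²),

whose argument reaches zero near p ≈ 0.8541; beyond the point where
d would exceed `d_max` (default 10 substitutions/site) the distance
saturates at `d_max` by design. A Poisson-model correction
d = −(19/20)·ln(1 − 20p/19) is also provided; it exactly inverts the
simulation model below and is what the parameter-recovery tests use, while
Kimura remains the user-facing default.

Neighbor joining is the canonical Studier–Keppler formulation: join the
pair minimizing Q(i,j) = (n−2)d(i,j) − R_i − R_j, branch lengths
v_i = d/2 + (R_i − R_j)/(2(n−2)) with negatives clamped to zero (no
redistribution), reduction d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2. Ties take
the lexicographically smallest pair of cluster representative labels.
No acceleration heuristics: at desk scale (tens to a few hundred taxa)
exactness and testability win. NJ is statistically consistent on additive
inputs; the tests exercise this as a hard guarantee for n ≤ 20.
Maximum-likelihood inference is intentionally out of scope; externally
built Newick trees can be imported for the comparison stages instead.

Rooting: by outgroup (the edge separating a monophyletic outgroup; an
incompatible outgroup is an error naming a conflicting bipartition) or by
midpoint of the longest leaf-to-leaf path. Both conserve total branch
length.

## Consensus, supertree, RF

Bipartitions are stored canonically (smaller side; size ties broken
lexicographically), which makes Robinson–Foulds a straight symmetric
difference and serialization deterministic. Normalized RF divides by
2(n−3), the maximum for binary trees.

The strict-majority consensus keeps exactly the splits occurring in > 50%
of input trees (guaranteeing pairwise compatibility), attaches their
occurrence frequency as support, and leaves unresolved regions polytomous.

The supertree stage maximizes the quartet score — the number of 4-leaf
subsets whose induced unrooted topology agrees between candidate and gene
trees, unresolved quartets counting as non-matching (conservative). For
n ≤ `exact_max_n` (default 8) the search enumerates all (2n−5)!! unrooted
binary topologies and is globally optimal, ties resolved to the canonically
smallest Newick; for larger n a greedy seed-shuffled stepwise insertion
followed by NNI hill-climbing yields a local optimum, reported with its
score. This replaces the polynomial dynamic programming of ASTRAL-style
tools with an implementation whose exact mode is directly checkable against
brute force; outside exact mode it is an approximation and documented as
such.

## HGT candidates

Tanglegram-style discordance is made algorithmic: restrict the gene tree
and the species tree to their shared leaves (dropped leaves are reported),
then iteratively remove the leaf whose deletion from both trees maximally
reduces RF (ties alphabetical), stopping at RF 0, after `max_removals`
(default 5, a guard against over-pruning), or when no removal helps. The
removal order ranks candidates by explanatory power; the residual RF says
how much discordance remains unexplained.

One identifiability caveat, demonstrated by the tests: a short-range
(NNI-scale) transfer changes a single bipartition that two different leaf
removals can repair, so *no* method can name the moved leaf from topology
alone. Recall is therefore guaranteed (and tested at 100%) for
distant-clade transfers — the synthetic generator's HGT scenarios place the
regraft at least 4 edges from the pruned position — while short-range
transfers may be reported as the equally parsimonious neighbor.

Raymond cluster assignment (vocabulary I, IA–ID, II, IIA–IIC, III) is
nearest-reference by Kimura distance, ties to the alphabetically first
reference. Reference exemplars are configuration, not hard-coded biology;
tree-placement-based assignment gives the same answer on the synthetic
truth sets and would add a dependency on rooting choices.

## Synthetic data: what it models and what it does not

Species trees are Yule (pure birth), ultrametric, scaled to a stated
root-to-tip height; recovery tests clamp branch lengths into [0.02, 0.3]
substitutions/site — the moderate-rate regime where distances are
informative but unsaturated. Sequences evolve under a 20-state
equal-exchangeability Poisson process: per branch of length d each site
differs from its parent with probability (19/20)(1 − e^(−20d/19)), giving
the closed-form identity P(same) = 1/20 + (19/20)e^(−20d/19) that the
law-of-large-numbers tests check directly. Optional discrete-gamma site
rates are available (off by default). Transfers are planted as SPR moves on
the gene tree, with a rejection step guaranteeing a real topology change
and an optional minimum regraft distance (above).

Genome fixtures plant, on a single contig: a six-gene operon inside a
stated span (default 12 kb), decoy paralogs at a stated distance (default
500 kb), fused EN/NB genomes (one record of exactly summed length), and
incomplete genomes (1–2 roles deleted); counts are exact
(round(fraction·n)) and every planted fact is logged in `SimulationTruth`,
reproducible byte-for-byte from the seed.

Deliberately not modeled: indels (so alignments of evolved sequences are
trivially correct — alignment quality is tested on constructed insertion
cases instead), empirical amino-acid exchange matrices (the Poisson model
buys closed-form oracles; JTT-like matrices would change distances but not
the pipeline logic), annotation errors or truncated genes, pseudogenes, and
genome rearrangement. Perfect screening scores on fixtures therefore
demonstrate the correctness of the decision rules, not robustness to
real-world annotation noise; on real data the symbol synonyms and the
window/fusion thresholds are the knobs that absorb that noise.

## Determinism and numerical choices

Every stochastic component takes an explicit integer seed
(`numpy.random.default_rng`); derived seeds stay below 2³¹. Canonical
Newick (children ordered by smallest leaf label, fixed-precision lengths
with trailing zeros stripped), sorted row/taxon orders, and fixed tie-break
rules make every artifact byte-stable: two runs with the same configuration
produce identical bundles, and the run directory is named by a hash of the
configuration. Stage wall-times are printed to stderr only, so timing never
leaks into the bundle. Problem sizes used by the test-suite and the
acceptance script (20-genome screening bundles, 16-leaf/2,000-site recovery
replicates, n ≤ 7 exhaustive supertree comparisons) were chosen as the
smallest sizes at which the properties under test are non-trivial and
stable across seeds.

## Known limitations

- Symbol-driven role matching: genomes annotated without recognizable gene
  symbols (or only with InterPro/Pfam accessions) need a synonym table.
- NJ only, natively; likelihood-based trees must be imported.
- The greedy supertree beyond `exact_max_n` and the greedy HGT pruning are
  local searches; both report scores so runs are comparable, but neither
  certifies global optimality.
- Cross-contig complements are rejected by default; with the flag disabled
  the span objective sums per-contig spans, which has no single "window"
  interpretation on fragmented assemblies.
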