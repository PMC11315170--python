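# Methods

This note documents the models, algorithms and numerical choices behind
`paraloscope`, and what the synthetic benchmarks do and do not establish.

## Synthetic study conditions

The generator (`paraloscope.synthetic_data`) emulates the conditions of a
family survey across many genomes. Its defaults are the package's study
conditions and are used unchanged by the acceptance checks:

| parameter | default | meaning |
|---|---|---|
| `n_taxa` | 8 | leaves of the species tree |
| `root_genes` | 6 | subfamilies (independent root genes) |
| `dup_rate`, `loss_rate` | 0.2, 0.1 | birth–death rates per lineage per unit tree time |
| `subst_scale` | 0.3 | expected amino-acid substitutions per site per unit tree time |
| `exon_count_range` | 3–6 | exons per subfamily blueprint |
| `protein_length_range` | 150–250 aa | root protein length |
| `intron_length_range` | 60–2000 nt | log-uniform intron lengths |
| `fragmentation` | 2 / 100 kb | expected assembly breakpoints |
| spacer length | 300–900 nt | intergenic filler |

**Species tree.** Pure-birth (Yule) with the height normalised to 1, so all
leaves are contemporaneous and `subst_scale` converts tree time directly
into expected substitutions per site. Under this ultrametric default the
patristic distance from the query taxon to every taxon outside its own root
clade is identical (2 in tree units) — the hardest regime for a
near-to-far search ladder, since first contact with the far clade always
happens at full divergence.

**Gene family.** Each root gene runs a linear birth–death process on every
branch and is copied into both daughters at speciations. With rates λ, μ
and height T, the expected leaf copy number per root gene is e^((λ−μ)T);
the test suite verifies this by Monte-Carlo against 2000 replicates.

**Sequences.** Each subfamily draws one root peptide (background residue
frequencies, leading Met) and one exon–intron blueprint: k−1 cut points in
CDS coordinates (≥45 nt between cuts), whose `position mod 3` fixes the
intron phases. Peptides evolve along the gene tree by per-site Poisson
substitution events; a replacement a→b is drawn with probability ∝
q_b·2^S(a,b) from BLOSUM62, a log-odds-compatible kernel that prefers
chemically similar residues. There is **no indel process**: exon counts and
lengths are conserved exactly within a subfamily, which is the premise the
per-exon search exploits (and a stronger form of the approximate
conservation seen in real families). Leaves are back-translated with
uniform codon choice; introns are `GT + random + 15-nt polypyrimidine tract
+ AG`. The pyrimidine tract mirrors the AG-exclusion zone of real acceptor
sites and keeps chance AG dinucleotides away from the true acceptor.

**Assembly.** Genes are placed on one chromosome per taxon, on both strands,
separated by random spacers; breakpoints are Poisson with the configured
rate and never fall inside an exon (±3 nt). Restricting breaks to
introns/intergenic DNA keeps truth phases and the split-gene merge semantics
(disjoint exon-index ranges) well defined; a mid-exon break would make
"re-merge to the full exon count" undefined rather than merely hard.
Coordinates are 1-based inclusive throughout (GFF3 convention); minus-strand
features are stored in forward-strand coordinates.

**What passing these benchmarks shows — and does not.** The generator gives
divergence that grows with tree distance, conserved exon architecture,
canonical splice sites and assembly fragmentation, with exact truth. It does
not model indels, splice-site turnover, non-canonical introns, GC/repeat
structure, sequencing error, or gene conversion between paralogs; real
surveys face all of these, so the recovery rates measured here are upper
bounds on real-data behaviour, not predictions of it.

## Per-exon profiles

One ungapped position-specific matrix per exon per paralog;
`score(a) = log2((count(a) + τ·q_a) / ((n + τ)·q_a))` bits with pseudocount
τ = 1 and a standard background q (both configurable). Columns with >50 %
gaps are dropped from the matrix but retained in the training alignment.
X scores 0 bits (background expectation); stop codons score −10 bits.
Scoring slides the profile over a peptide and reports the best window;
shorter peptides are charged the minimum column score for uncovered columns.
Ungapped matrices instead of full profile HMMs are a deliberate
simplification: per-exon decomposition makes the units short and (here,
exactly) gap-free, and an ungapped model admits an exact scoring oracle.

**Iterative updating** inserts each accepted exon peptide into its profile's
training alignment at its best-scoring offset and rebuilds the profile,
processing species strictly in patristic order from the query taxon (ties
broken lexicographically). Each genomic exon locus enters the training
alignment at most once.

## Genome search

Contigs are translated in all six frames (stops `*`, N-codons `X`), each
frame is scanned with every profile, and windows ≥ `min_bits` survive
non-maximum suppression per frame.

**Threshold policy.** The library default is `0.6 × profile maximum score`.
The pipeline uses `0.35 ×` the maximum of the *initial, query-only* profile,
frozen for the whole run, for two reasons decided on noise-margin analysis:

1. *Level*: a random-background window scores ≈ −0.8·L bits (L = profile
   columns) with ≈ 1.3·√L standard deviation; even the one-in-a-genome
   extreme-value tail stays below 0.35× the maximum for exon-sized profiles
   (L ≥ 30), while family members at ~50 % identity score ≈ 0.4×. At survey
   divergences sensitivity, not specificity, is the binding constraint.
2. *Freezing*: the threshold guards against genome background, which does
   not change as profiles mature; tying it to the *current* maximum would
   make the absolute bar rise with every update and could push marginal true
   hits back out of the hit set.

For the same reason the search keeps the **baseline hit set** (query-only
profiles) throughout: profile updating may only augment the pool of hits,
never shrink it. The species walk is run for up to two passes (stopping
early when a pass contributes no new training exons), because the first
member of a distant clade is necessarily met with profiles trained only on
nearer species; a revisit with the matured profiles recovers its weakest
exons.

**Splice snapping.** Interior exon boundaries are snapped to AG (acceptor,
upstream) and GT (donor, downstream). The phase-predicted offset is tried
first — intron phases are conserved within a family, and the query supplies
them, so the expected extension of a frame-aligned window is exactly
`(3 − phase) mod 3` on the acceptor side and `phase` on the donor side —
falling back to the nearest signal within a 15-nt radius. Pure
nearest-signal snapping mis-snaps a few percent of boundaries onto chance
dinucleotides; phase prediction removes that failure mode. Outer boundaries
of first/last exons are not snapped; a side whose search would cross the
contig edge is flagged `contig-end`.

**Chaining.** Maximum-total-score chains by DP over hits sorted by exon
index; consecutive members need increasing exon index and, within a contig,
the same strand and a gap within the intron bounds (default 40–20 000 nt, a
deliberately generous envelope). The pipeline adds a weak compactness prior
(`5·10⁻⁴` bits per gap nucleotide, default 0 in the library): with tandem
gene copies, exons of either copy can satisfy the intron bounds, and
near-ties must resolve toward the compact single-copy chain. Reported
scores remain plain sums. Chains are extracted greedily by score; each hit
serves once.

**Context rescue.** Exons missing from an assigned gene are re-sought only
in that gene's gaps and flanks (and, for genes already broken by the
assembly, in contigs hosting no assigned gene) at `0.15 ×` the initial
profile maximum. The search space is a few kilobases, so the local noise
floor is far below the genome-wide one and the weaker threshold is
statistically safe; this is how short, diverged exons (e.g. 20 aa at <50 %
identity, undetectable genome-wide by any sound threshold) are recovered.

## Assignment

Candidates conflict when their **exon intervals** overlap ≥1 nt on the same
contig and strand — exon-level rather than span-level, so complementary
chains through a tandem-copy region do not block each other. Exact mode
solves each connected conflict component by branch-and-bound (provable
optimum; first-found among equal scores in canonical (paralog, locus) order)
with at most `max_copies` loci per paralog per component (default 1; raise
it to hunt extra duplicates); instances above 25 candidates fall back to
greedy when permitted. Feasibility (no conflicts, locus uniqueness, score
consistency) is machine-checked after every solve. Same-paralog loci on
disjoint contig sets whose exon-index sets are disjoint and jointly gapless
are merged into one reported split gene.

The objective — maximum total bit score over conflict-free candidates — is
this package's formalisation of the paralog-to-contig assignment problem.

## Classification

- Length filter: keep strictly greater than 100 nt (nucleotide units by
  default; residue units available, since the filtered objects are proteins
  in practice).
- Progressive alignment: 3-mer distance guide tree (UPGMA), profile–profile
  merges with BLOSUM62 and affine gaps (open −10, extend −0.5, terminal gaps
  penalised); for two sequences this reduces exactly to global pairwise DP,
  which is cross-checked against Biopython's `PairwiseAligner`.
- Distances: p-distance over shared ungapped columns corrected as
  `−ln(1 − p − p²/5)`, clamped to 5.0 for p ≥ 0.85 (or no shared columns).
- Trees: classic neighbor joining (negative branch lengths clamped to 0,
  deficit moved to the sister branch); plain column-resampling bootstrap,
  support = % replicates containing the bipartition. Maximum-likelihood
  inference is out of scope; an externally computed Newick tree can be
  imported with `classification.read_gene_tree`.
- Clade labels: the tree is rooted on a reference leaf edge and each query
  takes the subfamily of the references in its smallest
  reference-containing ancestral clade. Because the reference serving as
  outgroup cannot vote under its own rooting, every reference rooting is
  tried and a label is assigned only when all resolving rootings agree;
  anything else is `unclassified`.
- Deduplication: single-linkage clustering at 0.99 global-alignment
  identity (matches / alignment columns); the longest member represents a
  cluster. Dedup feeds copy-number statistics only — recovery is scored
  before it.

## Evolution summaries

Copy-number matrices per taxon or per genus; a multi-genome genus cell can
be read as the **sum** or the **maximum** over member genomes, and both
modes are provided (sum is the default). Dollo parsimony restricts each
subfamily to a single gain — at the MRCA of its carriers — plus the minimal
set of maximal carrier-free subtrees below it as losses; within-subfamily
duplications are reported as copy counts, not extra gains. Reconstructions
are validated by replay (re-simulating the events reproduces the input
pattern) and, in tests, against exhaustive gain-placement enumeration.

## Motif scan

Ballesteros–Weinstein positions are resolved by global alignment against a
packaged **synthetic** annotated reference receptor (an idealised class-A
GPCR built segment by segment; it is a constructed stand-in, not a database
protein). Anchoring requires ≥30 % identity over ≥100 aligned columns;
otherwise the scan falls back to whole-sequence windows and the report is
flagged. Motif status: `canonical` = exact residue-class match, `variant` =
a named literature form (e.g. S/CWxW) or at most one substitution,
`absent` otherwise (with the best candidate's residues still recorded so
retained positions, like a lone TM6 proline, remain visible). The cysteine
check is presence of ≥1 Cys in each of the TM3 and ECL2 windows; no
disulfide geometry is computed. Signature classes are rule-based on the
report alone: NPR-like (TM6+TM7 intact, cys pair), FRPR-like (TM7 proline
lost, TM6 toggle Trp → H/N/Y, no cys pair), hybrid (canonical TM7 + cys
pair with a proline-only TM6), else indeterminate.

## Pipeline, determinism and problem sizes

Stages run simulate/ingest → profiles → search (iterative, with assignment
inside the species walk) → length filter → gene tree → classification →
dedup → matrices/Dollo → motifs, writing FASTA/GFF3/Newick/TSV/YAML/JSON
artifacts without timestamps, so a config+seed pair reproduces outputs byte
for byte. All randomness derives from one seed via `numpy` seed sequences.

Tests and the acceptance script run the default conditions at 8 taxa × 6
subfamilies (≈ 45–65 genes per replicate, ~25 kb per genome) over 20 and 10
replicate seeds respectively, and the iterative-vs-frozen comparison at 6
taxa × 3 subfamilies with divergence 0.5 — sizes chosen so the whole
battery completes in minutes on one CPU while keeping ≥ 500 planted genes
behind the recovery estimates. Recovery/merge rates are pooled over
replicates.

## Known limitations

- No indel process in the generator, hence no gapped exon scoring need;
  real surveys require profile HMMs with insert/delete states.
- Chimeric chains through *diverged* tandem copies are resolved by the
  compactness prior and exon-level conflicts, but a pathological layout can
  still cherry-pick exons across copies; copy counts, not recovery, would be
  affected.
- Dollo's single-gain assumption conflates repeated independent origins, and
  absence in a genome cannot be distinguished from missing data in
  fragmented assemblies — counts are lower bounds.
- The motif reference is synthetic; anchoring real receptor families should
  use a curated reference alignment through the same interface.
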