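# Methods

This note records the models, conventions and defaults behind each
statistic, the design choices made where the problem was genuinely
open, and what the synthetic benchmarks do and do not demonstrate.

## Alignment and scoring

Protein comparison uses exact local Smith–Waterman through Biopython's
C `PairwiseAligner` with BLOSUM62. Gap costs follow the "existence +
per-residue" convention: a gap of length L costs `gap_open +
L·gap_extend` (defaults 11 and 1), implemented as Biopython
`open_gap_score = -(open+extend)`, `extend_gap_score = -extend`. Bit
scores use the Karlin–Altschul form S′ = (λS − ln K)/ln 2 with the
standard gapped BLOSUM62(11,1) parameters λ = 0.267, K = 0.041, and
E = m·n·2^(−S′) where m and n are the total residue counts of the two
protein sets. Exact (not heuristic-seeded) alignment is deliberate:
inputs are desk-scale (the internal aligner refuses > 5,000 proteins
total; larger comparisons are ingested as precomputed 12-column
tabular hit files). A score-only pass screens all pairs; the full
alignment (identity, coverage, spans) is computed only for pairs
passing the E-value gate. Ambiguous `X` residues score as the BLOSUM62
X column, i.e. effectively as mismatches.

Nucleotide identity (16S and other marker genes) uses global
Needleman–Wunsch with match +1, mismatch −1 and gap cost 5 + 2L.
Columns inside leading/trailing gap runs are excluded from the
identity denominator: gene-boundary calls differ between draft
genomes, and internal divergence is the signal. Internal gap columns
count as differences.

## Ortholog calling (RBH)

Orthologs are reciprocal best hits: (x, y) is a pair iff y is x's best
qualifying a→b hit and x is y's best qualifying b→a hit. Qualifying
means E ≤ 1e-5, coverage of the shorter sequence ≥ 0.7, identity ≥ 0
(all configurable); "best" is max bit score, ties broken by higher
identity, then lexicographically smaller subject id, so the output is
fully deterministic. Because exact local alignment is symmetric in its
arguments, the b→a hit list is the mirrored a→b list when both
directions come from the internal aligner.

A subtlety worth recording: RBH is *not* monotone under hit removal.
Deleting a hit can create a new reciprocal pair (x's best hit falls
away and its second-best happens to point back), so the pair count can
rise. The suite therefore validates RBH against an exhaustive
brute-force enumerator on randomized hit tables rather than asserting
any monotonicity.

## AAI and ortholog fraction

AAI is the unweighted arithmetic mean of per-pair percent identity
over RBH pairs — the simplest reading of "average amino acid
identity" — with an alignment-length-weighted variant behind a flag.
Identity per pair is matches / alignment columns (gap columns
included) of the local alignment. AAI of a pair with zero orthologs is
an explicit error, never 0. The ortholog fraction divides the pair
count by the mean gene count of the two genomes, so identical genomes
score exactly 1.

Local alignment trims noisy termini, which biases measured AAI a few
tenths of a percent above the true site-wise identity at ~80-85%
identity; the synthetic recovery benchmark (below) bounds the total
error at one percentage point.

## Synteny blocks

A block is a maximal run of ortholog pairs whose ordinals strictly
increase in genome A while moving monotonically up ("same") or down
("inverted") in genome B, with at most `gap_tolerance` intervening
genes between consecutive pairs on each genome (default 1), at least
`min_block_size` pairs (default 2), never spanning a contig boundary.
Individual gene strands are ignored — the statistic is about gene
order — and orientation is derived from the B-ordinal direction.
Blocks are grown greedily left-to-right in A-order, always extending
to the candidate with the smallest A-ordinal; a seed that cannot reach
the minimum size is consumed but its partners are released for later
chains. Metrics: Synt/Orth = (Σ block lengths)/|pairs| and mean block
length = (Σ block lengths)/(number of blocks), NaN when there are no
blocks.

At gap tolerance 0 this greedy construction provably equals exhaustive
maximal-run enumeration (verified over all permutations up to 8
genes), and is symmetric under swapping the two genomes. At gap
tolerance ≥ 1 the chains are anchored in A-order and the A↔B swap can
split runs differently near bridged gaps; the defaults favour
determinism and auditability over swap symmetry, and gap 0 is
available when exact symmetry matters.

## Marker completeness

Completeness is the fraction of marker families with at least one
genome protein hitting any of the family's reference sequences at
E ≤ 1e-10 and coverage ≥ 0.7 of the shorter sequence (the same
thresholds as the strictest annotation tier). The marker set is
user-supplied: no curated universal-marker list is bundled, because any
such list is lineage-sensitive; the evolver's `make_marker_test_set`
builds synthetic marker sets with known expected completeness for
testing and demos. Reports carry an explicit note that 100% does not
mean a closed genome — draft assemblies retain inter-contig gaps.

## Annotation tiers

Evidence rows are either domain-database hits (TIGR/Pfam-style:
E-value + protein coverage, optionally flagged as conveying only
general function) or nr-style protein hits (identity + coverage).
Tiers, in precedence order:

- **specific** — a function-specific domain hit with E ≤ 1e-10 and
  coverage > 0.70;
- **putative** — a domain hit with E ≤ 1e-4 and coverage ≥ 0.50, or a
  general-function domain hit at specific strength;
- **probable** — an nr hit with identity > 30% over coverage > 0.70;
- **hypothetical** — nothing qualifying.

The bands are deliberately cumulative rather than closed intervals: a
closed putative band (E in (1e-10, 1e-4] *and* coverage in
[0.50, 0.70]) would make the classifier non-monotone — improving a
hit's coverage from 0.60 to 0.75 at E = 1e-6 would drop the gene from
putative to hypothetical. With cumulative thresholds, strengthening
any piece of evidence can never lower the tier (property-tested), and
every worked threshold example classifies identically. All boundaries
are configurable via `TierThresholds`.

Motif screening is a sliding-window Hamming scan (pattern, maximum
mismatches); the shipped table carries the sulfocyanin fingerprint
FNFNGTS and the aerobic form II CODH active-site motif AYRGAGR, both
with a one-mismatch budget since diagnostic copies in divergent
lineages are imperfectly conserved. Rusticyanin-specific motifs are
not bundled — no consensus is shipped that we could verify — so
rusticyanin screens should load a user motif table. The type I
copper-site check searches for an ordered H···C···H···M placement
within spacing windows defaulting to C at 20–60 residues after the
first H, the second H 1–10 after the C, and M 1–15 after the second H
(canonical cupredoxin architecture; fully configurable), returning the
left-most placement.

## Island detection

A gene is foreign-like when it has orthologs in at most
`max_panel_hits` reference genomes (default 0, i.e. "virtually no
orthologs"; 1 is a reasonable relaxation for spotty panels). Islands
are maximal runs of ≥ `min_run` consecutive foreign-like genes on one
contig; `min_run` defaults to 5, small enough to catch single-digit
gene blocks and large enough to suppress singleton annotation noise.
Composition annotation reports the island's GC over its concatenated
genes as a z-score against the per-gene GC distribution of the rest of
the genome (population SD; the island's own genes are excluded from
the background so a large island cannot dilute its own signal), plus
the strand GC skew (G−C)/(G+C). Both composition measures are
reported and neither is used as a detection filter: a transfer from a
donor with host-like GC leaves no compositional anomaly yet is still
detected through ortholog absence.

## The evolver

`evolve_pair` builds an ancestor of `n_genes` random proteins (uniform
over the 20 residues; lengths geometric around `mean_protein_len`,
minimum 50) and evolves two lineages independently: per-gene Binomial
substitution at per-site proportion s (replacement uniform over the
other 19 residues — identity is the measurand, so no rate matrix),
whole-gene loss with probability `loss_prob`, `gain_count` novel gene
insertions, and, in lineage B, `n_inversions` interval reversals
(strand-flipping) and `n_translocations` interval moves. Lineage A
optionally receives an island of novel genes whose DNA targets a GC
content shifted by `gc_shift_sd` standard deviations of the realized
per-gene background GC. DNA is produced by reverse-translating with
the standard codon table; synonymous codons are weighted by
exp(β·GC(codon)) with β solved by bisection so the expected GC over
the protein's amino acid composition hits the target. Genes are laid
on contigs with 20-nt random spacers; `evolve_panel` evolves k
lineages from one ancestor at staggered divergences, and
`evolve_family` produces a query-plus-panel family for island
benchmarks. One `numpy` generator seeded from `seed` drives all
randomness, so a seed reproduces byte-identical output.

Recorded truth: the ancestor-mediated orthology, per-pair realized
identities (positional comparison — substitutions only, no indels, so
identity is well-defined without alignment), strictly-adjacent
collinear segments computed by an independent run-scan over the final
ordinal permutation (not by the detector), and the island's contig and
ordinal span. Expected pairwise identity for lineages at s_a and s_b
is 100·(1−s_a)(1−s_b), ignoring back-substitution coincidences of
order s²/19.

What the evolver does *not* emulate — and hence what passing
benchmarks do not show about real data: within-gene indels and
frameshifts, site- and gene-rate heterogeneity, paralogous families
(every ancestral gene is unique, so RBH faces no paralog confusion),
codon-usage and amelioration dynamics beyond a single GC target,
assembly artifacts, and contamination.

## Benchmark problem sizes

The test and acceptance runs use deliberately modest instances — exact
all-vs-all alignment is quadratic, and these sizes already give tight
statistical checks: divergence recovery at 200 genes × 300 residues
(≈ 60k ortholog residues, binomial SD ≈ 0.15 points against a ±1
tolerance); block-length monotonicity over 20 replicates × 4 inversion
levels at 50 genes; island recovery over 200 replicates of 40-gene
genomes with a 2-genome panel; z-calibration over 1000 background
draws; oracle equivalence over 500 random hit tables and all 46,233
gene-order permutations of up to 8 genes.

## Degenerate inputs and numerical conventions

Zero orthologs: AAI raises, ortholog fraction is 0, synteny fraction
0 with mean block length NaN. Zero-length proteins are skipped with a
warning; empty protein or marker sets are errors. Coverage of the
shorter sequence is taken as max(q_cov, s_cov). E-values below the
double underflow print as 0.0. Gene tables are re-sorted by (contig,
start, gene_id) on read and ordinals reassigned 0..n−1 per contig, so
overlapping genes (including opposite strands) order deterministically.
Per-gene GC background uses the population (ddof = 0) standard
deviation; a zero-variance background yields ±inf z.

## Known limitations

- The internal aligner is exact and therefore quadratic; genome-scale
  all-vs-all should come from an external search engine as hit tables.
- RBH without paralog clustering can mispair recent in-paralogs; the
  synthetic benchmarks do not exercise this failure mode.
- Greedy block construction is swap-asymmetric for gap tolerance ≥ 1
  (see above).
- AAI from local alignments is slightly optimistic versus site-wise
  identity (terminal trimming).
- The 16S identity matrix treats every input sequence as a
  full-length, correctly oriented gene; no trimming or reverse
  complementing is attempted.
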