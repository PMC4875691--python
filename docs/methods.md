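# Methods

This note documents the models, conventions and numerical choices behind
`bamphy`, in the spirit of a package methods appendix: what each stage
assumes, which knobs matter, and what the synthetic data does and does not
emulate.

## The analysis in one paragraph

Putative single-copy nuclear orthologues are anchored on two reference
gene sets (a rice-like first reference and a *Brachypodium*-like second
reference). A gene is accepted as an anchor only when its sole filtered
hit in the other reference set points back at it — reciprocal uniqueness
is the guard against paralogy. Each bamboo taxon contributes the
homologous region of its best-scoring transcript, clusters incomplete for
any required taxon are dropped, clusters are aligned and per-gene trees
estimated, and every tree is rooted at the rice outgroup and scored for
the monophyly of named clades (woody bamboos, all bamboos, within-tribe
pairs, and the competing plastid arrangement). The per-hypothesis tallies,
printed as truncated two-decimal percentages, are the headline statistic.
A parallel workflow identifies MADS-box floral proteins, collapses
conspecific assembly redundancy, and assigns copies to the A, B, C/D, E,
SOC-like and SVP-like families from an anchored tree.

## Homology search

`score_local_alignment` is optimal affine-gap Smith–Waterman; the engine
is Biopython's `PairwiseAligner` (C implementation), with this module
owning the conventions: a gap of length L costs `gap_open + L·gap_extend`;
nucleotide defaults +1/−2 with gaps 5/2; protein mode uses BLOSUM62 with
gaps 11/1. `seeded_search` aligns every query/subject pair sharing at
least one exact k-word (both strands in nucleotide mode; k defaults to 11
nucleotide / 3 protein) and keeps one hit per pair — multiple high-scoring
segments collapse to the best, because downstream "exactly one hit" logic
counts subjects, not segments. The test suite checks the engine against an
independently written plain-Python DP on thousands of random pairs.

Karlin–Altschul λ and K are scheme constants (standard published values),
not estimated from data: every decision the pipeline takes depends only on
threshold crossings, which the tests control explicitly. E-values use the
database-wide search space m·n_total (n_total = summed subject lengths),
with no edge-effect correction. All three filter comparisons are inclusive
at the stated thresholds (`E ≤ 10⁻⁵`, `length ≥ 100`, `identity ≥ 0.70`),
reading "maximum"/"minimum" literally. Percent identity counts gapped
columns in the denominator and never the numerator.

The end-to-end pipeline raises the seed word size to k = 16: with
genome-scale gene sets, two unrelated kilobase sequences share an 11-mer
by chance about half the time (≈ L²/4¹¹), which makes the candidate list
quadratic, while true homologs at ≥ 70 % identity still share hundreds of
exact 16-mers. This changes only which pairs are *attempted*; scores and
filters are unaffected.

## Orthologue clusters

Reciprocal uniqueness is evaluated after filtering (filter first, then
count subjects), and ties in the best-bit-score member are broken by
higher identity, then lexicographically smaller subject id. The second
reference joins each cluster through the anchor-defining hit (its
homologous span on the second-reference gene); extracted minus-strand
regions are reverse-complemented so all members are co-oriented with the
anchor. The completeness rule is exact: a cluster survives only if every
required taxon has a member.

## Alignment, supermatrix, gap stripping

The built-in aligner is deterministic progressive alignment: pairwise
k-mer distances (k = 6) feed a greedy average-linkage guide tree with ties
broken by input order, and profiles are merged by affine-gap global DP
over profile column-frequency scores (the inner loop is JIT-compiled with
numba, with a pure-Python fallback). Determinism and testability are the
design goals; alignment quality beyond that is not, and an
`external_aligner` escape hatch accepts any FASTA-in/FASTA-out command
(e.g. `mafft`) for users who want a consistency-based aligner. The
invariant enforced after every alignment: ungapping any row reproduces its
input sequence exactly.

Concatenation requires identical taxon sets across alignments and records
a partition table in 0-based half-open column coordinates. Gap stripping
removes every column in which any row has a gap — only `-` counts as a
gap; `N` and other ambiguity codes are ordinary states — and remaps
partition boundaries onto surviving columns. Stripping is idempotent and
checked against a direct column scan.

## Trees

Distances are Kimura two-parameter with pairwise deletion: for each pair
only columns where both rows hold A/C/G/T enter, P and Q are the
transition and transversion proportions, and
`d = −½·ln((1 − 2P − Q)·√(1 − 2Q))`. Saturated pairs (log argument ≤ 0)
are capped at d = 10.0 with a warning — far above any distance the
generator produces, so a triggered cap signals degenerate input rather
than a tuning choice.

Neighbor joining is the classical Saitou–Nei algorithm. Q-criterion ties
break lexicographically on the pair of clade labels, where an internal
node carries the smallest leaf label of its clade — this makes the
topology independent of input order. Negative branch-length estimates are
clamped to zero. The endgame joins the last three lineages at a
trifurcation with the closed-form pendant lengths, so on additive matrices
the output reproduces the generating tree's path distances exactly (the
suite verifies 100 random additive 6-taxon matrices to 1e-9).

Maximum-likelihood estimation is deliberately out of scope: the quantities
this package exists to produce — topology counts, consensus, support — are
estimator-agnostic, and a desk-scale repository should not carry a
half-tested likelihood engine. An `external_tree` hook accepts any
FASTA-in/newick-out program (e.g. `fasttree -nt`).

Bootstrap support resamples alignment columns with replacement (same
column count), re-estimates NJ trees, and scores each internal bipartition
of the point-estimate tree by its pseudoreplicate frequency. The
majority-rule consensus keeps exactly the bipartitions with frequency
strictly greater than the threshold (default 0.5, below which retained
splits could conflict); the retained splits form a laminar family from
which the (possibly multifurcating) consensus is built directly, with each
split labeled by its frequency. A test cross-checks the retained
bipartition set against dendropy's independent consensus machinery. The
consensus is descriptive output; the headline counts come from per-tree
classification.

## Hypothesis support and the percentage convention

Trees are rooted on the edge subtending the designated outgroup leaf. A
taxon set is monophyletic iff some node's descendant leaf set equals it
exactly; polytomies get no soft credit, and trees where the outgroup sits
inside a hypothesized clade simply fail that clade. Hypotheses are
evaluated independently, so one tree may count toward several.

Percentages are **truncated** to two decimals, in exact integer
arithmetic: `floor(count·10⁴ / total) / 10²`. The convention is forced by
the published pairs themselves — 2374/3878 = 61.2171 % prints as 61.21
(rounding would give 61.22), and 2412/3878 = 62.197 % prints as 62.19 —
and is frozen as the report's contract.

## MADS-box workflow

Candidates are translated transcripts (a longest-ORF helper over six
frames stands in for full ORF prediction; no start-codon requirement) with
at least one filtered protein hit from the labeled reference anchors and
length strictly greater than 100 aa. The protein filter policy keeps the
E-value and identity thresholds but lowers the minimum alignment length to
50 residues (the 100 of the nucleotide policy is a bp quantity).

Conspecific redundancy — the same protein assembled twice — is collapsed
by single-linkage grouping at pairwise identity strictly above 0.95,
computed over overlap-only columns of an end-gap-free global alignment so
partial assemblies of one protein compare cleanly. The threshold sits
above the most similar pair of genuinely distinct reference copies (93 %
identical), so real paralogues survive. Each group collapses to the
majority-residue consensus over the union of aligned positions, ties going
to the longest source: this realizes both published outcomes ("reduced to
one copy" when one source covers the other, "merged" when they cover
different regions) with a single deterministic rule.

Family assignment builds one NJ tree over all copies plus labeled
references on protein p-distances (1 − identity; no rate correction, since
assignment depends only on relative placement), roots it at the midpoint,
and gives each copy the family of its smallest enclosing clade containing
references — of exactly one family, else the copy stays unassigned. This
is the deterministic version of assigning clades by inspection of the
non-bamboo reference genes they contain. Per-family subtrees are then
re-aligned and re-estimated, each rooted at the lexicographically first
reference copy of the family (a fixed stand-in for per-family outgroup
choice); sister-group classification (is a copy's sister composed
exclusively of bamboo copies from other species?) runs on these trees.

## The synthetic data generator

The generator's defaults are the study conditions the tests assume:

| parameter | default | meaning |
|---|---|---|
| taxa | 7 study species | rice-like + *Brachypodium*-like references, then herbaceous, 2 tropical woody, 2 temperate woody bamboos |
| concordance | 0.62 | probability a gene tree matches the species topology |
| alternative | plastid rearrangement, 0.38 | the single discordant topology, so counts map onto the two named hypotheses |
| gene length | uniform 300–1500 bp | desk-scale choice; no empirical length distribution is claimed |
| model | HKY, κ = 2, π = (0.3, 0.2, 0.2, 0.3) | simplest model with both a ts/tv ratio and unequal frequencies |
| branch scale | 0.02 subs/site per unit branch | keeps reference-to-bamboo identity ≈ 0.89 — inside the 70 % filter with signal to spare |
| branch jitter | lognormal, σ = 0.3, mean 1 | per-edge multiplicative rate variation |
| paralogue rate | 0.1 /gene/taxon | extra copies diverged a further 0.25 subs/site, truncated to 50–100 % length (the source of gapped alignment columns) |
| variant rate | 0.1 | near-duplicate conspecific copies at < 5 % divergence, to exercise redundancy merging |

Sequence evolution applies the per-branch HKY transition matrix
`expm(Q·scale·t)` independently per site, with Q normalized to one
expected substitution per site per unit branch. Indels are not simulated;
raw sequences are pure A/C/G/T, and gaps arise only from alignment of
truncated paralogues. The two reference gene sets are emitted noise-free:
they model curated single-copy syntenic gene sets extracted from sequenced
genomes, which is how the anchors were obtained. The MADS generator draws
one ancestral protein per class (classes ≈ 35 % diverged from a common
root, far beyond the 95 % merge radius), per-taxon copies at ≈ 10 %
divergence from their class ancestor, two labeled anchors per class at
≈ 8 %, and unrelated random decoys; all family copies exceed 100 aa.

What the generator does **not** emulate — read-level errors, assembly
chimeras and fragmentation, expression-level dropout, allopolyploid
subgenomes, codon structure and selection, indel processes — bounds what
passing tests show: they validate the *decision logic* of the pipeline
(filters, uniqueness, completeness, classification, tabulation) under the
statistical structure the analysis assumes, not robustness to real
assembly artifacts.

## Problem sizes and determinism

The concordance-recovery suite runs the full pipeline at 500 genes over
six taxa (the package's chosen desk-scale size; one run takes a few
minutes on one CPU) and checks the recovered woody-monophyly fraction
against the exact binomial 99 % interval for p = 0.62, n = 500. Cluster
bookkeeping is verified at 60 genes with 10 % transcript dropout against
direct truth-table enumeration; oracle-equivalence suites use 1,000 random
pairs (≤ 30 bp) and every unrooted topology on up to 7 leaves. All
randomness flows from explicit integer seeds through numpy Generators, and
identical configurations produce byte-identical FASTA/newick output.

## Known limitations

- NJ on K2P distances mis-resolves very short internal edges more often
  than ML would; at the default branch scale this depresses recovered
  concordance by a percentage point or two, well inside the stochastic
  test bands, but users pushing `branch_scale` much lower should expect
  estimator noise to dominate.
- The progressive aligner scores profile columns by frequency products
  with position-independent gap costs; it is not a consistency-based
  aligner and will be beaten by one on distant or indel-rich homologs.
- `subtree_category` and sister-group classification assume strictly
  bifurcating rooted family trees (NJ output rooted at a reference);
  polytomies in externally supplied trees classify as "none".
- The E-value model ignores edge effects and composition; at the 10⁻⁵
  threshold with kilobase sequences this is immaterial, but single very
  short queries near the threshold would need proper finite-size
  corrections.
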