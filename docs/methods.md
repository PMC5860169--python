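# Methods

This document records the models, parameter choices and numerical
decisions behind `gbdphylo`, including where the implementation had
latitude and why each option was taken.

## 1. Local alignment

### Built-in aligner

The built-in aligner is a deliberately simple seed-and-extend *ungapped*
local aligner:

- **Seeds**: exact word matches — 11-mers for nucleotide data, 3-mers for
  amino-acid data. All word positions of the subject are indexed in a hash
  table; query positions are streamed against it. A per-diagonal frontier
  skips seeds that fall inside an extension already performed on the same
  diagonal.
- **Extension**: ungapped X-drop in both directions (drop-off 20 for
  nucleotide scores, 15 for protein scores), vectorized with numpy prefix
  sums. Extensions on the same diagonal are deduplicated by their extent.
- **Scoring**: nucleotide match +2 / mismatch −3; protein scoring uses
  BLOSUM62. Both strands are searched for nucleotide data by aligning
  against the reverse complement and mapping coordinates back; minus-strand
  HSPs store ascending subject coordinates plus a strand flag.
- **Statistics**: e-value `K · m · n · exp(−λ · S)` with K fixed at 0.1
  and λ solved per scoring scheme by bisection on
  `Σ p_i p_j exp(λ s_ij) = 1` (uniform background frequencies) to 1e-9.
  For +1/−1 scoring this gives the textbook closed form λ = ln 3, which
  the tests assert. The simplification of a fixed K and uniform
  backgrounds changes absolute e-values but preserves the score ordering,
  which is what the e-value grid filter consumes.

Ungapped alignment understates homology compared to a gapped aligner; the
distance formulas only consume matched-column and identity totals, and the
filter/formula pipeline is agnostic to the aligner, so an external gapped
tool can be substituted (see below).

### External backend

Any tool emitting 12-column tabular hits (query, subject, % identity,
length, mismatches, gap opens, q. start/end, s. start/end, e-value, bit
score) can feed the pipeline; `pipeline.external_hsps` shells out to
locally installed BLAST+ when available. Coordinates are converted to
0-based half-open; a subject start greater than the subject end marks a
minus-strand hit. Identities are recovered as `round(pident/100 × length)`.

## 2. HSP filtering

Two mutually exclusive algorithms resolve overlapping HSPs; both operate
per genome pair and direction.

- **Greedy trimming**. HSPs are processed in descending score order (ties:
  longer first, then input order). Each HSP is reduced to its longest
  contiguous run of alignment columns whose query *and* subject positions
  are still unclaimed by previously accepted HSPs (earliest run on ties);
  identities are scaled proportionally to the retained fraction. A rule
  that instead shortens only from the HSP ends by the total overlap length
  was considered and rejected: when a previously accepted HSP claims
  positions in the *middle* of a candidate, end-shortening either leaves
  claimed positions counted twice or is not idempotent. The longest-free-run
  rule reproduces the intended behaviour on end-overlaps exactly and is
  idempotent (re-filtering retained HSPs is a no-op), which the tests
  enforce and a position-set brute force verifies.
- **Coverage**. HSPs are processed in the same order; each contributes its
  newly covered query and subject positions to a union, and identities are
  prorated by the newly covered query fraction. Nothing is discarded, so
  repeated regions count once.

The retained per-HSP contributions (matched lengths, columns, identities)
are the resampling units for the pseudo-bootstrap.

## 3. Distances

With `MatchSummary` totals (matched_A, matched_B, columns C, identities I)
and genome lengths L_A, L_B:

| formula | definition | character |
|---|---|---|
| d0 | 1 − (matched_A + matched_B)/(L_A + L_B) | resolution among close genomes |
| d4 | 1 − I/C (1 if C = 0) | robust to incomplete genomes |
| d6 | 1 − 2I/(L_A + L_B) | balanced; classification default |

Each pair is aligned in both directions; the pair distance is the mean of
the two directional distances, clamped to [0, 1]. Replicate r resamples
each direction's contribution list with replacement using an RNG derived
from `SeedSequence([seed, crc32("idA|idB"), r])`, making every pair and
replicate independent of processing order — the matrix is invariant under
genome reordering, which the tests check.

The distance matrix type enforces symmetry (tolerance 1e-12), an exactly
zero diagonal, [0, 1] bounds and unique labels at construction, so any
violation fails fast rather than propagating.

## 4. Trees

- **Neighbour joining** (Saitou–Nei with the Studier–Keppler Q criterion)
  is implemented directly so that tie-breaking is deterministic: equal Q
  values resolve by the lexicographically smallest pair of cluster labels.
  Negative branch-length estimates are clamped to zero, and zero-length
  internal edges are collapsed into multifurcations — an all-zero matrix
  therefore yields a star tree rather than an arbitrary resolution. NJ is
  consistent on additive matrices; the tests verify exact recovery of
  random additive trees and agreement with an independent implementation
  (scikit-bio) when available.
- **Midpoint rooting** places the root halfway along the path between the
  two most distant leaves (lexicographic tie-break; an all-zero tree roots
  at the smallest leaf's edge). The two most distant leaves end up
  equidistant from the root, a property the tests assert on random trees.
- **Branch support**: each replicate matrix yields a replicate NJ tree;
  an internal edge's support is the rounded percentage of replicate trees
  containing the same bipartition (canonical form: the side not containing
  the lexicographically smallest taxon). Trivial splits score 100.

## 5. Taxon support and monophyly

A taxon's leaves are classified as monophyletic (exact clade),
paraphyletic or polyphyletic. The para/poly distinction follows maximum
parsimony on the binary membership character (Sankoff up/down passes): the
taxon is paraphyletic iff some most-parsimonious reconstruction assigns
the member state to the MRCA. An exhaustive reconstruction oracle in the
tests checks this on small random trees. Signed per-taxon support is the
branch support of the clade for monophyletic taxa and minus the maximum
support among contradicting clades otherwise; the per-rank overall score
is Σ signed / Σ |signed| ∈ [−1, 1].

## 6. Clustering

Threshold clustering links pairs with d ≤ T and greedily merges the
cluster pair with the highest linked fraction f = links/(|P||Q|) subject
to f ≥ F, breaking ties by smallest inter-cluster distance then labels.
F = 0 reproduces connected components and F = 1 produces cliques (both
properties are tested against independent references). Default F = 0.5.

Partition agreement (MRI) is the Hubert–Arabie adjusted Rand index,
delegated to scikit-learn and verified in the tests against an
independent pair-counting formula, exhaustively over all set partitions
of small element sets. Threshold optimization scans the midpoints between
consecutive observed distances plus one candidate below the minimum and
one above the maximum — the finite set of all behaviourally distinct
thresholds — and returns the smallest maximizer.

Default per-rank thresholds (d6, F = 0.5): species 0.022085, genus
0.842700, subfamily 0.997270, family 0.997455 for nucleotide data;
species 0.118980, genus 0.749680, subfamily 0.888940, family 0.985225
for amino-acid data. They are calibration constants, not laws; `run`
accepts per-rank overrides.

## 7. Settings grid and selection

The study grid crosses sequence type (nucleotide, amino acid), e-value
threshold (10, 1, 0.1, 0.01, 1e-3, 1e-8), filter algorithm (trimming,
coverage) and formula (d0, d4, d6) — 72 points, or 240 with the full
ten-slot formula registry. Each point is scored by six objectives: overall
taxon support and best achievable MRI at species, genus and family rank.
Selection is a two-step Pareto filter per sequence type — non-dominated on
the three taxon-support objectives first, then non-dominated on the three
MRI objectives within that set. The order matters (a point with the best
MRI but dominated taxon support is excluded), and the grid evaluation
computes HSPs once per pair at the loosest e-value and re-filters them per
grid point, since the HSP set at a stricter threshold is a subset.

Host specificity of a cluster is the modal-host share m/N over its
annotated members, at host species (binomial) or host genus (first token)
rank.

## 8. Synthetic data generator

Purpose-built for ground-truth testing, not realism:

- **Tree**: balanced, caterpillar or random shape over n taxa; branch
  lengths i.i.d. exponential (default mean 0.02 expected substitutions per
  site) or fixed per edge class. `min_internal_length` adds a floor to
  internal branches (shifted exponential) for recovery studies: an
  internal branch with a handful of expected substitutions is statistically
  unresolvable, so recovery claims are only meaningful above a signal
  floor.
- **Evolution**: uniform random site replacements, Poisson(rate × branch
  length × genome length) per branch — a Jukes–Cantor-like process without
  rate heterogeneity, indels (unless block deletions/inversions are
  enabled) or selection. Optional truncation of designated leaves models
  incomplete genomes.
- **Taxonomy/hosts**: species/genus/family assigned in consecutive leaf
  blocks; on balanced trees with a power-of-two taxon count these blocks
  coincide with clades, giving a consistent ground truth. One host species
  per designed virus species makes host specificity 1 by construction.
- **Proteomes** are emulated by translating consecutive 900-nt blocks
  (bacterial code, stops mapped to X) — this exercises the protein
  pipeline without a gene finder, at the cost of unrealistic gene
  boundaries.

Limits: no mosaicism or horizontal transfer, no compositional bias, no
gapped divergence. Conclusions from the generator are about algorithmic
correctness, not biological performance.

## 9. Determinism and numerics

- All stochastic components (replicates, simulations, the acceptance
  script) derive from explicit integer seeds via `numpy.random.SeedSequence`
  chains; identical seeds give byte-identical output files.
- λ bisection to 1e-9; matrix symmetry tolerance 1e-12 internally and
  1e-9 for files (matrices are written with 9 decimals).
- Problem sizes used in the test oracles (≤ 8 taxa for exact NJ recovery,
  ≤ 6 HSPs for the trimming brute force, ≤ 6 elements for exhaustive
  partition enumeration, ≤ 50 points for Pareto scans) are chosen so the
  independent brute-force references stay exact and fast; the algorithms
  themselves have no such limits.
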