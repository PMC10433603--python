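# Methods

## Problem and model

Given reference genomes of many strains of one bacterial species and a
short-read sample, the task is to report which strains are present and
their relative abundances. Strain collections are heterogeneous: some
strains differ by whole gene islands, others by a handful of SNVs. A single
flat search over all strains wastes the easy cases and fails the hard ones,
so the method is hierarchical: a coarse, fast **cluster search** over
groups of near-identical strains, then a fine **within-cluster resolution**
using every k-mer with discriminative power.

All sequence comparison is on canonical k-mers: the lexicographically
smaller of a k-length ACGT word and its reverse complement, 2-bit encoded.
k is odd so no k-mer equals its own reverse complement. Windows containing
ambiguous bases are skipped; input case is folded.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 31 | k-mer length (odd, ≤ 63; 2-bit packed in 64 bits) |
| H | 0.95 | Jaccard cutoff for single-linkage cluster formation (inclusive: J ≥ H joins) |
| derep threshold | 0.99 | complete-linkage dereplication similarity; representative = highest mean similarity, ties to smallest id |
| α | 90% | leaf k-mer prevalence filter (fraction of cluster strains containing a k-mer; boundary inclusive) |
| min_kmers | 1000 | weak-node augmentation floor |
| e | 0.01 | scalar sequencing error rate for the binomial stop test |
| β | 0.05 | significance level of the stop test |
| frac floor | 0.1 | matched fraction below which a node's abundance is forced to 0 |
| F cutoff | 0.4 | weighted matched fraction a leaf path must exceed to be reported |
| stop threshold | 1240 (= 31·40) | remaining-occurrence mass ending iterative strain detection |

Depth estimates are in per-k-mer coverage units; nominal read coverage is
larger by the factor `L_read/(L_read − k + 1)` (and, with errors, by
`(1−e)^{−k}`).

## Cluster search tree

Node k-mer sets are built by the promotion procedure: leaves start from the
α-filtered cluster sets; the intersection of two siblings' current sets
moves to the parent; after the sweep, any k-mer still held by more than one
node is deleted everywhere. The result per node equals the closed form
`⋂_{leaves under v} L_i − ⋃_{leaves outside v} L_i` (the test suite checks
this equivalence on random trees), so every node's set is unique to its
subtree and node sets are pairwise disjoint.

Nodes can end up with few k-mers — in a star-like radiation the deep
intersections are nearly empty — and small sets are matched by chance.
Such nodes are augmented: candidate k-mers must occur in at least one
subtree strain, in no strain outside the subtree, and in no other node;
candidates are taken in decreasing within-subtree prevalence (ties by
k-mer value) until the floor is reached. Augmentation therefore never adds
cross-subtree ambiguity; it does dilute a node's "shared by most subtree
strains" property, which lowers the matched fraction for samples
containing only one subtree strain — acceptable because the binomial test
operates on the positive-count mean, not the fraction.

The search is breadth-first from the root. The root's children enter the
queue whenever the root has positive abundance; thereafter a node is
expanded (or, at a leaf, kept as a candidate) when the binomial test
rejects the hypothesis that its abundance is the parent's abundance eroded
by sequencing errors. Abundances are rounded half-up to integers for the
test; a child exceeding its parent yields p = 0 and always traverses. Both
siblings may pass, so several clusters can be identified. Each candidate
leaf is scored over the path from the root of the maximal subtree
containing no other candidate down to the leaf; counts of path k-mers also
present in another candidate's strains are first reduced by that
candidate's (preliminary, unadjusted) abundance estimate and floored at 0,
so shared ancestral k-mers are not double counted. The adjustment is
symmetric over all candidates rather than sequential, since either member
of a sibling pair may need discounting against the other. A per-k-mer
exclusion variant (drop shared k-mers instead of subtracting) is available
in the API.

Degenerate references with a single cluster skip the tree walk: the lone
leaf is accepted directly when it has positive abundance and passes the F
cutoff.

## Within-cluster resolution

The cluster's strain matrix X holds every k-mer whose presence pattern
across member strains is non-constant. Rows are annotated: **joint** if a
Hamming-1 partner k-mer exists with the complementary pattern (SNV/indel
alternatives — checked before the popcount rule, since in a two-strain
cluster a variant k-mer is both single-strain and partnered),
**strain-specific** if exactly one strain carries it, **group-specific**
otherwise. The annotation is diagnostic; identification uses all rows.
Identical member k-mer sets are rejected (columns would be
indistinguishable). Single-strain clusters get a capped all-ones matrix
used only for depth estimation.

The observation vector y is the read count of each matrix k-mer, with
k-mers present in any *other identified* cluster masked to zero. Detection
zeroes y outside the [5th, 95th] percentile of its positive entries
(attained-value quantiles, so tiny vectors keep their extremes), then
repeats: score each unselected strain by `f_j = X[:,j]·y`, select the
argmax (ties to the smallest id), zero y on the selected strain's k-mers.
Iteration stops when the remaining occurrence mass `Σy` drops below the
stop threshold or no strain scores positive. The occurrence-sum reading of
the stop quantity is used because it separates signal from noise at any
reference size: remaining true-strain occurrences scale with sequencing
depth (several counts per k-mer), while error-induced occurrences stay
near one per k-mer. A count-of-positive-k-mers variant (`stop_on='count'`,
with a proportional small-matrix scaling) is retained; note that with
joint k-mers each variant locus contributes about equally many derived and
ancestral rows, so one strain's private rows are ≈ M/2N of the matrix and
a count threshold of M/10 cannot find the fifth strain of a five-strain
cluster even noiselessly.

Depths of the selected strains are fit per cluster by non-negative
elastic net without intercept or standardization (binary design, columns
on comparable scales), with the mixing weight over {0.1,…,1.0} and a
50-point log-spaced penalty path (down to 1e-4·λ_max) tuned by 5-fold
cross-validation on contiguous folds — fully deterministic. The regression
uses the masked but *untrimmed* y: the percentile trim is a detection-stage
guard, and clipping genuinely high-count shared rows biases minor-strain
depths. Strains with zero coefficients are dropped. Within-cluster
abundances are normalized coefficients; across clusters each strain is
weighted by its cluster's tree-search abundance and renormalized.

## Evaluation

Precision/recall/F1 count exact strain identities; the cluster-level
variant maps both sides through the cluster assignment first, so any
representative of the right cluster is a true positive. Ratios with empty
denominators are 0. Abundance profiles are compared with the base-2
Jensen–Shannon divergence (bounded in [0,1]); profiles are aligned by
strain id with absent ids as zeros, with pure positional zero-padding
available behind a flag.

## Synthetic data

The simulator emulates a single species at desk scale. An ancestral random
genome (default 50 kb) radiates into 6 cluster ancestors (substitution
rate 5·10⁻³, small-indel rate 10⁻⁴, one segmental deletion and insertion
of 80–200 bp each), each of which radiates into strains
((5,4,4,3,2,2) per cluster; substitution rate 1.2·10⁻⁴, indel rate
2·10⁻⁵, one segmental deletion and insertion per strain). These rates put
pairwise within-cluster Jaccard near 0.96–0.98 (above the H = 0.95 cutoff)
and between-cluster Jaccard near 0.6 (well below it), the similarity
regime the method targets; the realized structure is verified after
generation and regenerated with nudged rates a bounded number of times if
it misses. Small-indel lengths are geometric with mean 10; mutation
positions are uniform, with collisions resolved by the sequential edit
order rather than explicit bookkeeping.

Reads follow the standard benchmark protocol: paired 250 bp reads,
fragment length normal(600, 150) truncated to [read length, genome
length], uniform substitution errors at 1%, constant quality strings,
read pairs ≈ depth·L/(2·250). Mixtures pool per-strain simulations
(depth profiles 100/10, 100/50/10, and 100/70/50/20/10 for 2, 3, and 5
strains) and shuffle; truth abundances are depth·length shares. Everything
is bit-reproducible under a fixed seed.

What the simulator does **not** model: real error profiles (quality-
dependent, indel errors), GC and coverage bias, shared gene gain/loss
along the phylogeny (cluster ancestors radiate independently from one
ancestor), repeats and mobile elements, and host or off-target species
background (an unrelated random genome can be spiked in manually). Passing
tests therefore demonstrate correctness of the algorithms and calibration
of the statistics under idealized, uniform-coverage data — not robustness
to real-library artifacts. Genome sizes are two orders of magnitude below
real bacterial chromosomes, so per-strain discriminative k-mer counts (and
hence the attainable depth precision at fixed coverage) are accordingly
smaller; test problem sizes (20 strains, 50 kb, ≤ 250X pooled coverage)
were chosen to preserve the method's similarity regimes at that scale.

## Numerical and design notes

- Exact Jaccard on full k-mer sets, not sketches: desk-scale sets make
  sketching unnecessary, and exactness simplifies the oracles.
- Hierarchical clustering and the exact binomial CDF come from scipy; the
  dendrogram cut is an explicit threshold walk over the merge tree (equal
  to connected components of the J ≥ H graph for single linkage, which the
  tests verify independently).
- Merge-height ties in agglomeration follow scipy's deterministic
  ordering; cluster membership at any cut is tie-invariant under single
  linkage.
- Rounding "to nearest integer" in the stop test is half-up.
- The serialized index is all plain text with sorted, versioned files;
  rebuilding from identical inputs is byte-identical.
- Known limitations: no streaming counting (counts are held per batch in
  memory); single species per index; no incremental index updates; the
  weak-node augmentation procedure is a reconstruction that preserves the
  no-added-ambiguity contract but is not guaranteed identical to any
  particular production implementation.
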