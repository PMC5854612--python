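# Methods

## Problem setting

A module detection method takes a genes × samples expression matrix and
returns named gene modules. Unlike ordinary clustering output, these modules
may overlap (a gene can sit in several regulatory programs) and need not be
exhaustive (many genes belong to no detected module). Evaluating such output
against a gold standard therefore needs scores defined for overlapping,
non-exhaustive set systems, a chance baseline that accounts for the gold
standard's own structure, and a tuning protocol that controls for parameter
overfitting. This package implements that evaluation stack and a synthetic
generator to exercise it end to end.

## Gold standards from regulatory networks

Known modules come from a trusted regulator→target network under three
definitions:

- *minimal co-regulation*: one module per regulator, equal to its regulon.
  Overlapping by construction; the weakest notion of co-regulation.
- *strict co-regulation*: genes grouped by identical incoming-regulator
  sets. A partition of the regulated genes; the strongest notion.
- *interconnected modules*: Markov clustering (MCL) of the network graph.
  Captures dense interconnection rather than shared regulators.

MCL details (the choices a bare description leaves open): the adjacency
matrix is symmetrized with max(A, Aᵀ); unit self-loops are added; columns
are normalized; expansion is the matrix square; inflation raises entries
elementwise to the inflation power and renormalizes; entries below 1e−8 are
pruned each iteration; convergence is a maximum absolute change below 1e−6,
with an error after 200 iterations. Clusters are read from attractor rows
(positive diagonal); identical clusters are deduplicated, overlapping
attractor rows may legitimately yield overlapping clusters and are kept.
Typical inflation values are 2 (coarse), 10 and 50 (fine). Weighted
networks (e.g. network-inference rankings) are first thresholded to
unweighted edges.

Derived module sets are cleaned by `filter_modules`: modules are first
intersected with the expression universe when one is given; then, while any
pair has Jaccard above the merge threshold (default 0.8), the currently
highest-Jaccard pair is replaced by its union (ties broken by the
lexicographic name pair, making the procedure deterministic); finally
modules below the minimum size (default 5 genes) are dropped.

## Scores

Four scores compare known modules M with observed modules M′; all lie in
[0, 1] and all equal 1 when the two sets are identical.

**Precision / recall (CICE-BCubed).** Gene-pair-centric: for gene g and
each gene g′ sharing at least one observed module with it, the score asks
whether the *number* of shared modules matches between M and M′
(the min/ratio term) and whether the shared modules themselves *look like*
known modules (the Φ term, a mean over observed modules containing both
genes of their best Jaccard match among known modules containing both).
Recall is the same computation with the roles of M and M′ swapped — the
implementation literally swaps the arguments, so the symmetry
`precision(M, M′) = recall(M′, M)` is exact. The outer average runs over
genes covered by at least one observed module (for precision) or known
module (for recall): for a non-exhaustive detector the per-gene term is
undefined when M′(g) is empty, and averaging over covered genes is the
BCubed convention. Subset variants (precision*/recall*) restrict and
renormalize the outer average to a chosen gene subset — e.g. genes in
exactly one vs several known modules — while the inner sums still run over
the full neighbourhood; they quantify specifically how well a method handles
overlapping genes.

**Recovery / relevance.** Module-centric best-match Jaccard: relevance
averages, over observed modules, the best Jaccard with any known module;
recovery swaps the roles. Cheap, intuitive, but blind to module
multiplicity — which is exactly what the pair scores add.

Before scoring, observed modules pass through `restrict_observed`: genes
absent from the gold-standard universe are removed (they cannot be judged —
most belong to modules the gold standard does not know, and counting them
as false positives would swamp the comparison), then modules below the
minimum size are dropped. Restriction precedes the size filter.

## Permutation null and the composite

Raw scores are not comparable across gold standards: small, few, disjoint
known modules are easier to hit by chance. Each raw score is therefore
divided by its mean over permuted known module sets (default 500
permutations; the calibration tests in this repository use 100 or fewer to
keep runtimes in seconds). A permutation maps the dataset's genes through
one uniform random bijection, preserving module number, sizes and the
entire pairwise-intersection structure. The normalized score reads as a
fold improvement over chance; the four normalized scores combine by
harmonic mean (so one chance-level score drags the composite down hard, and
a zero forces 0). The permutation universe is the dataset's gene list when
an expression matrix is in play, else the known-module gene union. All
randomness flows through explicit seeded `numpy` generators; identical
seeds give bitwise-identical reports.

The sticky rewiring null for networks draws each potential directed edge
(r, t) independently with probability min(1, s_out(r)·s_in(t)), with
stickiness indices s_out(r) = outdeg(r)/√|E| and s_in(t) = indeg(t)/√|E|
computed separately for outgoing and incoming edges; degree sequences are
preserved in expectation. The probability cap at 1 is our choice (the
factorized product can exceed 1 for hubs); the factorized directed form is
a reconstruction of the undirected stickiness model.

## Enrichment scoring (aucodds family)

For gold standards given as weighted per-context regulons, direct module
comparison is replaced by regulator coverage. Per weight cutoff (default: the
deciles of the positive weight distribution, since no canonical grid
exists): each regulon is thresholded; each (regulator, context) family of
per-module right-tailed Fisher tests is Holm–Šídák-corrected (the family is
the minimal set of jointly compared tests); per (regulator, module) the
context with the minimal corrected p is kept together with its odds ratio;
per regulator the maximal odds ratio among modules with corrected p below
0.1 is retained, or 1 (the floor of the integration interval) when no
module is significant. The aucodds score integrates the fraction of
regulators with odds ratio at or above a cutoff over log₁₀ cutoffs in
[1, 1000], normalized by the interval width — computed in closed form as
the mean clipped log-odds-ratio over the interval width; odds ratios above
1000 saturate. Odds ratios use Haldane's +0.5 on all cells when any cell is
zero (never the p-value, which is the exact hypergeometric upper tail).

F-aucodds runs the same integral in both directions over a functional
gene-set collection — per gene set the best odds ratio among modules where
it is enriched, and per module the best among gene sets — and combines the
two by harmonic mean; it rewards covering *all* functions and having
*every* module enriched. Collections are first de-redundantified: iterating
from the largest set, a set is dropped when its Jaccard with a larger
retained set exceeds 0.7. The biological homogeneity index is the fraction
of annotated intra-module gene pairs sharing at least one functional class,
averaged per module and then across modules (the per-module averaging is
one of two defensible readings of the index; pooling pairs across modules
would weight large modules quadratically).

## Internal quality

Cluster validity indices run on the distance matrix d = 1 − |r| (Pearson);
the absolute value treats strong anti-correlation as proximity, matching
signed regulatory programs. They require an exhaustive partition, so
unassigned genes are first added to the module with the highest mean member
correlation and multi-module genes are resolved the same way (ties go to
the lowest-index module, deterministically). Silhouette uses the
precomputed-distance form; Davies–Bouldin is computed in a medoid
formulation (scatter = mean distance to the cluster medoid, separation =
inter-medoid distance) because centroids do not exist in a pure distance
space; Kim–Ramakrishna is realized as the sum of its under-partition term
(mean within-cluster mean distance to the medoid) and over-partition term
(cluster count over minimal inter-medoid separation), without the K-sweep
rescaling of the original formulation, which needs a whole family of
clusterings rather than a single module set — as a parameter-selection
criterion the unscaled sum ranks candidates the same way within a fixed
dataset.

Per-module co-expression is summarized three ways: mean pairwise Pearson
correlation; the mean over genes of each gene's average top-5%-of-samples
z-score (per-gene z-scoring, sd with n−1; captures extreme,
condition-specific activity — the top 5% is taken per gene because pooling
samples across the module would let one hyperactive gene dominate); and the
RMSD of gene-standardized values around the per-sample module mean (0 for
perfectly parallel profiles). The permutation test compares per-module
metric values of the real modules with those of gene-relabelled modules
(two-sided Mann–Whitney rank-sum, exact for small samples via scipy,
plus the median difference).

## Tuning harness

Training score = best permutation-normalized composite over a declared
parameter grid (cartesian product, declaration order; ties go to the first
maximizer; a detector crash at a grid point scores 0 with a warning rather
than aborting the grid). Test score = the composite on a target dataset at
the source dataset's best parameters. Transfer between synthetic and real
datasets is refused when realness tags are supplied, since optimal
parameters differ systematically between the two. Aggregation weights each
row by 1/(n_organisms · n_datasets_in_that_organism · n_definitions), so
every organism and every module definition carries equal total influence
regardless of how many datasets an organism contributes. Perturbation
utilities subsample samples without replacement and add i.i.d. Gaussian
noise for sensitivity analyses.

## Synthetic generator

The generator plants `n_regulators` regulons of `targets_per_regulator`
genes; a fraction `overlap_fraction` of each regulon is borrowed from other
regulons' own pools, creating genes with several regulatory programs. The
expression model is linear: each module gets a standard-normal activity per
sample; a `local_fraction` of modules is active only in a random
`active_sample_fraction` subset of samples (local co-expression); a gene's
value is the sum of its modules' activities plus N(0, noise_sd²) noise;
background genes (default half as many as module genes, so
universe-restriction code paths are exercised) are pure noise.

Defaults (10 regulons × 20 genes, 20% overlap, 100 samples, 20% local
modules active in 30% of samples, noise sd 0.5 — half the unit activity
scale) describe a small but structurally complete compendium: overlap,
locality and noise are all present at levels where detection is possible
but not trivial. What the linear model deliberately omits relative to real
compendia: nonlinear and combinatorial regulation, regulator saturation,
correlated (batch-like) noise, and heavy-tailed expression distributions.
Passing tests therefore demonstrate that the *evaluation machinery* behaves
correctly on data with known structure — not that any detector will perform
comparably on real data.

`degrade_modules` swaps a controlled fraction of each module's members for
random outside genes, preserving sizes; because exactly k members leave and
k non-members enter, the Jaccard with the original module is
deterministically (s − k)/(s + k), which makes it a clean instrument for
monotone-degradation checks.

## Numerical choices and degenerate inputs

- Jaccard of two empty sets is 0; Φ over an empty candidate set is 0 (it is
  multiplied by a zero min-term whenever that happens naturally).
- Harmonic means return 0 when any argument is 0 (continuous limit).
- Score computations reject empty module sets; normalization rejects a null
  mean of 0 with a pointer to a larger universe.
- Fisher p-values come from the exact hypergeometric survival function, not
  a normal approximation; sample standard deviations use n − 1 throughout.
- Duplicate modules (same genes, different names) are legal and kept
  distinct; they genuinely change the pair scores through module counts.
- Test problem sizes (100–500 genes, 20–100 permutations, 5 synthetic
  datasets in the transfer study) were chosen so the full suite runs in a
  few minutes on one CPU while every statistical assertion retains a
  comfortable margin; defaults in the library itself stay at the
  full-protocol values (500 permutations).

## Known limitations

- The interconnected definition ships with MCL only; transitivity
  clustering and affinity propagation variants of the same idea are not
  implemented.
- Only Pearson correlation backs the distance and co-expression machinery;
  alternative similarity measures are out of scope.
- No expression preprocessing beyond variance filtering (no RMA/quantile
  normalization, no platform-specific readers) — inputs are assumed
  normalized TSV matrices.
- The aucodds weight-cutoff grid (deciles) and the coupling of each
  regulator's odds ratio to its minimal-p context are documented choices
  where no canonical convention exists.
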