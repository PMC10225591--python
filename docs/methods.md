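# Methods notes

This note records the modelling assumptions, default parameters, and
design decisions behind the package, along with what the synthetic
validation does and does not demonstrate.

## Individual-specific networks

The leave-one-out interpolation `wₙ = N·w − (N−1)·w̄₋ₙ` estimates the
contribution of one sample to a population association network.  Three
properties worth keeping in mind:

* For estimators that are averages of per-sample statistics the ISNs
  average exactly to the global network; for correlation-type
  estimators the identity is approximate (`isn_average_check` reports
  the per-edge deviation).
* `wₙ` can be negative even when `w` and `w̄₋ₙ` are both positive —
  precisely when `w < (N−1)·w̄₋ₙ/N`.  The absolute-value transform is a
  separate, explicit step because it deliberately discards the sign of
  associations.
* To first order, `wₙ` equals the sample's influence statistic, which
  for correlation estimators is essentially a product of that sample's
  standardized deviations.  A single individual's ISN is therefore
  dominated by a rank-one "outer product" of their own deviation
  vector, with per-edge noise of order one regardless of N.  This is
  inherent to single-sample networks, not an implementation artifact,
  and it shapes what per-individual dynamics can and cannot detect
  (see *Synthetic cohort* below).

ISN construction uses exactly N+1 estimator calls.  The minimum
reference size is 3 (a correlation needs at least two samples).  The
bundled `fallback_estimator` (Pearson on CLR-transformed counts, or
Spearman on raw counts, with optional quantile sparsification) is a
plain correlation stand-in for testing: it models neither zero
inflation nor overdispersion and removes no indirect associations.
Dedicated compositional estimators should be supplied through the
estimator contract or the per-subset network-file convention.  The
end-to-end cohort pipeline builds ISNs from *unsparsified* correlations:
a sparsification threshold inside the leave-one-out loop makes the
interpolation formula discontinuous in single samples (an edge
hovering at the threshold flips between `N·w` and `N·w − (N−1)·w̄₋ₙ`),
which injects large spurious edge changes.

## Walk profiles and the encoder-decoder

Reach semantics: entry j of a profile is the probability that node j is
visited at least once within `walk_length` steps of a weighted random
walk (transition `w_uv / Σ w_ux`), start node excluded.  Walks that hit
a zero-degree node terminate early; their visits count.  Two
implementations exist: Monte-Carlo simulation (default; per-(layer,
node) random streams derived from one master seed, so results are
independent of evaluation order) and an exact absorbing-chain
computation (one absorbing chain per target node) used as the oracle in
tests.  Defaults: `walk_length` 5, 100 walks per start node.

The encoder-decoder is a single-hidden-layer network, K inputs →
`hidden_dim` rectifier units → K logistic outputs, trained with Adam on
mean squared error.  `hidden_dim` defaults to 10 (the least-MSE choice
in a sweep over {2, 5, 10, 15, 20}; `hidden_dim_sweep` reproduces such
a comparison).  It is implemented directly on numpy: the model is tiny,
CPU training takes seconds, and the implementation is bit-reproducible
for a given seed on one thread.

**Fitting depth matters, and the right depth depends on the question.**
The package default (learning rate 3e-3, 2000 epochs, batch 32) trains
benchmark-sized problems (a few hundred rows) to near-interpolation.
This is required for *node-level* change detection: an underfit encoder
collapses toward degree-like summary features, embeds unrelated sparse
neighborhoods in similar directions, and blurs which specific nodes
rewired.  Trained to convergence, a node whose neighbor set is replaced
wholesale moves far in embedding space while a node with identical
neighbor vectors in both layers moves exactly zero.  Conversely, for
*cohort-level* contrasts (comparing individuals by their overall
dynamics profile), a compressed regime (~100 epochs at the same
learning rate) is both an order of magnitude faster on
individuals×layers×taxa training sets and acts as a denoiser: the
bottleneck projects the noisy per-individual edge rows onto the shared
association structure.  The cohort analyses in the test suite use that
reduced schedule; both regimes are plain `EDNNConfig` settings.

Weighted inputs/targets are the default; binary mode (uniform
transitions, 0/1 neighbor vectors) is retained but empirically weaker.
No input scaling is applied.

## Dynamics, ensembles, and consensus clustering

Cosine distance is undefined for zero vectors; rectifier units can die
and produce all-zero embeddings.  Convention: both vectors zero → 0,
exactly one zero → 2 (bounded, monotone, logged via a warning).

Because the training loss is non-convex, different seeds give different
embedding spaces.  `ensemble_dynamics` retrains per seed (default 50
repeats) and averages distances; walk profiles are computed once and
shared, since the ensemble targets training variability, not
Monte-Carlo error.

Consensus clustering has two modes.  For taxa, the items are the
(node, layer) points of each repeat's embedding space; each repeat is
partitioned by k-means (k by silhouette over 2–6) and the consensus
matrix is the co-clustering frequency across repeats, cut by
average-linkage hierarchical clustering.  For individuals, the input is
a single dynamics matrix and the ensemble comes from item subsampling
(80%, 50 repeats): for each candidate k a consensus matrix is built
from subsampled k-means runs and k is chosen by the proportion of
ambiguous co-clustering (PAC, entries in (0.1, 0.9)), taking the
smallest k within 0.02 of the minimum.  Individual dynamics profiles
are strongly right-skewed — a few individuals reorganize a lot — so
`cluster_individuals` rank-normalizes each feature first; without this,
Euclidean k-means splits the long tail instead of the groups.

"Extreme dynamics" detection sorts the per-node scores and finds the
largest consecutive gap within the top and bottom q-fraction (default
q = 0.25); ties break toward smaller flagged sets and a zero gap flags
nothing.

## Phenotype prediction

Leave-one-out cross-validation with, inside each training fold only:
undersampling of the majority class, greedy forward feature selection
by inner stratified-CV AUC (default 5 folds, cap 10 features), and an
RBF-kernel SVM with standard hyperparameters on the selected,
standardized features.  The left-out individual's decision score is
pooled across folds into one ROC/AUC per repeat (one sample per fold
precludes per-fold curves); selection counts accumulate across folds
and repeats and rank discriminative taxa.

Two choices are worth flagging.  First, undersampling targets a *fixed*
per-class size (the full-data minority count minus one) so every fold
trains on the identical class composition; letting the balance drift
with the left-out sample's class biases pooled null AUCs well below
0.5.  Even so, pooled-LOOCV AUC under permuted labels has a mild
pessimistic bias and substantial per-permutation variance, so
chance-level checks should average several permutations.  Second, the
selection loop scores candidate subsets with a closed-form
ridge-regularized linear discriminant rather than refitting the kernel
SVM thousands of times per fold; the SVM is fit once per fold on the
selected features.  This keeps the selection criterion (inner-CV AUC)
while making the full protocol run in seconds.

`compare_clusterings` uses the chi-square statistic on the contingency
table (no continuity correction) with a permutation p-value
`(1 + #{χ²_perm ≥ χ²_obs}) / (1 + n_perm)`; marginals are
permutation-invariant, so the expected table is computed once.

## Phylum aggregation, difference networks, filtration curves

Phylum-level edge aggregation divides the inter-phylum edge count (or
weight sum) by `n₁·n₂` and a phylum's own edges by `n(n−1)/2`, so
binary-mode values are occupancy fractions in [0, 1].  Difference
networks average the group's ISNs per layer, subtract earlier from
later, and restrict to seed taxa plus their distance-1 neighbors in
either averaged layer; they are antisymmetric under swapping the layer
order.  Filtration curves evaluate a descriptor (edge count, total
absolute weight, or connected components including isolates) on the
subgraph with |weight| ≥ t at every observed threshold; the edge-count
curve is non-increasing by construction.  The node-label-histogram
descriptors from the graph-filtration literature are out of scope.

## Planted benchmark

`make_benchmark_multiplex` draws degrees as 2 + Poisson(mean−2)
(default mean 4) — every node keeps at least two partners, since a
neighborhood change is ill-defined for isolated or pendant nodes — and
realizes them with a configuration model (parallel edges and self-loops
removed, so realized degrees can dip slightly).  Weights are
|N(0.3, 0.15)| truncated to (0, 1].  The second layer deletes every
edge incident to the m control nodes (default 10 of 95) and redraws,
per control, the same number of edges to uniformly chosen non-control
partners disjoint from the old ones, with fresh weights.  Controls
therefore keep their degree but replace their entire neighbor set;
non-controls change only where a control edge touched them.  With mean
degree 4, each control touches ~8 other nodes, so a substantial
minority of non-controls sees a one-edge change — detection must
separate wholesale replacement from such single-edge perturbations,
which the converged encoder does.

Uniform noise Uniform(0, max), max ∈ {e⁻¹⁰, …, e⁻²}, is added to every
off-diagonal adjacency entry (zeros included — the operation acts on
the adjacency matrix and densifies the graph), mirrored for symmetry.

The comparison baseline represents each layer's nodes by their rows in
the matrix of the 10 smallest non-trivial eigenvectors of the
combinatorial Laplacian L = D − W (null-space vectors skipped, one per
connected component; 10 matches the embedding dimension for fairness),
aligns eigenvector signs across layers by correlation, and scores nodes
by cosine distance.  On the default benchmark it recovers roughly a
fifth of the planted nodes; the exact value depends on generator
details that are only loosely constrained, which is why the validation
accepts a broad band around it.

## Synthetic cohort

The cohort generator produces two-time-point counts for n individuals
(default 60) over K taxa (default 40) from a latent Gaussian copula
with zero-inflated negative-binomial marginals (quantile transform of
the copula uniforms, so the count map is monotone given the latent
state).  Three structural choices came out of tracing how a planted
effect survives the CLR → correlation → leave-one-out → |·| → cosine
chain:

* **Guild factors are zero-sum contrasts.**  Taxa form guilds of 5
  driven by one latent factor each, half the guild loading positively
  and half negatively.  A *common* (all-positive) block factor is
  largely absorbed by the CLR's geometric-mean subtraction —
  development measurements showed equicorrelated blocks of 20 taxa
  losing ~90% of their correlation after CLR — whereas a zero-sum
  contrast is orthogonal to the row mean and survives compositional
  closure.  `rho` (default 0.95) is the factor's variance share, i.e.
  the |latent correlation| between guild mates.
* **Coupling runs through temporal persistence.**  Both latent factors
  and idiosyncratic levels carry over between time points with
  autocorrelation `stability` (default 0.995).  Subgroup 1 keeps a
  nearly frozen co-occurrence pattern; subgroup 2's rewired taxa
  (default 32 of 40) move to a different guild with fresh idiosyncratic
  levels at the second time point.  A purely cross-sectional rewiring
  (different correlation structure, independent draws at both times) is
  essentially invisible to per-individual dynamics, because the
  rank-one structure of single-sample ISNs makes every individual's
  network change look alike; persistence-versus-reorganization is the
  contrast the measure actually detects — the same contrast as
  persistent versus changing diet in infant cohorts.
* **Sparsity comes from sampling zeros, not a structural-zero cliff.**
  The `zero_inflation` knob is implemented (uniforms below π map to
  zero) and tested, but defaults to 0: a structural zero in an abundant
  taxon jumps the CLR by ~6 log-units and those outliers dominate the
  correlation fallback's leave-one-out influence — the very pathology
  that motivates zero-inflation-aware estimators, which this package
  deliberately does not reimplement.  With the defaults, zeros arise
  rank-consistently from the negative-binomial sampling of rare taxa
  (lognormal abundance profile, depths 20–30k).

The defaults constitute a deliberately *strong-coupling validation
regime*: they verify that the pipeline recovers a planted
individual-level contrast when one clearly exists (subgroup clustering
and prediction both succeed across development seeds), and that it
stays at chance under permuted labels and near zero under no rewiring.
Passing these tests says the machinery is correct; it does not say the
method attains such accuracy on real cohorts, where effects are weaker,
zeros are structural, estimators differ, and phenotype labels are
noisy.  The generator also does not emulate taxonomic correlation of
effects, varying sequencing protocols, or more than two time points.

## Degenerate inputs and numerical conventions

Symmetry checks use relative tolerance 1e-8 (asymmetric inputs are
averaged only under an explicit flag); diagonals must be zero.  CLR
uses pseudocount 0.5 by default (half-count convention) and refuses
zeros at pseudocount 0.  Prevalence filtering is strictly greater than
the threshold ("exceeding"), computed on whatever sample set is passed
in; appearing/disappearing classification uses the single time point's
samples against the merged set.  Constant taxa yield zero association
with a warning.  Quantile sparsification zeroes entries at or below the
threshold, so at most a (1−q) fraction survives.  Top-m detection and
discriminator ranking break ties lexicographically by node ID.  All
derived seeds stay below 2³¹ and come from `numpy.random.SeedSequence`
entropy lists, so per-component streams are order-independent.
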