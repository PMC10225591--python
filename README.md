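# mnda — multiplex network differential analysis of microbial co-occurrence

Longitudinal microbiome studies usually compare taxon *abundances* over
time.  This package targets the complementary question: how does each
taxon's local *co-occurrence neighborhood* change between two time
points or conditions — per individual — and what can those neighborhood
dynamics tell us about phenotypes?  It is aimed at microbiome
researchers with a sample-by-taxon count table, per-sample metadata
(individual, time point, phenotype), and a global association network
from any inference tool.

## The method

1. **Individual-specific networks (ISNs).**  Given an association
   estimator fitted on all N reference samples (edge weights `w`) and on
   the leave-one-out subset without individual n (`w̄₋ₙ`), the nth ISN
   edge is the linear interpolation

       wₙ = N·w − (N−1)·w̄₋ₙ

   so that the global network is (exactly, for estimators linear in
   per-sample contributions) the average of the ISNs.  Edge weights are
   then replaced by their absolute values, since only association
   strength is of interest downstream.  Real analyses should feed
   networks from a dedicated compositional estimator (MAGMA, SparCC,
   …) via the pluggable estimator contract or the `from-dir` file
   convention; a CLR+Pearson / Spearman fallback is bundled for tests
   and demos only.

2. **Multiplex embedding.**  Each individual's per-time-point ISNs are
   stacked into a multiplex network.  For every node of every layer of
   every multiplex, a shallow encoder-decoder maps the node's
   direct-neighbor vector (length K, no self-loop) to its
   random-walk *reach profile* — the probability that each other taxon
   is visited at least once by a fixed-length weighted random walk.
   The single hidden layer (10 rectifier units; logistic outputs; MSE
   loss) is the embedding, one joint space for all individuals and
   layers.

3. **Neighborhood dynamics.**  A taxon's dynamic is the cosine distance

       d_cos(A, B) = 1 − A·B / (|A||B|)   ∈ [0, 2]

   between its two layer embeddings.  Unchanged neighborhoods give
   identical neighbor vectors, hence distance exactly 0.  Because
   training is non-convex, ensembles over seeds provide robust ranks,
   consensus clusterings of taxa and individuals, and per-individual
   dynamics feature matrices for phenotype prediction (RBF-SVM,
   leave-one-out CV, in-fold undersampling and forward feature
   selection).

Validation is simulation-based: a planted benchmark rewires m "control"
nodes between two layers and scores detection by the Jaccard index
against the planted set, with a Laplacian-eigenvector baseline and a
uniform-noise robustness sweep; a synthetic two-time-point cohort with
subgroup-specific rewiring drives end-to-end clustering/prediction
tests.  See `docs/methods.md` for modelling details and limitations.

## Worked example

Recover planted rewired nodes on the benchmark (95 taxa, mean degree 4,
10 rewired controls, noise-free):

```python
from mnda import (SimulationSpec, make_benchmark_multiplex, run_mnda,
                  detect_topm, jaccard, laplacian_baseline)

mpx, controls = make_benchmark_multiplex(SimulationSpec(), seed=1)
result = run_mnda([mpx], seed=1)
print("final reconstruction MSE:", round(result.embeddings.final_loss, 5))
detected = detect_topm(result.dynamics, 10)
print("planted :", sorted(controls))
print("detected:", sorted(detected))
print("Jaccard (embedding):", jaccard(detected, controls))
baseline = detect_topm(laplacian_baseline(mpx)["distance"], 10)
print("Jaccard (Laplacian baseline):", round(jaccard(baseline, controls), 3))
```

prints

```
final reconstruction MSE: 0.00101
planted : ['n002', 'n018', 'n020', 'n048', 'n060', 'n064', 'n075', 'n079', 'n085', 'n093']
detected: ['n002', 'n018', 'n020', 'n048', 'n060', 'n064', 'n075', 'n079', 'n085', 'n093']
Jaccard (embedding): 1.0
Jaccard (Laplacian baseline): 0.333
```

The embedding-based ranking finds all ten rewired taxa (Jaccard 1.0):
their neighbor vectors change wholesale between the layers, so their
embeddings drift while untouched taxa stay at distance 0.  The
eigenvector baseline recovers only a third of them.

The same pipeline runs from the shell: `mnda isn`, `mnda embed`,
`mnda dynamics`, `mnda cluster-taxa`, `mnda cluster-individuals`,
`mnda predict`, `mnda aggregate-phyla`, `mnda diff-network`,
`mnda filtration`, `mnda simulate` (see `mnda --help`); every
subcommand stamps a `run_manifest.json` with its effective
configuration and seed.

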