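# Methods

## The model

`nnembed` compresses directed binary neuronal connectivity networks with a
symmetric, linearly tapered autoencoder ("neural network embedding", NNE).
Each node's row of outgoing connections is one sample: a network of `n`
neurons contributes `n` binary vectors of length `n`, and samples from all
training networks are pooled.  The architecture is fixed by two integers —
*Depth* (number of encoder weight layers from input to the narrowest
layer) and *Middle Size* (units in that layer).  Unit counts at encoder
step `d` of `D` are `round(n + (m − n)·d/D)` with round-half-to-even; the
decoder mirrors the encoder without duplicating the middle, so the
operating point `(Depth, Middle Size) = (3, 13)` on 100-node networks has
level widths `[100, 71, 42, 13, 42, 71, 100]` and `2·Depth` weight layers
in total.  Hidden layers are ReLU, the output layer sigmoid; output
probabilities thresholded at 0.5 (the boundary value counts as an edge)
give the reconstructed binary network.  The *features* are the
middle-layer activations: at `(3, 13)` on 100-node input, 13 vectors of
100 components per network.  They are nonnegative by construction (ReLU).

Training minimises the mean binary cross-entropy
`−(1/N) Σ [y·log p + (1−y)·log(1−p)]`, with probabilities clipped at
`1e-7`, using Adam at Keras-default hyperparameters (learning rate 1e-3,
β₁ = 0.9, β₂ = 0.999, ε = 1e-7), mini-batches of 32, and early stopping:
when the monitored loss has not improved for 50 consecutive epochs
(`patience`), training stops and the best-epoch weights are restored.
The monitor is the validation loss by default (the validation networks
exist precisely for early-stopping evaluation) and is configurable to the
training loss.  The optimiser, backpropagation and initialisation
(Glorot uniform) are implemented directly in NumPy: the model is small
enough that this is fast (seconds per fit at the study scale), and it
makes training bit-for-bit reproducible for a given seed on a fixed
BLAS — a property the test suite asserts.

`max_epochs` defaults to 2000 as a safety net; at the scales used in the
tests and the acceptance script it is set to 400, which early stopping
never reaches under the default conditions.

## Data conventions

Networks are square {0,1} adjacency matrices, `A[i, j] = 1` meaning a
directed link from neuron `i` to neuron `j`.  Self-connections are
forbidden; a nonzero diagonal on input is zeroed with a logged warning
(transfer-entropy pipelines exclude self-interaction, and nothing
downstream is defined for it).  Neurons with neither inputs nor outputs
are effectively isolated in the slice and are pruned (recorded, so
results map back to original labels).  When per-node annotations are
available, neurons are ordered by the scalar index
`(cell_category − 0.5) × layer_category` (cell category 0 = inhibitory,
1 = excitatory; layer category 1–4 for cortical layers 1–3, 4, 5, 6),
giving every matrix the same positional semantics.

Cross-validation partitions a collection of `N` networks into `k` equal
test folds; within each fold's training remainder, a seeded uniform draw
designates the validation (early-stopping) networks — with 15 networks
and 5 folds: 3 test, 3 validation, 9 pure training.

## Synthetic networks

The generator stands in for the unreleased effective (transfer-entropy)
networks and defines the conditions under which the package is tested.

**Microconnectome-like networks** use a directed Chung–Lu-style model:
node `i` carries a Zipf propensity `w_i = (i+1)^(−1/(γ−1))` applied to
both its out- and in-connections, and edge `(i, j)` occurs with
probability `min(1, c·w_i·w_j)`, with `c` calibrated by bisection to the
target density.  Defaults: 100 nodes, density 0.1 (a typical order for
effective microcircuit networks), tail exponent γ = 2.2 (near scale-free,
as reported for local neuronal circuits), reciprocity 0.3 (cortical
microcircuits show reciprocity well above chance).  Reciprocity is
adjusted to the target by converting unreciprocated edges into mutual
pairs (or breaking surplus mutual pairs), conserving the edge count;
isolated nodes are reattached with a single edge.  Tying the propensity
to node *index* mirrors the deterministic neuron ordering applied to the
real datasets: independently generated networks share positional hub
structure, which is what makes cross-network training and held-out
reconstruction meaningful.  What the generator does **not** emulate:
spatial geometry and distance-dependent connectivity, cell-type-specific
motifs, community structure beyond what heavy tails induce, and
measurement noise of transfer-entropy estimation.  Passing tests
therefore demonstrate the pipeline's correctness and its behaviour on
heavy-tailed directed networks, not biological conclusions about cortex.

**Barabási–Albert controls** use the standard preferential-attachment
construction.  The study's controls were 1,000 nodes at ~40% density; at
desk scale the tests use 100 nodes with attachment 26, which reproduces
the ~40% density (`m(n−m)` undirected edges).  BA graphs are undirected;
the default conversion sets both directions (symmetric adjacency), with
random single-orientation as an option.  With fixed `(n, m)` the BA edge
count is deterministic; no density jitter is added.

**Edge swapping** relocates `round(f·E)` edges (round half away from
zero) onto off-diagonal cells that are empty after the removal — vacated
cells are eligible, which keeps a 100% swap feasible for rows denser than
half.  Degree-preserving mode relocates strictly within each source row,
leaving the out-degree sequence (histogram and per-node values) exactly
invariant; non-preserving mode draws destinations uniformly from all
empty off-diagonal cells, conserving only the total edge count.  Both
modes never create self-loops or duplicate edges.

## Metrics

Fifteen per-node metrics in three categories (7 centrality /
3 noncentrality / 5 new).  Conventions where the definitions leave room:

- Betweenness, closeness and PageRank are computed on the directed graph
  (betweenness unnormalised, so a path's middle node scores 1);
  subgraph centrality is the diagonal of the matrix exponential of the
  (directed) adjacency; core number and the clustering coefficient
  `2e/(k(k−1))` (0 when `k < 2`) use the undirected projection, which is
  the form the printed formula assumes.
- Local efficiency is implemented as stated: the nodal mean of inverse
  shortest-path lengths to all other nodes (unreachable pairs contribute
  0).  This is what is often called nodal efficiency; the
  neighbourhood-subgraph variant is deliberately not substituted.
- The participation coefficient `1 − Σ_s (k_is/k_i)²` uses seeded Louvain
  communities of the symmetrised graph and undirected degrees.
- Hubs are the `floor(0.2·n)` top-degree nodes (minimum one), out-degree
  by default (configurable to in/total), ties at the cutoff broken by
  ascending node index with a warning.
- The new metrics use exact directed forward shortest-path distance
  ("N steps apart" means exactly N, not ≤ N); the backward variant is a
  flag, and the transposed analysis probes it automatically.  Degenerate
  cases resolve to 0 (empty shells, zero mean neighbour degree, nodes
  with no out-neighbours), always with a warning, so metric tables are
  finite by construction.

## Interpretation

Mutual information between each feature (one middle-layer unit across
nodes) and each metric is estimated with the Kraskov-style kNN estimator
for continuous pairs (k = 3, tiny seeded jitter for ties; negative
estimates clipped at 0).  Significance uses a permutation test (100
shuffles of the metric vector) with the add-one p-value
`(1 + #{MI_perm ≥ MI_obs})/(1 + n_perm)`, then Benjamini–Hochberg over
the pooled feature × metric family (per-metric families are an option).
Note the resolution limit: with 100 permutations the smallest possible
p is 1/101, so pooled BH over 13 × 15 tests cannot produce q ≤ 0.05
unless ~40 pairs are simultaneously at the minimum; q-values near 0.19
for maximally significant pairs are an artifact of this granularity, not
evidence of independence.

Raw MI mainly reflects what all features share, so values are min-max
normalised per metric across features (constant columns flagged and set
to 0); each feature is then assigned the argmax metric (ties broken
toward the earlier catalogue position, logged).  The headline category
proportions are counts over all (feature, network) assignments,
normalised to 1.  This aggregation rule is explicit because fractions
finer than 1/13 imply pooling beyond a single feature set; a
normalised-MI-weighted variant would be a straightforward extension.

## Robustness and baseline

A trained model is evaluated on swap ladders 0–100% in steps of 10%.
TP accuracy (`100·TP/(TP+FN)`, recall of presented edges) and BCE loss
are measured against the swapped input itself — the model is asked to
reconstruct what it is shown; comparing against the original unswapped
matrix is available via a flag since either reading of "error on swapped
data" is defensible.  Curves aggregate means and standard deviations
across networks × replicates.  The mode comparison reports per-fraction
deltas and a trapezoidal area-under-curve gap, positive when the
non-preserving mode degrades faster.

The PCA baseline fits principal components on the pooled mean-centred
rows of all networks, back-projects at a matched component count, clips
to [0, 1] and thresholds at 0.5.  Zero components reduce to thresholded
column means (the per-cell majority class); full rank reconstructs
exactly.  The NNE-vs-PCA comparison is a paired per-network accuracy
difference without a default hypothesis test (the Welch machinery used
for the middle-size table is available).  On the synthetic networks used
here the two methods are close — the heavy-tailed positional structure
is substantially linear — so the comparison is reported as a paired
delta rather than asserted as a superiority claim.

## Model selection

The middle-size table compares per-network accuracies of each middle
size against the reference size 1 with Welch's unequal-variance t-test,
corrected by Benjamini–Hochberg or Bonferroni, flagged `*`/`**`/`***` at
0.1/0.05/0.01.  The default survey grid is depths 3–11 and middle sizes
1–29 in steps of 2.

## Problem sizes

Tests and the acceptance script run the full pipeline at the study's
network size (100 nodes, 14 networks, architecture (3, 13)) but use the
100-node BA controls described above, 1–5 replicates per swap fraction,
and 200-trial calibration runs; the full 5-fold survey over the complete
grid is exposed through `grid_survey`/`nne survey` rather than executed
in the test suite.

## Known limitations

- Determinism is per-backend: bit-for-bit reproducibility holds for a
  fixed NumPy/BLAS build.
- The kNN MI estimator is biased at small samples; with 100 nodes per
  network, MI values are comparable across pairs (which is all the
  normalisation needs) but not unbiased absolute quantities.
- Louvain communities are stochastic up to the seed; participation
  coefficients can shift between seeds on networks with weak community
  structure.
- The generator's positional hub structure is a modelling choice; on
  data without cross-network node correspondence, held-out
  reconstruction above the majority baseline should not be expected.
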