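# Methods

This note documents the model, the numerical choices, and what the
synthetic benchmarks do and do not establish.

## Model and assumptions

The predictor treats miRNA–disease association as bipartite link
prediction with side information. Its core assumption is *guilt by
association*: functionally similar miRNAs tend to associate with
semantically similar diseases, so the similarity structure of each side
of the network is informative about unobserved links.

Four similarity views enter the model:

1. **miRNA functional similarity (FS)** is an input, not computed here:
   the package loads a labelled, symmetric matrix in [0, 1]. Loaders
   validate symmetry (tolerance 1e-10, then exact symmetrisation by
   averaging with the transpose) and range, and never impute missing
   entities.
2. **Disease semantic similarity (SS)** is computed from ontology
   annotations. The contribution of an ancestor term decays by a factor
   of 0.5 per generation, taking the **max** over paths (a diamond does
   not double-count) and, for diseases annotated to several ontology
   positions, the max over annotations with the ancestor set being the
   union. The pairwise score normalises the shared-ancestor
   contribution mass by the two semantic values, so it is 1 on the
   diagonal and 0 for disjoint ancestries.
3. **GIP kernels (GS_m, GS_d)** adapt a radial-basis kernel to network
   density: the bandwidth is λ′ divided by the mean squared profile
   norm, with λ′ = 1. miRNA profiles are rows of the adjacency matrix
   and disease profiles are columns. An all-zero side of the network
   leaves the bandwidth undefined and is rejected with an explicit
   error rather than silently regularised.

## Negative sampling

Unobserved pairs are unverified, not confirmed negatives. To avoid
concentrating the negative class near a few hub entities, the
zero-pairs are clustered (k-means, squared Euclidean, k-means++
seeding, 10 restarts, 300-iteration cap, seeded) over per-pair feature
rows `[FS row of the miRNA ‖ SS row of the disease]`, and negatives are
drawn per cluster with quotas as equal as possible: `floor(n/k)` each,
remainder assigned to the largest clusters, deficits of undersized
clusters redistributed (with a warning). The default is 23 clusters and
one negative per positive. Because the requested total is generally not
divisible by the cluster count, exact per-cluster equality is
impossible; floor-plus-remainder is the closest feasible reading.

## High-order features

One stacked autoencoder per view is trained on that view's similarity
rows — entity-level inputs, so a 100-miRNA network gives 100 training
vectors of width 100. Training is greedy: layer i + 1 reconstructs
layer i's codes. Choices:

* hidden widths 256 → 128 → 64 (the last width is the code size);
* sigmoid on encoder and decoder — inputs are similarities in [0, 1];
* untied encoder/decoder weights;
* objective `½Σ_k‖x_k − y_k‖² + λ‖θ‖²` with λ = 1e-4 on weights and
  biases;
* full-batch gradient descent on the per-sample mean of the objective,
  learning rate 0.1, 500 epochs per layer — deterministic given the
  seed, and the per-layer loss trajectory is recorded so monotone
  decrease is testable;
* Glorot-uniform initialisation `±(6/(fan_in + fan_out))^{1/2}`, biases
  zero, seeded.

The optimiser settings are deliberately simple (no momentum, no
mini-batching); at the entity counts this package targets the full
batch fits comfortably in memory and keeps runs bit-reproducible.

Feature extraction is **transductive** by default: encoders see all
similarity rows, which carry no pair labels directly but do include the
full adjacency through the GIP kernels. A `strict` mode recomputes the
GIP kernels from the training-fold adjacency (held-out positives
zeroed) and retrains the encoders inside every fold; it is slower by a
factor of the fold count and is the mode to report when leakage through
the kernels matters.

## Cross features and the ensemble

Per pair, each miRNA-side code is concatenated with each disease-side
code: D1 = [fs‖ss], D2 = [gs_m‖ss], D3 = [fs‖gs_d], D4 = [gs_m‖gs_d];
with 64-d codes each block is 128-d. No projection back to 64-d is
applied — concatenation keeps the two views' coordinates intact for the
forests.

Each block trains a random forest (300 trees, √d feature subsampling,
bootstrap, min leaf 1). The meta-learner is a logistic regression over
the four base probabilities. Its training meta-features are
**out-of-fold**: 5 internal stratified folds, each forest scoring the
fold it did not see, after which the forests are refit on the full
training set. A `naive` mode (in-sample meta-features) exists for
comparison; it inflates the meta-learner's trust in the forests and is
not the default. The final score is `σ(wᵀp + b)` — the logistic link,
so scores are probabilities in [0, 1].

## Evaluation

Stratified k-fold cross-validation (default 5), per-fold AUC (midrank
tie handling), AUPR (step-wise precision–recall integration),
precision, recall and F1 at a 0.5 threshold (configurable; zero
denominators report 0 with a flag). The ablation harness runs each
cross feature through a single forest and the full stack under an
identical fold partition, verifiable by a fold-assignment hash.
Stratification departs from plain random splitting only to prevent
degenerate folds at small sample counts.

## The synthetic benchmark

`simulate_block_network` plants a block structure: miRNAs and diseases
are assigned to 5 blocks (defaults 100 × 80 entities), associations are
Bernoulli with p_in = 0.30 within blocks and p_out = 0.02 across.
Surrogate FS/SS matrices score same-block pairs around 0.8 and
cross-block pairs around 0.1 with Gaussian jitter (s.d. 0.1), clamped to
[0, 1] — similarity structure aligned with association structure, which
is exactly the premise the predictor relies on. An uninformative mode
shuffles the block labels behind the similarities, giving a negative
control in which only the GIP views carry signal. A toy ontology
generator (random forest of term trees, diseases annotated at the
deepest tier) exercises the semantic-similarity path, including the
hand-checkable chain arithmetic.

**What passing these benchmarks shows** — the pipeline recovers planted
similarity-aligned association structure, ranks within-block candidates
above cross-block ones, collapses to chance under label permutation,
and integration of the four views does not lose to the best single
view. **What it does not show** — performance on real association
networks, whose degree distributions are heavy-tailed, whose similarity
matrices have richer-than-block structure, and whose negatives are
unverifiable; the generator makes no attempt to emulate those.

A property of the generator worth knowing when reading benchmark
numbers: with p_in = 0.30, a sizeable minority of sampled negatives lie
*within* blocks, and for those pairs the label is a coin flip that no
similarity-derived feature can call. A scorer with oracle access to the
planted blocks and degrees tops out near AUC 0.82 at the default
settings, and the full pipeline lands essentially at that ceiling
(≈ 0.815 at the seeds used in the tests); numbers in the high 0.8s are
not attainable under these conditions and should not be expected.

## Numerical and degenerate-input choices

* Similarity matrices are exactly symmetrised by `(M + Mᵀ)/2` after
  construction; asymmetry beyond 1e-10 on load is an error, not a fix.
* Kernel diagonal is set to exactly 1.
* Ranking breaks score ties by miRNA identifier for reproducibility.
* Duplicate association pairs warn and count once; unknown identifiers
  are errors naming the offender.
* Every random draw flows from a single top-level seed through
  `numpy.random.default_rng`; derived seeds stay below 2³¹.
* Cluster quotas: see negative sampling above; `k` larger than the
  number of distinct zero-pair feature rows is an error.

## Known limitations

* The MISIM functional-similarity algorithm is out of scope; FS must be
  supplied (or simulated).
* Transductive defaults overstate fold independence when the GIP views
  dominate; use `strict` mode for leakage-sensitive comparisons.
* The meta-learner sees only four base probabilities; no interaction
  terms between forests are modelled.
* Desk-scale problem sizes are used throughout the test-suite
  benchmarks (networks of 30–100 miRNAs); the code paths are identical
  at database scale but the reported numbers are not comparable to
  full-database results.
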