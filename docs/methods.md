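# Methods

## Model and assumptions

The package treats DTI prediction as binary classification of concatenated
drug+target descriptor vectors. Its working assumptions are those of
feature-based chemogenomics: (i) descriptor similarity is informative —
similar drugs tend to hit similar targets; (ii) approved interactions are
trustworthy positives; (iii) unannotated pairs are a mixture of true
negatives and undiscovered positives, so they may not be used as negatives
indiscriminately. Both sampling stages exist to extract, from the
unannotated mass, a negative class that is (a) small enough to train on and
(b) unlikely to be contaminated with undiscovered positives near the decision
boundary.

### Stage 1: shared nearest neighbours and medoid representatives

`SNN_k(x, y) = |NN_k(x) ∩ NN_k(y)|` with exact L2 neighbour lists, self
excluded, distance ties broken by ascending entity index for determinism.
The *pool* of an entity is the set of shared-neighbour objects — every
member of its own list that also appears in at least one other entity's
list. Pools seeded by an approved pair are summarised by k-medoids (PAM:
greedy BUILD initialisation, then alternating assignment/update, all ties
to the lowest index, hence deterministic without a random state), and the
cartesian product of the medoid entities forms the candidate negatives.

Cluster-count selection uses the Calinski–Harabasz index with two guards
that matter on small pools:

* candidate counts are restricted to 2 ≤ k ≤ n/2 — for k approaching n the
  within-cluster dispersion rests on fewer degrees of freedom than there
  are clusters and the pseudo-F spikes on singleton clusters;
* the best partition is accepted only if its CH value is at least 5.
  CH behaves like an F statistic and hovers near 1 on a structureless
  (unimodal) pool for every k, with a noisy argmax that otherwise drifts
  toward the largest k and would return nearly every pool member as a
  representative. Below the evidence bar the pool is treated as one
  cluster and its single overall medoid returned — which is also the
  fallback when the index is undefined everywhere (coincident points).

With these guards the sampler reduces the desk-scale fixture's search space
by a factor of ~50–80 while candidates remain near known interactions.

### Stage 2: fuzzy-rough scoring

Per-feature similarity variants (all symmetric, reflexive, in [0, 1]):
linear/tolerance `1 − |Δ| / range`, Gaussian `exp(−Δ²/2σ²)`, triangular
`max(0, 1 − |Δ|/σ)`, where range and σ are per-feature statistics of the
matrix being scored. A feature with zero range/variance distinguishes
nothing and yields degree 1. Aggregation over features uses the Łukasiewicz
t-norm by default (the n-ary form telescopes to
`max(0, Σ R_f − (|C| − 1))`, which is how it is vectorised) with minimum as
the alternative. Approximations use the Łukasiewicz t-norm/implicator pair
with a crisp decision attribute, so the upper approximation reduces to the
maximum relation degree over concept members (asserted equal to the literal
sup/T form in tests) and the lower approximation to the minimum of
`1 − R` over non-members.

Group-averaged scoring shuffles positives into m and candidates into n
contiguous groups (seeded), scores each candidate once per positive group,
and averages. Group size defaults to 500, bounding each table at
O(1000²·|C|) similarity evaluations; m = n = 1 reproduces the single-table
score bit-for-bit.

**Dimensionality.** The Łukasiewicz aggregation subtracts the *sum* of
per-feature dissimilarities, so over hundreds of raw pair features almost
every degree clamps to 0 and the score carries no ranking information.
Pair vectors are therefore compressed with incremental PCA before scoring;
the pipeline default is 10 components, which preserves the cluster geometry
the relation needs while keeping degrees spread over (0, 1). The standalone
`reduce_dimensions` operation defaults to min(100, n_features) for general
use; the mini-batch (incremental) formulation is used so the projection
scales to arbitrarily many pairs.

### Thresholds, promotion and balancing

Candidates with FRUA ≥ t_p (default 0.95) are promoted to the positive
class; candidates with FRUA ≤ t_q are kept as negatives; both comparisons
inclusive. When t_q is not given the pipeline sets it adaptively to the
score quantile that keeps approximately as many negatives as positives —
the regime where under-sampling alone balances the classes and no
oversampling is needed. Classes are considered balanced when
minority/majority ≥ 0.9; otherwise ADASYN generates synthetic minority
samples by interpolating towards minority neighbours, apportioned by the
fraction of majority points among each minority point's k = 5 neighbours
(largest-remainder rounding so the deficit is filled exactly); a minority
class smaller than k + 1 falls back to random duplication. Original rows
are never removed and synthetic rows are provenance-tagged.

### Classifiers and evaluation

Defaults follow grid-search optima for this task: decision tree (gini,
depth 9, min split 6), random forest (gini, depth 20, min leaf 3, min
split 8, 200 trees), SVM (RBF, C = 10, γ = 0.1), RUSBoost (500 stumps,
learning rate 1.0); tree learners use √n_features per split. RUSBoost is
implemented here directly: each boosting round randomly under-samples the
majority class to the minority size (draws weighted by the boosting
weights), fits a stump, and performs AdaBoost-style weight updates on the
full set. RBF-SVM has no native probabilities, so its signed decision
scores feed the AUC (recorded in the report metadata). Evaluation is
stratified 5-fold CV or a stratified 70:30 holdout; per-fold confusion
counts are kept in the report so every derived metric (G-mean in
particular) can be recomputed independently. Feature selection averages
per-learner sum-normalised importance vectors of XGBoost and random forest
over balanced positive/negative group pairs and keeps the top-k (ties by
ascending index).

## Synthetic fixture

The generator plants the structure the method exploits: drug and target
cluster centres drawn uniformly in the unit hypercube, entities scattered
around them (Gaussian, sd = `cluster_spread`), each drug cluster compatible
with one target cluster, approved pairs drawn within compatible blocks at
`interaction_density`, plus a `noise_interactions` fraction of off-block
approved pairs. A Bernoulli per-cluster-profile mode emulates binary
fingerprints. Defaults: 60 drugs × 40 targets, dims 30/40, 3 × 2 clusters,
spread 0.1, density 0.3, noise 0.05. The noise pairs matter: they seed
off-block candidate negatives, mirroring the annotation promiscuity of real
interaction data — without them stage 1 could only propose pairs inside
compatible blocks.

What the fixture does *not* emulate: realistic descriptor distributions
(real descriptors are heavy-tailed, collinear and block-correlated),
target family hierarchies, assay biases, or the extreme scale of real pair
spaces (millions of unannotated pairs). Passing tests therefore demonstrate
that the machinery is correct and that the sampling mechanism behaves as
designed on clusterable data; they are not evidence about performance on
any particular real descriptor set.

## Numerical choices

* All fuzzy degrees are clipped to [0, 1] after arithmetic to absorb
  rounding at the boundaries.
* Min-max normalization maps constant features to 0 (no information, and
  avoids 0/0); it is fitted on the full matrix before any splitting and is
  idempotent on its own output.
* PCA is fitted on the assembled pair vectors (positives + candidates)
  rather than on drugs and targets separately, so the similarity relation
  and the classifier see the same reduced space.
* knn/medoid/grouping tie-breaks all resolve to the lowest index; every
  stochastic step (grouping shuffle, ADASYN, CV shuffling, classifiers)
  takes an explicit seed, and the pipeline derives per-stage seeds from one
  master seed via a seed sequence, so identical inputs and seed give
  identical outputs end to end.
* Problem sizes in the test-suite and acceptance runs (60 × 40 fixture,
  five seeds, 30-object oracle tables, 240 × 20 feature-recovery data)
  were chosen to exercise every stage at desk scale in seconds.

## Known limitations

* FRUA scores depend on the PCA dimension through the Łukasiewicz clamp;
  very different component counts require rethinking thresholds.
* The adaptive t_q targets class balance rather than a fixed degree; when
  candidates are fewer than positives it degenerates to "keep everything
  below t_p" and balancing falls entirely to ADASYN.
* The CH evidence bar (5) is a heuristic calibrated to the pseudo-F null;
  pools with weak but genuine substructure may be collapsed to one medoid.
* RUSBoost here uses SAMME-style updates with stumps; it is a faithful but
  minimal implementation, not a performance-tuned ensemble.
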