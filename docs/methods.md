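# Methods

## Model and assumptions

GRADIS treats GRN reconstruction as supervised link prediction over ordered
(TF, gene) pairs. Its premise is inductive: pairs whose expression
relationship resembles that of experimentally supported TF→target pairs are
themselves likely regulatory. Three assumptions follow. First, the gold
standard's positives are trustworthy and representative of the
interactions to be found. Second, the unlabelled pool is dominated by
non-interactions (true for sparse regulatory networks), so negatives can be
mined from it. Third, a regulatory relationship leaves a footprint in the
joint distribution of the two genes' expression across samples — the method
cannot recover regulation that expression data do not reflect (e.g.
post-translational control).

The feature is deliberately richer than a scalar similarity. After k-means
compression of samples and per-gene min–max rescaling, a pair is a set of k
points in the unit square and the feature vector is all C(k, 2) pairwise
point distances — the upper triangle of the complete weighted graph's
adjacency matrix, row-major, diagonal excluded as identically zero. The
feature is exactly symmetric under swapping the TF and the gene; direction
is carried entirely by which *ordered* pairs are labelled positive and by
restricting prediction sources to the TF list. Both the Euclidean and
Manhattan point metrics are supported; per entry w ≤ w_m ≤ √2·w, so the two
feature spaces are strongly concordant (Mantel r ≈ 0.98 on the default
fixture, matching the 0.96–0.99 range reported for the original benchmark
data).

## Parameters

| parameter | default | notes |
|---|---|---|
| k (sample clusters) | min(50, m/2), m = samples | dimensionless; performance saturates around k = 50 on dense compendia; k(k−1)/2 features |
| k-means restarts | 10 | best within-cluster sum of squares kept; max 300 Lloyd iterations, relative tolerance 1e-6 |
| SVM C, γ | 1, 1/(D·var(X)) | features are bounded ([0, √2] or [0, 2]) and homogeneous, so no standardization; grid search optional (`tune`) |
| RF backend | 500 trees, unlimited depth, √D features/split | comparison backend; the max-margin classifier is the default |
| negative threshold | 0 | pairs never classified positive; relaxed one unit at a time (logged) if a minimum pool size is requested |
| CV | 10 folds × 10 repetitions | training folds balanced by uniform negative subsampling; held-out folds unbalanced |
| confidence level | 95% | normal fit to the per-repetition statistics: mean ± 1.96·sd |

## Numerical and procedural choices

- **Cluster relabelling.** Raw k-means labels are arbitrary, but feature
  coordinates are indexed by cluster, so clusters are canonically relabelled
  (descending size, ties by lexicographically smallest member sample id).
  One clustering is computed per dataset and shared by all pairs. Centroids
  are recomputed as exact per-cluster means of the final assignment.
- **Rescaling scope.** Each gene is min–max rescaled over its own k centroid
  values, independently of its partner, so a gene's scaled profile is
  pair-independent and cacheable. A constant profile maps to all-0.5 (the
  centre of the unit interval) rather than fabricating an extreme corner.
- **Scoring convention.** With n subsets the scheme trains n classifiers; by
  default a pair is assessed only by the n−1 classifiers that did not use it
  as training negatives, so the maximum score is n−1. The alternative
  convention — every classifier scores every pair, maximum n — is available
  as `score_own_iteration` for comparability with implementations that
  report a maximum score equal to the classifier count.
- **Per-iteration training.** Each scoring iteration fits one SVM at fixed
  hyperparameters. Optional `inner_cv` selects (C, γ) by tenfold grid search
  inside every iteration; it multiplies cost by the grid size × 10 and is
  off by default.
- **Subset remainder.** ⌊|U|/|P|⌋ subsets are formed; the last absorbs the
  remainder (sizes |P|, …, |P|, |P|+r), after a seed-controlled permutation
  of a deterministically sorted pool, so the partition is reproducible and
  order-independent.
- **Held-out folds are unbalanced.** Balancing is a training-time device
  against classifier bias; test folds keep all their negatives so AUC/AUPR
  reflect the true prevalence. `balanced_test=True` provides the balanced
  variant for comparison with protocols that balance throughout.
- **AUC/AUPR.** AUC is the Mann–Whitney rank statistic with half credit for
  ties. AUPR is a step-wise sum of precision × Δrecall over distinct score
  thresholds, with no linear interpolation between PR points (a constant
  ranker scores the prevalence; a perfect ranker scores 1). Both are
  cross-checked in the test suite against brute-force counting and
  scikit-learn.
- **Mantel test.** Pearson correlation of vectorized upper triangles with a
  seeded permutation p-value (rows/columns of one matrix permuted
  simultaneously, one-sided greater). Implemented in-package because
  determinism under an explicit seed is part of the pipeline contract; the
  test suite checks r against scikit-bio's implementation.
- **Wisdom-of-crowds combiner.** Each score matrix is scaled by its global
  maximum and combined by an element-wise minimum, which is the exact
  logical equivalent of "above threshold in all matrices" and makes ROC/PR
  sweeps over the conjunction well defined.
- **Pair universe.** Uncharacterised pairs default to
  {(tf, g) : tf ∈ TFs, g ∈ all genes, g ≠ tf} minus labelled pairs; a
  `target_universe` restriction supports benchmarks that score only a known
  target set. Self-pairs are excluded throughout.
- **Degenerate inputs** raise `DataValidationError` (non-finite values,
  single-class labels, mismatched dimensions, contradictory gold-standard
  labels, empty candidate sets); classifier failures inside the scoring loop
  abort with the iteration index rather than silently skipping.

## The synthetic generator

`synthetic_data` plants a sparse directed TF→gene network (uniform edges,
capped in-degree, no self-loops) and simulates expression in which each
regulated gene responds as tanh(Σ β·x_reg) plus Gaussian noise, with effect
sizes |β| ~ U(0.5, 2.0), repression probability 0.3 (`activation_fraction`
0.7), and noise sd 0.3. The saturating response keeps relationships
non-linear without being pathological. TF→TF edges are restricted to run
down the TF index order, forming an acyclic cascade simulated in one
topological pass through *observed* expression — an early design that drove
targets from latent TF activities left most planted edges without any
observable footprint, which defeats the purpose of a learnability fixture.
Unregulated genes are independent noise; the matrix is shifted
non-negative.

Named shapes mirror public benchmark dimensions: `dream4_like` (100 genes ×
210 samples, 40 TFs, 150 edges), `dream5_like` (1643 × 805, 178 TFs, 4012
edges), `tiny` (20 × 30) for unit tests. `hold_out_edges` splits the planted
edges into an observed gold standard and hidden truth, emulating an
incomplete gold standard so enrichment of high pair scores for unreported
true interactions can be measured against a 1000-draw null — the synthetic
analogue of cross-checking predictions against an external interaction
database.

What the generator does **not** emulate: kinetic/ODE dynamics, time-course
autocorrelation, knockout or perturbation designs, measurement-platform
effects, combinatorial logic between regulators, or feedback loops. Passing
tests therefore demonstrate that the implementation recovers planted
statistical dependence under the stated conditions — not that it attains
any particular accuracy on real compendia, where signal is weaker and
confounded.

## Problem sizes used by the tests and the acceptance script

Unit tests run on `tiny`; pipeline-level checks use `dream4_like` at k = 30
(435 features, ~3800 unlabelled pairs, 25–51 scoring iterations depending
on the gold-standard size). The acceptance script evaluates with tenfold CV
× 10 repetitions and a 3-repetition label-permuted control; the
`dream5_like` shape is exercised for data-handling at full size but not run
through the full pipeline, whose all-pairs featurization at that scale
(~290k pairs × 1225 features) is a memory-heavy batch job rather than a
test-suite workload.

## Known limitations

- Mined negatives are model-dependent: a pair the SVM consistently rejects
  may still be a true interaction badly reflected in expression; the
  evaluation treats them as negatives.
- The per-gene rescaling makes features invariant to each gene's location
  and scale but not to monotone non-linear distortions of expression.
- Scores are SVM margins, not calibrated probabilities.
- `choose_k_report` is advisory and re-runs the whole pipeline per k;
  at compendium scale it is expensive.
- The CLI `featurize` writes dense TSV feature matrices; at DREAM5 scale
  prefer the library API, which keeps features in memory as one array.
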