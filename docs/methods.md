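# Methods

This note documents the statistical procedure binsight implements, the
defaults and why they are set where they are, what the synthetic generator
does and does not emulate, and the numerical decisions a maintainer would
want written down.

## The procedure

Given a continuous expression matrix **D** (I samples × J genes,
non-negative, typically log2(x+1)-scale RNA-seq) with binary labels
(1 = tumor, 0 = normal):

1. **Min-max normalization.** Each gene column is rescaled to [0, 1] by
   `(x − min)/(max − min)`, the min/max taken over that column. A constant
   column has no defined rescaling; it maps to all zeros, lands in bin 0,
   carries zero chi-square score, and is filtered out downstream — shape is
   preserved without special-casing.

2. **One-hot binarization.** Each gene becomes K indicator columns, column
   k firing iff the normalized value lies in [k/K, (k+1)/K). Taken
   literally, that membership test leaves the value 1.0 — which min-max
   guarantees occurs in every non-constant column — outside every bin and
   would break the one-active-indicator-per-gene property, so the top
   interval is closed: [(K−1)/K, 1]. Interior boundary values (exactly
   k/K) belong to the upper tile by the `≥` test. Binary columns are
   ordered gene-major then bin-ascending and named `<gene>|bin<k>`, which
   makes the inverse map from any model coefficient or attribution back to
   a (gene, interval) pair trivial and deterministic.

3. **Chi-square ranking.** Each binary feature is scored against the label
   with the 2×2 contingency statistic Σ(O−E)²/E (equivalently
   I·(ad−bc)²/(r₀r₁c₀c₁)), no continuity correction, no p-values — the
   statistic is a ranking criterion, not a test. Degenerate tables (a zero
   marginal) score 0 rather than dividing by zero. Ranking is descending
   with ties broken by ascending column index, so selection is a pure
   function of the data. The top-k features are kept; k is any positive
   integer, with 20/200/2000/20000 as the documented presets
   (0.01%–10% of a 20,530-gene binarized matrix).

4. **Classifier families and search.** Five backends share one interface:

   | family | backend | searched dimensions |
   |---|---|---|
   | decision_tree | scikit-learn | criterion {gini, entropy}, max_depth 10–100, min_samples_split 2–10, min_samples_leaf 1–4, max_features {sqrt, log2} |
   | random_forest | scikit-learn | the tree dimensions + n_trees 100–1000 |
   | xgboost | xgboost | n_trees 100–1000, max_depth 10–100, learning_rate, gamma, min_child_weight, reg_lambda each uniform on [0.01, 0.1] |
   | svm | scikit-learn SVC | kernel {linear, poly, rbf, sigmoid} |
   | neural_network | bundled numpy MLP | layers {1, 2, 3}, nodes/layer 2–input size, dropout 0.1–0.3, activation {ReLU, ELU, GELU, Swish}, learning rate 1, Adadelta |

   Ranges printed with integer endpoints are sampled as discrete uniforms,
   real ranges as continuous uniforms, each dimension independently.
   Random search draws 200 configurations per family and scores each by
   mean F-Measure over stratified 10-fold CV on the training part; the
   argmax wins, first-encountered on ties, so a fixed seed fully
   determines the choice. The SVM space has exactly four points and is
   enumerated once each rather than redundantly resampled. If the
   minority class is smaller than the fold count, folds are reduced to
   the minority count with a warning.

   The MLP is trained with sigmoid output + binary cross-entropy, Glorot
   initialization, inverted dropout on every hidden layer, and Adadelta
   (ρ = 0.95, ε = 1e-6) — a scale-free update rule whose conventional
   learning rate is 1. Epochs (100) and batch size (32) are fixed with no
   early stopping; both are recorded in the estimator's parameters. The
   nodes-per-layer upper bound is the post-selection input dimensionality.

5. **Evaluation.** Repeated stratified splits (default 10 repeats, 80:20),
   per-class train counts rounded to the nearest integer. Metrics are
   computed from confusion counts exactly as defined: accuracy,
   sensitivity, specificity, GMean = √(sens·spec), MCC, precision, recall,
   F1 — any metric whose denominator is zero on a degenerate fold reports
   0 so rows stay total. AUC uses the Mann-Whitney rank identity
   (S_p − n_p(n_p+1)/2)/(n_p·n_n) with midranks for ties, fed by the
   model's continuous positive-class score (probability or decision value);
   with hard 0/1 predictions the identity still applies but degenerates to
   a two-level statistic, so scores are preferred whenever the backend
   provides them. AUC on a single-class test fold is undefined and is
   reported as missing, never as 0. F1 and GMean are positive-class
   quantities, not micro- or weighted averages.

6. **Attribution.** Shapley values with an interventional value function:
   v(S) is the mean model output over a background set whose features in S
   are replaced by the explained sample's values. Two engines:

   * *Exact enumeration* — all 2^F subsets, capped at F ≤ 15. The
     reference implementation; satisfies efficiency, symmetry, and the
     null-feature axiom by construction and reproduces the closed form
     φᵢ = wᵢ(xᵢ − E[zᵢ]) for additive models.
   * *Tree engine* — for scikit-learn decision trees and random forests,
     an exact closed-form computation: every root-to-leaf path is a
     conjunction of per-feature interval constraints; for each
     (sample x, background row z) a path's features split into A (x
     satisfies, z does not — must be in the coalition), B (z only — must
     be out), and irrelevant. The leaf's value then enters each φᵢ with a
     weight that sums the Shapley coalition weights over the free
     features: W_in(a,b) = Σⱼ C(f,j)(a−1+j)!(d−a−j)!/d! for i ∈ A and
     −W_out(a,b) = −Σⱼ C(f,j)(a+j)!(d−a−j−1)!/d! for i ∈ B, f = d−a−b.
     This is linear in leaves instead of exponential in features and
     agrees with exact enumeration to machine precision (the test suite
     asserts 1e-4 per entry; observed ~1e-16).

   The default background is 100 training rows drawn with a fixed seed —
   large enough to stabilize v(∅), small enough to keep the engines
   affordable. Attributions are summarized per feature as mean
   |attribution| over the explained samples, ranked descending (ties by
   column order), and rendered through the bin map as
   `gene ∈ [lo, hi)` rows plus a sign summary (the fraction of
   range-occupying samples whose attribution is positive). The model
   explained is, by default, the best-F1 repeat of a (family,
   feature-count) cell.

## Protocol fidelity vs hygiene

Normalization statistics and feature ranking are computed on the **full
matrix before splitting** by default. That is the protocol this package
models (selection precedes the train/test split) and it leaks label
information into the feature ranking; results under this default measure
the protocol, not generalization. `selection_scope="train"` recomputes
normalization and ranking inside each repeat's training partition only
(test rows are then clipped into the fitted [0,1] range before binning).
Hyperparameter search is redone per repeat by default — repeats would
otherwise be coupled through one split — with `search_once` available to
reuse the first repeat's winner.

## The synthetic generator

`SyntheticSpec` defaults describe a scaled-down tumor/normal cohort:
300 samples, 90% positive (the ~10:1 majority-positive imbalance typical
of public tumor cohorts), 200 genes of which 5 are informative, K = 10,
p_signal = 0.9. Background genes are i.i.d. log-normal (location 1.5,
scale 0.8 on the log scale), giving the non-negative, right-skewed
marginals of log-scale RNA-seq. Each informative gene is built in
normalized coordinates — positives land in one planted bin with
probability p_signal and uniformly elsewhere otherwise; negatives are
uniform — then mapped affinely onto a gene-specific expression range.
Because min-max normalization inverts affine maps exactly, the two extreme
negative-class draws are pinned to the range endpoints so the constructed
coordinates survive normalization unchanged and planted mass cannot drift
across bin boundaries. The planted (gene, bin) pairs are returned as a
truth manifest.

What the generator does **not** emulate: count noise (no negative-binomial
sampling or library-size variation), gene–gene correlation, batch
effects, or any relationship between expression level and variance.
Passing recovery tests therefore shows that the chain detects
bin-localized marginal signal at realistic imbalance — not that it is
robust to correlated or technically confounded real cohorts.

The 300 × 200 default keeps a full pipeline cell (25 search draws, 5-fold
CV, 3 repeats) to a few minutes on one CPU; the generator itself scales to
full-cohort sizes (tens of thousands of genes) if asked.

## Numerical choices and edge cases

- Bin assignment uses `searchsorted` on the exact float grid {k/K}, which
  reproduces the literal `v ≥ k/K ∧ v < (k+1)/K` comparisons including
  their floating-point behaviour; the equivalence is asserted against a
  triple-loop transcription in the tests.
- Chi-square uses the closed 2×2 form; scores are exact rationals in
  float arithmetic and the perfect-association bound χ² = I is attained
  exactly.
- Seeds: every stochastic component (generator, splits, search, backends,
  dropout, background choice) flows from explicit integer seeds; repeat r
  of a run with master seed s uses s + r (mod 2³¹−1). Identical seeds give
  byte-identical reports.
- Degenerate folds: single-class training data makes SVC fail (surfaced
  with family and configuration attached); the MLP degrades to a constant
  predictor; metrics with zero denominators report 0; AUC reports missing.
- Exact Shapley batches subset evaluations so model `predict` is called on
  at most ~65k rows at a time.

## Known limitations

- The chi-square ranking treats binary features marginally; complementary
  bins of the same gene are correlated by construction (their indicators
  sum to 1) and often co-rank, so the top-k list can spend several slots
  on one gene.
- The tree attribution engine covers scikit-learn decision trees and
  random forests; XGBoost and SVM models are explained only through exact
  enumeration, hence only for feature counts ≤ 15.
- Equal-width binning is the design under study; quantile or adaptive
  binning is intentionally out of scope.
- With K = 10 and strong class imbalance, sparsely populated bins of the
  minority class can make individual fold metrics unstable; the repeated
  splits and the zero-denominator conventions are what keep aggregate
  reports well-defined.
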