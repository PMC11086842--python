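# binsight

Explainable tumor-vs-normal classification from RNA-seq expression via
**one-hot interval binarization** of continuous genes, chi-square ranking of
the resulting binary *range-features*, and Shapley-value attribution that
names both the influential gene **and** the expression range driving a
prediction.

## The problem and the approach

Expression-based cancer classifiers work on tens of thousands of continuous
gene measurements. Even when post-hoc explainers rank the important genes,
"gene *g* matters" is a weak clinical statement — what a practitioner wants
is "*samples whose normalized expression of g falls in [0.9, 1.0] are pushed
toward the tumor call*". This package makes that statement a first-class
object:

1. **Min-max normalization.** Each gene column is rescaled to [0, 1] via
   `(x − min)/(max − min)` (constant genes map to 0).
2. **Binarization.** Each gene is expanded into K (default 10) mutually
   exclusive indicator features, one per equal-width interval
   `[k/K, (k+1)/K)`; the top interval is closed at 1.0. Per gene, every
   sample activates exactly one indicator.
3. **Chi-square selection.** Every binary feature is scored against the 0/1
   label by the 2×2 contingency statistic `χ² = Σ (O−E)²/E` (no continuity
   correction) and the top-*k* features are kept (presets 20 / 200 / 2000 /
   20000).
4. **Classification.** Five families — decision tree, random forest,
   XGBoost, SVM, and a numpy MLP (dropout, ReLU/ELU/GELU/Swish, Adadelta) —
   tuned by **random search** (200 draws) with stratified 10-fold CV,
   selected by F-Measure, evaluated over 10 repeated stratified 80:20
   splits with imbalance-aware metrics: GMean, MCC, F1, and rank-based AUC
   `(S_p − n_p(n_p+1)/2)/(n_p n_n)`.
5. **Explanation.** Predictions are attributed to the selected binary
   features by Shapley values (exact subset enumeration up to 15 features,
   or a closed-form interventional engine for tree ensembles) and reported
   as ranked `(gene, value range)` intervals.

A seeded synthetic-cohort generator plants bin-localized signal with known
ground truth so the whole chain can be validated for recovery.

## Worked example

```python
import binsight as bs

ds = bs.generate(bs.SyntheticSpec(seed=0))           # 300 x 200, 5 planted bins
b = bs.binarize(bs.minmax_normalize(ds.matrix), K=10)
scored = bs.score_all(b)
print(sorted(scored.rank[:20]))                      # chi-square top-20 columns
print(sorted(ds.truth_columns))                      # planted (gene, bin) columns
```

prints (seed 0)

```
[7, 9, 480, 483, 485, 486, 489, 1120, 1123, 1124, 1127, 1292, 1295, 1298, 1780, 1785, 1787, 1788, 1789, 1858]
[9, 483, 1124, 1295, 1789]
```

— all five planted columns (e.g. column 1124 = gene `G0112`, bin 4, i.e.
normalized expression in `[0.40, 0.50)`) are recovered among the 20
best-scoring of 2,000 binary features. A scaled-down end-to-end run:

```python
cfg = bs.ExperimentConfig(feature_counts=(20,), families=("random_forest",),
                          n_draws=25, folds=5, repeats=3, seed=0)
report = bs.run_experiment(ds.matrix, cfg)
print(report.means[["family", "n_features", "f1", "gmean", "mcc", "auc"]])
```

```
          family  n_features   f1  gmean  mcc  auc
0  random_forest          20  1.0    1.0  1.0  1.0
```

(a perfect cell on this seed; other seeds land slightly below 1 — the
acceptance run below reports mean F1 ≈ 0.99 at seed 1).

The same chain is available from a shell:

```bash
binsight simulate --seed 0 --out-dir sim
binsight run-all sim/matrix.tsv --labels sim/labels.tsv \
    --top-k 20 --families random_forest --draws 25 --folds 5 --repeats 3 \
    --out-dir run
binsight explain sim/matrix.tsv --labels sim/labels.tsv --top-k 20 \
    --out intervals.tsv
```

`intervals.tsv` ranks features by mean |attribution|; on this seed its top
five rows are exactly the five planted ranges, led by
`G0112|bin4  G0112  [0.40, 0.50)  0.0491  1.0` — gene, value range, mean
absolute Shapley value, and the fraction of range-occupying samples pushed
toward the tumor class.

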