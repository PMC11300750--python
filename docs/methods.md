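# Methods

`radstab` evaluates tabular radiomic features for benign/malignant lesion
classification on medium-sized cohorts (tens of lesions), where the ratio of
features to samples makes naive model selection leak and overfit.  The
package implements four connected procedures: perturbation-based feature
stability scoring, correlation redundancy correction, nested leave-one-out
(LOO) cross-validation with per-fold threshold calibration, and
importance-driven adaptive feature selection.  A synthetic cohort generator
with known ground truth stands in for clinical feature tables, which are
typically not shareable.

## Instability score

A radiomic extraction is repeated over a grid of segmentation-mask variants
(`reduced`, `standard`, `increased`) and gray-level bin widths (by default
15, 20, 25, 30, 35), with `standard:25` as the reference extraction.  For
feature *i* the instability is

```
Delta_i = 1 / (V * n_p) * sum over variants v, lesions p of
          |f_i(v, p) - f_i(ref, p)|  /  ( max_p f_i(ref, p) - min_p f_i(ref, p) )
```

where `V` is the number of variants in the grid (15 for the default 3x5
grid; the reference is included and contributes zero terms, so the
prefactor generalizes `1/15` to any grid) and `n_p` the number of lesions.
Normalizing by the cohort range of the reference feature makes `Delta`
invariant under affine rescaling of a feature and comparable across
features with arbitrary units.

Numerical edge cases: a feature constant at the reference extraction has an
undefined score, reported as NaN and logged — never silently 0 or infinite.
Scores require at least two lesions (otherwise the range is undefined).  No
outlier trimming is applied to the reference range.

## Redundancy correction and PCA check

Pearson correlations are computed between all feature pairs on the
reference-variant table only.  Pairs with `|r|` above a threshold (default
0.95; the absolute value treats strong negative correlation as equally
redundant) are processed once, in descending `|r|`; in each pair the member
with the larger `Delta` is dropped.  An undefined `Delta` counts as larger
than any defined one; an exact tie drops the lexicographically later name,
keeping reruns deterministic.  A pair with an already-dropped member is
skipped, so a connected cluster of correlated features always retains at
least one member.  Because the pass never re-examines pairs, a feature
recorded as a retained partner can still be dropped later through a
different pair; the recorded partner is the one kept *at processing time*.

As a sanity check, the number of principal components needed to reach 99%
cumulative explained variance of the column-standardized table is reported
before and after the correction; dropping genuinely redundant columns
should not change it.  Constant columns are excluded from standardization
and contribute no variance.

## Nested leave-one-out cross-validation

The external LOO holds out one lesion at a time and provides the unbiased
performance sample: one score and one hard call per lesion.  Inside each
external fold, an internal LOO over the remaining `n - 1` lesions drives

1. a hyperparameter grid search — for each setting, the internal LOO
   produces `n - 1` held-out scores whose AUC-ROC is the selection
   criterion; ties break toward the simplest setting (fewest trees,
   smallest cost), then grid order;
2. threshold calibration — the classification threshold maximizing
   sensitivity + specificity over the internal held-out scores (candidates
   are midpoints between consecutive distinct scores plus one candidate
   below the minimum and one above the maximum; ties break toward the
   smallest threshold; prediction is positive iff score >= threshold).

The winning setting is refitted on the full training fold and applied to
the held-out lesion with its calibrated threshold.  The held-out lesion
never enters standardization, grid search, calibration, or the refit of its
own fold.  Internal training sessions number exactly `|grid| * n * (n-1)`;
the `n` refits are tallied separately.

Model families and score scales:

| family | model | score | hyper grid (default) |
|---|---|---|---|
| `rdf` | random decision forest | fraction of trees voting malignant | `n_trees` in {50, 100, 150, 200, 250} |
| `svm_poly3` | SVC, polynomial kernel, degree 3 | signed decision value | `cost` in {1, 2, 5, 10} |
| `logit` | unpenalized logistic regression | predicted probability | (none) |

Features are z-scored with training-fold statistics for `svm_poly3` and
`logit`; the forest sees raw values (tree splits are monotone-invariant).
Thresholds are calibrated on the same score scale they are applied to, so
no cross-family probability calibration is performed; raw thresholds are
not comparable across families.  Pooled external AUC combines scores from
`n` different per-fold models, while the counting metrics (accuracy,
specificity, precision, recall) use each fold's own calibrated threshold.
A zero denominator (e.g., precision with no positive calls) flags the
metric as undefined (NaN) rather than 0.

Reproducibility: every stochastic fit derives its seed from the master seed
plus the fold index, hyperparameter index, and internal position, so reruns
are bit-identical and folds are mutually independent.

Patient grouping: by default the unit of analysis is the lesion.  When the
labels file carries a `patient_id` column and group mode is enabled, the
external LOO leaves out whole patients (all their lesions share one fold
model), preventing leakage between lesions of the same patient; the
internal loop remains per-lesion.

## The in-package random decision forest

`radstab.forest.RandomDecisionForest` is a compact CART forest (Gini
splitting, bootstrap resampling, `sqrt(d)` candidate features per node,
trees grown to purity, midpoint thresholds, deterministic first-best tie
breaks).  The nested-LOO engine needs `|grid| * n * (n-1)` forest fits per
evaluation and the adaptive selection runs ~20 such evaluations, so fit
latency dominates the whole pipeline; the numba-compiled forest fits a
50-tree ensemble on a ~70 x 20 fold in ~2.5 ms, keeping full runs
interactive on one CPU.  The test suite cross-checks it against
scikit-learn's forest (held-out AUC on a common dataset, rank agreement of
Gini importances) and validates the OOB permutation importance against an
independent longhand re-implementation.

A tied leaf votes 0.5.  A node whose sampled candidate features are all
constant becomes a leaf.  Mean decrease Gini is the bootstrap-weighted
impurity decrease credited to the split feature, summed per tree and
averaged over trees (unnormalized).  Mean decrease accuracy is the per-tree
out-of-bag accuracy drop after permuting one feature's OOB values, averaged
over all trees (trees not using the feature contribute zero).

## Distributional importance and adaptive selection

The external LOO yields `n` fitted models, hence a *sample* of `n`
importance values per feature instead of a point estimate.  Family-native
measures: mean decrease accuracy and mean decrease Gini for `rdf`; the
absolute pseudo-weight `|sum_j alpha_j y_j x_j|` over support vectors for
`svm_poly3` (computed on the standardized scale); the drop-one increase in
training deviance for `logit`.  Each feature's sample is summarized by its
mean and interquartile range (linear-interpolation quantiles).

Adaptive selection:

1. evaluate the full (redundancy-corrected) feature set by nested LOO;
2. aggregate the distributional importance of that run;
3. split the mean importances into most/less relevant by one-dimensional
   2-means, solved exactly by enumerating the `n - 1` ordered split points
   (no initialization randomness); the cluster with the larger center seeds
   the model;
4. evaluate the seed set by nested LOO;
5. offer each remaining feature in descending mean importance (mean
   decrease accuracy for `rdf`; the family's single measure otherwise);
   keep it only if the external nested-LOO AUC strictly increases.

Seed-cluster features are accepted wholesale and never pruned; equality of
AUC is not an improvement, so a feature adding nothing is dropped.  The
importance ranking is computed once, up front, not re-computed after each
acceptance.  Every AUC in the trace uses the same master seed, so replaying
any recorded feature set reproduces its AUC exactly.

**Selection bias caveat**: the importances that seed and order the
selection come from a nested-LOO run on all lesions, and the reported final
AUC is maximized over the same external folds it is estimated on.  The
final AUC is therefore an optimistically biased estimate; an unbiased
estimate would need an additional outer validation layer, which a ~70
lesion cohort cannot afford.

## Synthetic cohort generator

Defaults mirror the target study shape: 69 lesions, 35 malignant, 25
features (5 geometric, 20 texture), a 3-mask x 5-bin-width grid referenced
at `standard:25`.  Baseline features are iid standard normal; informative
features add a standardized mean shift `d` (default 1.5 on three features)
to the malignant class; clone features are `r * standardized(source) +
sqrt(1 - r^2) * noise`, hitting the target correlation in expectation
(default pairs at r = 0.99 and 0.97).  Labels assign exactly
`floor(prevalence * n)` malignants by shuffling, so both classes are always
present.  Non-reference variants add

```
mask_offset(m) * sigma_pert * sd_f * eps  +  bw_slope * (bw - 25) * sd_f * eta
```

with independent standard-normal `eps`, `eta` per variant and
`mask_offset` zero for the standard mask, one otherwise; both scales are
relative to the feature's cohort SD, so the parameters are unitless.
Default scales: `sigma_pert` 0.05 for geometric and 0.25 for texture
features, bin-width slope 0.05 per unit for texture and zero (enforced) for
geometric features — reproducing the empirical pattern that shape features
are stable across extractions while texture features drift with bin width.
The reference variant reproduces the baseline matrix bit-exactly.

What the generator does *not* emulate: realistic marginal distributions
(log-normal volumes, bounded ratios), covariance shifts between classes,
correlated perturbation noise across features, or inter-reader segmentation
variability.  Passing tests therefore demonstrate the statistical machinery
— leakage-free estimation, correct accounting, recovery of planted
structure — not radiological validity on real images.

## Problem sizes in the test suite and acceptance script

Simulation-backed checks are sized to run comfortably on one CPU: the
permutation-null check uses 40-lesion, 10-feature cohorts over 30
repetitions with the reduced forest grid {50, 100}; the signal-recovery
check runs the full adaptive selection at the study scale (69 lesions, 20
features, 3 informative at d = 1.5) over 5 generator seeds with grid {50};
the importance-concordance and clone/PCA checks use 20 seeds each.  The
acceptance script executes one complete pipeline at the default study
shape.  Statistical assertions use confidence bounds computed from the
actual repetition counts.

## Known limitations

- The single-pass redundancy correction does not re-examine pairs, so the
  kept set can retain an above-threshold pair when chains interact (the
  processed pair list is authoritative).
- Logistic fits on separable folds have unbounded maximum-likelihood
  coefficients; the optimizer stops at its iteration cap, which is
  deterministic but yields saturated probabilities (a known property of
  unpenalized logit on small folds, not a defect of the fold machinery).
- The SVM pseudo-weight linearizes a degree-3 kernel machine; it is the
  standard heuristic but not a faithful decomposition of the decision
  function.
- Group-aware folds apply to the external loop only; the internal loop
  remains per-lesion even in group mode.
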