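# Methods

## The prediction problem

The target is a binary within-14-days hypoalbuminemia risk label (serum
albumin < 30 g/L) for geriatric inpatients, predicted from four admission
examination panels: vital signs (VS), NT-proBNP, blood routine
examination (BRE) and urine routine examination (URE), 19 numeric
features in all. Patients are analysed in two pneumonia strata because
the discriminative panel differs between them. No time-series structure
is modelled: the label is a fixed risk horizon, not an onset time.

## Synthetic cohort generator

The generator emulates the study design, not a particular hospital's
marginals (per-feature subgroup means/sds of the original cohort are not
public, so calibration to them is impossible).

* Subgroup sizes default to 21 PHP / 15 NPHP / 21 PNHP / 61 NPNHP
  (118 patients), the design's printed composition.
* Each feature is drawn Normal(μ, σ) with (μ, σ) from
  `reference_ranges.yaml` — clinically plausible laboratory reference
  values in routine units. These only set scale; the analyses operate on
  standardized features.
* Effect placement is pneumonia-conditional: all BRE features are shifted
  by `effect_size_bre`·σ in the PHP stratum only, all URE features by
  `effect_size_ure`·σ in the NPHP stratum only. Both effect sizes default
  to d = 1.2, a "particularly significant" panel-level shift of the size
  that yields the heavily starred group differences the design reports;
  the choice was made once, on Cohen's-d conventions, and is exposed in
  `CohortSpec`.
* Albumin is drawn from truncated normals — Normal(26, 2.5) on
  (10, 30) g/L in hypoalbuminemia strata, Normal(38, 4) on (30, 55) g/L
  otherwise — so the label equals 1{albumin < 30} exactly, by
  construction rather than by resampling.
* Age is Normal(78.37, 8.57) truncated to [60, 100]; sex is
  Bernoulli(63/118) (1 = female). Rows carry a stable integer
  `patient_id`.

What the generator deliberately does **not** emulate: feature
correlations within panels (features are independent given the stratum),
skewed laboratory distributions (NT-proBNP and urine counts are
log-normal-ish in reality), missingness, and label noise. Passing tests
therefore demonstrate that the pipeline recovers planted panel-level
structure under clean conditions; they say nothing about robustness to
correlated or heavy-tailed features.

## Augmentation

The enhancement recipe standardizes features (population sd, ddof = 0),
adds `n_copies` = 2 Gaussian-noise copies of every row (sd 0.1 on
standardized features — small relative to unit variance, so copies stay
near their source; the recipe fixes no scale), and subsamples subgroups
without replacement to `target_counts`, defaulting to
{PHP 63, NPHP 45, PNHP 55, NPNHP 53}: hypoalbuminemia strata are kept in
full (21·3, 15·3) and the non-hypo strata are cut to balance the classes
at 108 apiece. The exact rule that yields 55/53 rather than an even
54/54 is under-determined by the design description; the counts are
configuration, not logic. Copies inherit every label and demographic
column and record `source_id` and `copy_idx`.

## Train/test protocol

Splits are stratified on the (pneumonia, hypoalbuminemia) subgroup at a
4:1 ratio. For augmented tables the default protocol groups the split by
source patient (`by_source=True`): noisy copies are near-duplicates, and
a row-level split leaks them across the boundary, letting any
high-capacity model score well by memorization — which in particular
confounds the leave-one-panel-out ablation, since a reduced model without
the signal panel can still recognise its training patients in the
remaining noise panels. The row-level split (the protocol implied by
augmenting before splitting) remains available via
`split_by_source=False` and reproduces noticeably higher, leakage-inflated
baseline accuracies.

## The gradual-fusion model

* **Panel order.** Panels are ranked by the mean plug-in mutual
  information (bits) of their member features with the label, features
  discretized into equal-frequency bins (`n_bins` = 10, shrunk to
  ⌊√n⌋ when n < 100 to keep cells populated). Ties break by the fixed
  order VS, NTproBNP, BRE, URE. The ranking is computed on the training
  split only and frozen into the model.
* **Stagewise fitting.** s₀ = 0; step k fits its submodel to the signed
  residual y − s_{k−1} (all submodels are regressors so residuals compose
  additively; the first step's target is y itself) and adds γ_k times its
  prediction, γ_k = ⟨r, p⟩/⟨p, p⟩ being the exact line-search step for
  squared error. γ_k equals 1 for least-squares and regression-tree fits
  (normal equations) and guarantees that the training sum of squared
  residuals never increases, also for the ε-insensitive SVR candidate,
  which does not itself minimize squared error. The final label is
  s₄ ≥ 0.5.
* **Submodel selection.** Each step computes Deng's grey relational grade
  (distinguishing coefficient ρ = 0.5, both sequences min–max normalized
  to [0, 1], Δmin/Δmax over all positions) between its target and each
  panel feature; mean grade ≥ τ (default 0.75) selects the linear
  least-squares submodel, otherwise the nonlinear candidate. A grade of 1
  means the normalized target coincides with the features. A constant
  sequence normalizes to zeros; two identical sequences give grade 1 by
  convention (Δmax = 0).
* **Nonlinear candidate.** Default is an RBF support-vector regressor
  (C = 1, γ = scale); a depth-4 regression tree is selectable
  (`nonlinear="tree"`). The SVR default was adopted because the
  depth-limited tree cannot match margin-based classifiers on the
  linearly separable panel shifts the generator plants, which defeats the
  model's central purpose of outperforming its own single-panel
  baselines; with the SVR candidate the fused model does so consistently.
* **Persistence.** Models serialize to JSON (panel order; per-step kind,
  grade, γ and raw parameter arrays; scaler; threshold; config echo), and
  prediction re-evaluates the stored arrays, so a saved model is
  reproducible without pickling.

## Descriptive statistics

Group differences use the pooled-variance Student t-test (Welch behind a
flag) and Cohen's d signed hypo minus non-hypo; significance bands are
the conventional 0.05/0.01/0.001 stars with no multiple-testing
correction by default (a Benjamini–Hochberg option would be a one-liner
via `statsmodels` but the descriptive suite mirrors raw bands). Panel
importance is the mean absolute standardized coefficient per panel from
one multivariable L2-regularized logistic regression (C = 1; the ridge
keeps small-stratum fits finite under separation, which is flagged). The
Mantel test correlates the upper triangles of a Euclidean
standardized-feature distance matrix and a 0/1 label-mismatch matrix;
the permutation p-value is one-sided (greater) with the observed
statistic in the null set, or exhaustive over all n! permutations on
request.

## Evaluation

Accuracy, recall and specificity come from confusion counts with
hypoalbuminemia positive; undefined rates (no positives/negatives) are
reported as missing, never as 0. ROC/AUC use the unique-score threshold
sweep with trapezoid integration, which equals pairwise concordance with
ties at ½. "Overall" metrics pool the per-stratum models' test
predictions. The order sweep imposes each of the 24 panel permutations on
the fusion pipeline; the sensitivity analysis refits the model per
stratum without each panel in turn (mutual information re-ranked among
the remaining three) and reports ACC⁻ = full-model accuracy minus
reduced-model accuracy, preserving negative values (removal can help) and
flagging them.

## Problem sizes and numerical choices

The shipped study conditions are the design's own: 118-patient cohorts,
216-row augmented tables, ~172/44 splits. Replicate-rate checks use
20–25 generator seeds, and the acceptance script averages over 10; at
these sizes a full study (24-order sweep included) runs in seconds.
Degenerate inputs are handled explicitly: zero-variance features abort
standardization with the feature named, constant features get MI 0 with
a warning, single-class labels abort fitting, and Δmax = 0 in the grey
relational coefficient (identical sequences) yields grade 1.

## Known limitations

* The grey relational grade between a 0/1 residual and continuous
  features rarely exceeds τ = 0.75, so on realistic inputs the nonlinear
  candidate is selected at every step; the linear branch is exercised
  when the target genuinely tracks a feature (and by the boundary
  settings τ = 0 / τ > 1).
* The fixed 0.5 threshold is uncalibrated: replicates can show perfect
  AUC with lower accuracy. Score calibration is out of scope.
* Reported performance is synthetic-cohort performance under the planted
  effect structure; no claim transfers to any real cohort.
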