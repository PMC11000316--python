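# Methods

This note documents the statistical procedures in `omicsvote`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that matter when reproducing runs.

## Data model

A cohort is a samples × features table with three feature kinds — numeric
clinical, categorical clinical, peptide intensity — a binary diagnosis
label (BPH → 0, PCa → 1; PCa is the positive class everywhere), and an
explicit missing marker. On disk the dialect is plain CSV with `NaN` (any
casing) or an empty cell for missing; label spellings `PCa`/`PCA`/`pca` and
`BPH`/`bph` normalize to the two classes, and anything else is an error
rather than a silent third class. Per-feature per-class summaries
(mean/std/quartiles) use the sample standard deviation (ddof = 1); a class
with a single observation reports std 0 rather than NaN.

## Preprocessing

Order: drop configured irrelevant columns → drop sparse rows then columns →
impute → encode categoricals → min–max normalize.

- **Sparsity thresholds** (`sample_max_missing_frac`,
  `feature_max_missing_frac`, both default 0.5): a row or column whose
  missing fraction exceeds the threshold is removed. The defaults are a
  judgement call — "too many missing values" has no canonical cutoff — and
  both are config-exposed.
- **Imputation**: class-conditional mean by default — each missing numeric
  cell takes the mean of observed values of the same feature *within the
  same diagnosis class*. This preserves per-class means exactly and is
  idempotent. A `global_mean` mode uses the overall mean instead. A
  (feature, class) pair with no observed values falls back to the global
  mean with a warning; a fully missing feature is an error.
- **Leakage policy**: the default fits imputation means and scaling ranges
  on the full labelled table, reproducing a whole-dataset preparation
  workflow. Because this lets held-out fold information (and labels, via
  class-conditional means) influence the transform, a
  `fold_safe_preprocessing` switch refits all parameters inside each CV
  training fold. At prediction time labels are unknown, so held-out tables
  are imputed with the stored *global* training means and scaled with the
  training ranges, clipped into [0, 1].
- **Categoricals** become ordinal integer codes 0..(levels−1) in sorted
  level order; the mapping is stored, and an unseen level at transform time
  is an error. Ordinal (not one-hot) encoding is deliberate: the binary
  clinical flags this targets (prior surgery, prior biopsy) lose nothing,
  and panel bookkeeping stays one-column-per-feature.
- **Normalization**: x → (x − min)/(max − min) per numeric feature; a
  constant feature maps to 0 by convention.

No outlier-specific treatment is implemented beyond the sparsity drops;
unit harmonization across assays is likewise the caller's responsibility.

## Consensus feature selection

Each of five methods nominates exactly `k_per_method` features
(default `max(10, ⌈n_features/10⌉)` — comparable set sizes are what makes
the 0–5 consensus score meaningful):

- **Pearson**: features ranked by |r| with the 0/1 label; the ranking is
  scanned greedily, discarding any feature whose |r| with an already-kept
  feature exceeds the redundancy cutoff (default 0.9), so near-duplicate
  peptides cannot fill the set; if pruning leaves fewer than k survivors
  the set is topped up from the pruned ranking to honour the size
  contract. The matrix itself is R = C/√(diag C ⊗ diag C) from the sample
  covariance; constant features get r = 0 off-diagonal (warned) and 1 on
  the diagonal.
- **Chi-square**: the standard nonnegative-feature construction — per
  feature, class-wise value sums tested against the class-prior
  expectation (scikit-learn's `chi2`). Requires the [0, 1]-normalized
  table; negative input raises with a pointer to normalization. The
  general contingency-table statistic Σ(O−E)²/E is exposed separately as
  `chi2_statistic` and is the oracle the unit tests pin to hand-computed
  2×2 tables.
- **RFE**: recursive feature elimination with an L2 logistic-regression
  base estimator, removing `rfe_step` (default 1) lowest-|weight| features
  per refit. The base estimator and step are free choices; logistic
  regression keeps the eliminated-first order reproducible against a
  brute-force refit oracle, and coarser steps are recommended beyond a few
  hundred features.
- **Random forest**: mean impurity-decrease importance from a seeded
  500-tree forest ("hundreds of trees" is the operative scale; 500 makes
  importances stable enough to rank).
- **L1 logistic regression**: rank by |coefficient| of a seeded
  liblinear fit with C = 1; the sparsity prunes redundant features.

`consensus_score[f]` counts the methods nominating `f`. The final panel is
all features with score ≥ a threshold chosen by sweeping the candidate
thresholds (default 5, 4, 3, 2, 1, strictest first): each candidate panel
is cross-validated with the full model zoo and scored by the best model's
mean AUC (mean-over-models AUC is available). The chosen threshold is the
strictest one whose score is within one standard error (over folds, at the
best threshold) of the maximum. This parsimony rule — the same convention
as one-SE selection on a regularization path — exists because on finite
folds adding pure-noise features moves AUC by amounts well inside fold
noise, and a strict argmax would let a +0.002 fluctuation drag the panel
from 6 to 18 features. `sweep_rule="max"` restores the strict argmax; exact
ties always resolve toward the stricter threshold.

## Classification and metrics

Five families with seeded, config-exposed defaults: logistic regression
(L2, C = 1), decision tree (no depth cap), k-NN (5 neighbours, Euclidean),
SVM (RBF, C = 1, γ = 1/n_features, Platt-calibrated probabilities), random
forest (500 trees). No hyperparameter search is performed.

Assessment is stratified 10-fold cross-validation (stratification keeps
per-fold class counts within 1 of proportional and can be switched off).
Folds are deterministic given the seed. A training fold that degenerates
to a single class is skipped with a warning and metrics average over
completed folds, with the completed count reported.

Metrics, with PCa (1) positive: sensitivity TP/(TP+FN), specificity
TN/(TN+FP), accuracy, F1 = 2TP/(2TP+FP+FN), and AUC computed by the rank
(Mann–Whitney) formula with midranks for ties — a constant score therefore
gives exactly 0.5, and any strictly monotone transform of the scores leaves
AUC unchanged. Models without probabilities contribute a monotone logistic
map of their decision values, which is AUC-neutral. The tests verify the
rank AUC against the trapezoidal area under the empirical ROC to 1e-10.
Reported values are fold means ± sd; the "best model" is the argmax of mean
AUC.

## Ensemble voting

Hard voting returns the majority label of the five models (ties are
impossible with five; user-configured even subsets need an explicit tie
rule). Soft voting computes Σ wᵢpᵢ from positive-class probabilities with
weights proportional to each model's mean CV accuracy (uniform weights
available), normalized to sum 1, and calls PCa when the score ≥ 0.5 — the
threshold and its tie direction are conventions, chosen once. With
degenerate 0/1 probabilities and equal weights, soft voting reduces to
hard voting exactly. Holdout validation reports per-model calls and
probabilities, both ensemble calls, and correct counts per strategy when
labels are present.

## Synthetic cohorts

The generator emulates the *statistical shape* of a prostate case–control
study, not its biology or measurement process:

- **Clinical features** are drawn per class from truncated normals with
  (mean, sd, min, max) defaulting to published per-class summaries — e.g.
  age PCa 66 ± 6.23 in [47, 77] vs BPH 69 ± 6.49 in [56, 81]; gland volume
  PCa 39.78 ± 14.26 vs BPH 71.67 ± 35.86 ml; total PSA PCa 10.33 ± 11.47
  vs BPH 4.02 ± 5.09 mg/l; free PSA PCa 18.41 ± 10.88 vs BPH
  39.22 ± 19.83; F/T ratio PCa 1.73 ± 1.36 vs BPH 1.49 ± 1.95. The F/T
  parameters sit on a different scale than example records elsewhere print
  (values 8–71); the generator takes the parameters at face value and
  offers `derive_ft_ratio` to compute the column as free/total instead.
  Features are sampled independently by default; deriving the ratio is the
  one dependence hook.
- **Peptides** are log-normal (log-mean 9, log-sd 1 — intensities around
  e⁹ ≈ 8×10³, right-skewed as MS intensities are). The first
  `n_informative` peptides are shifted up by `effect_size_d` log-sd units
  in the PCa class (default d = 1.5, the regime where selection should
  succeed at n ≈ 100/class); the rest are identical across classes.
- **Missingness** is completely at random at rate 0.1 (default), confined
  to the clinical columns where real exports are sparse (gland size, PSA
  family).
- Default class sizes follow the two study designs the package targets:
  67/54 (urine-like) with the serum-like 69/74 used where 143-sample
  designs are exercised.

Draws iterate features in sorted name order so a cohort is a pure function
of (spec, seed) regardless of dict insertion order; identical spec + seed
gives byte-identical CSV. The holdout generator uses a disjoint seed
stream. `self_test` checks generated moments against the spec's own
truncated-normal moments at z = 4 and the missing-cell count against a
binomial band.

What passing on these cohorts does *not* show: robustness to batch
effects, heteroscedastic or feature-correlated noise, informative
missingness, label noise, or distributional mismatch between clinic sites
— none of which are simulated.

## Orchestration and reproducibility

The library surface is `ConsensusPipeline(table, ...).fit()` →
`PipelineResults` (panel, CV report, fitted models, weights, `summary()`,
`predict()`, ROC export). The CLI stages (`simulate`, `preprocess`,
`select`, `train`, `vote`, `run-all`) are file-based wrappers over the same
functions; `run-all` literally chains them, so staged and one-shot runs are
the same code path and produce identical artifacts. One global seed is
fanned out per stage through counter-keyed seed sequences (all derived
seeds < 2³¹), so a stage can be rerun in isolation yet reproducibly. The
manifest records the config (and its hash), the per-stage seeds, package
version, stage logs with row/feature counts and durations, and the artifact
list.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run at sizes chosen to exercise
the statistics without waste: planted-feature recovery uses 100 samples
per class with 5 informative among 100 peptides at d = 1.5 across 20 seeds
(10 in the script); null calibration permutes labels on 200-sample,
30-peptide cohorts; the end-to-end synthetic runs use the 143- and
121-sample designs with 32 and 300 peptides respectively, the wide run
with RFE step 5 — a panel-width reduction that leaves every pipeline stage
and contract identical while keeping the recursive wrapper proportionate.

## Known limitations

- The whole-dataset (default) preparation policy is optimistic; fold-safe
  mode is the statistically sound assessment and typically scores lower.
- Chi-square scoring on continuous features uses class-wise sums, not a
  binning scheme; it is a ranking device, not a calibrated test (no
  p-values, no multiplicity correction).
- Binary classification only in this version; the consensus and voting
  machinery would extend to more classes but is not wired for it.
- Ordinal categorical encoding imposes an arbitrary order on >2-level
  factors.
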