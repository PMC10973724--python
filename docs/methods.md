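# Methods

This note records the models implemented in `glycostrat`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices a maintainer would otherwise have to
reverse-engineer.

## Data model

A cohort is one row per plasma sample: 24 glycan-peak relative abundances
(GP1–GP24, fractions of total chromatogram area summing to 1 within 1e-6),
integer age in [18, 100], sex, batch labels (measurement year and plate) and
a binary disease status. Tables stored as percentages are accepted when
declared (`schema_mode="percent"`, tolerance 1e-4 on the 0–100 scale) and
rescaled on read; the mode is recorded, never guessed. Sex enters models as
a one-hot male indicator. GP values are written at 12 significant digits,
which makes read–write round trips stable.

Batch correction deliberately does **not** renormalise the corrected
fractions to unit sum — renormalisation would reintroduce cross-feature
coupling — so post-correction tables are read with the unit-sum check
relaxed. That is the one place the compositional invariant is allowed to
drift (by ~1% in practice).

## Batch correction

Log-transformed GP matrices are adjusted by the standard parametric
empirical-Bayes location/scale scheme: per feature, an OLS fit of batch
dummies plus protected biological covariates (label, age, one-hot sex);
standardisation by the covariate-adjusted mean and pooled residual variance;
batch-wise additive effects γ̂ and multiplicative effects δ̂² on the
standardised residuals; shrinkage of γ towards a normal prior and δ²
towards an inverse-gamma prior (hyperparameters moment-matched across
features) by fixed-point iteration (relative tolerance 1e-6, cap 500
iterations); adjustment (z − γ*)/δ*, de-standardisation and exponentiation
back to fraction scale.

Numerical conventions worth knowing:

* Per-batch variances use the population (ddof = 0) denominator so they are
  consistent with the pooled variance; a single batch, or identical batches,
  then gives γ̂ = 0, δ̂² = 1 exactly and the adjustment is the identity.
* Batch effects are identified only up to the sample-weighted grand mean
  (Σ nᵢγᵢ = 0), so the estimable quantity for a two-batch injection is the
  contrast γ*_B − γ*_A; `BatchModel.batch_shift_log` returns effects on the
  log scale (γ*·σ̂).
* EB shrinkage biases features whose standardised batch effect deviates
  from the cross-feature average; with heteroscedastic features this leaves
  a pooled-mean perturbation of order 1e-4 and per-feature residual batch
  gaps below 0.02 log-units at n = 200/batch. Exact mean preservation holds
  only in the shrinkage-free degenerate cases, and the tests state this.
* Zero GP values are a hard error rather than an epsilon patch: the
  generator has a positivity floor, and silent pseudo-counts would distort
  the log-scale model.
* The default batch factor is the year×plate combination treated as a
  single level set; both columns are configurable.

Covariate balance is audited with the Mann-Whitney U test (exact null when
min(n) ≤ 8 and no ties, normal approximation with tie and continuity
correction otherwise) for numeric variables, Fisher's exact test for sex,
and Benjamini-Hochberg step-up q-values across the tested set, significance
at q < 0.05.

## Covariate-matched augmentation

The non-augmented route keeps samples with age ≤ 60 (inclusive boundary).
The augmented route drops every sample above 74 (the control upper bound),
then synthesises controls with SMOTE (k = 3 nearest Euclidean neighbours on
the 24 GP features only, interpolant a + λ(b − a), λ ~ U(0,1)): exact
case-count matching per age 61–71, floor-half matching at 72–74 (a ceil
variant is available). Age and sex are *assigned*, not interpolated — the
stratum age exactly, sex Bernoulli at the observed control male proportion —
because interpolating the matching covariates would contradict the matching
goal. Neighbour search runs within the age stratum and widens ±1 year at a
time when a stratum has ≤ k controls; strict 2–3-sample strata would
otherwise make k = 3 impossible. Provenance (parents and λ per synthetic
row) is attached to the augmented cohort for auditing. Augmentation runs
after batch correction, on fraction-scale GPs.

SMOTE is known to hurt calibration; no pre-calibration adjustment is
attempted here — the post-hoc Venn-Abers step is the remedy.

## Pipeline search

A pipeline is (scaler ∈ {none, minmax, standard}) × (learner ∈ {LR, SVM,
RF, XGB}) × hyperparameters. Default grid: LR C log-uniform [1e-3, 10],
penalty {L1, L2, elastic-net} (saga solver), l1_ratio [0, 1]; SVM C
log-uniform [1e-3, 10], kernel {linear, polynomial, rbf}; RF 20–400 trees
(step 20), depth 2–10, criterion {gini, entropy}; XGB 40–400 trees (step
40), depth 2–8, booster {gbtree, dart}, gamma [0, 15]. SVM margins are
squashed through a logistic so every learner emits scores in [0, 1]; the
downstream Venn-Abers step is invariant to this monotone map.

Objectives per trial, over stratified inner folds with the scaler fitted on
each fold-train only: mean validation AUC-ROC (midrank Mann-Whitney
formulation, ties ½) and the first Wasserstein distance between the train
and validation AUC vectors (train AUCs come from fold-train predictions per
fold). The sampler is a simplified Pareto-dominance Parzen estimator: 10
uniform start-up trials, then the archive is split by non-domination rank
into "good" (the ranks covering the best ⌈0.25·n⌉ trials) and "bad";
one-dimensional densities are Laplace-smoothed frequencies (categoricals)
or Silverman-bandwidth Gaussian KDEs (continuous, log-scaled where
declared); 24 candidates are drawn from the good model and the best
good/bad density ratio wins. A hyperparameter dimension that either group
cannot model (too few observations of that learner) contributes ratio 1 —
crediting a dimension one side knows nothing about lets a sharp density in
the other group dominate for arbitrary values, a failure mode found during
development. This preserves the contract of the full multi-objective TPE
(dominance-guided sequential sampling) at tractable complexity; a pure
random sampler is available (`sampler="random"`). Failed trials (learner
exceptions) are recorded and excluded from the front, never imputed. The
selected pipeline is the front member with the lowest mean validation
log-loss (probabilities clipped at 1e-15); ties break towards higher AUC,
then lexicographic configuration order.

## Venn-Abers calibration

The inductive Venn-Abers predictor stores the calibration pairs; each query
s performs two weighted isotonic fits — calibration ∪ {(s, 0)} and
calibration ∪ {(s, 1)} — and reads them at s, giving [p₀, p₁], combined as
p₊ = p₁/(1 − p₀ + p₁). Isotonic regression is solved by
pool-adjacent-violators with ties in the abscissa pre-pooled by weighted
mean; evaluation between breakpoints interpolates linearly and clips at the
ends. The per-query naive double refit is the reference implementation; the
default query path pre-pools the calibration set once and calls a C PAVA
routine per augmented fit, and the tests require it to match the naive
reference to 1e-12 (observed: one ulp). Calibration quality is measured by
log-loss and the expected calibration error over 10 equal-width,
right-closed bins (bin count configurable; empty bins skipped), plus an
exportable reliability-bin table.

## Nested cross-validation and the final fit

Stratified 5-fold outer loop; per fold, the pipeline search (default 50
trials) runs on the training portion with stratified 5-fold inner splits,
the winner is refit on the whole training portion, and the held fold is
split stratified 60/40 into a Venn-Abers calibration set and a test set.
Reported per fold: AUC of p₊, sensitivity/specificity/false-negative rate
at threshold 0.5, ECE, log-loss; aggregated: mean AUC, its standard error
and a 95% CI using the normal multiplier 1.96 (a t(4) multiplier is a flag
away; the mean ± SE convention matches how such results are usually
printed), and misclassification counts in 5-year age bins pooled over all
outer test folds. Synthetic (SMOTE) rows may train and calibrate but are
excluded from outer test metrics by default so performance is stated on
real samples; a toggle mirrors the opposite convention. The outer-fold
60/40 split is stratified by class — an unstratified split of ~8% of a
small cohort can lose a class entirely. Stage seeds derive from the master
seed by fixed offsets (kept below 2³¹), so every stage is independently
reproducible. A fold that fails is reported as failed; the report is still
produced if at least 3 folds succeed.

The deployment protocol (`final_fit`) is separate from evaluation: pipeline
search with 5-fold CV on a stratified 90% of the data, refit on that 90%,
Venn-Abers calibration on the held-out 10%, returning an object with
`predict_proba` and `predict_interval`.

## ALE interpretation

First-order Accumulated Local Effects on the calibrated p₊ of the final
pipeline: interval edges at empirical quantiles (default K = 20,
duplicated edges merged), local effect of an interval = mean over the
samples inside it of f(x | xⱼ = upper edge) − f(x | xⱼ = lower edge),
accumulated by cumulative sum and centred so the count-weighted mean of the
interval-midpoint effects is zero (an exact identity, asserted in tests).
Binary features (the sex indicator) use the two-level categorical effect —
interval construction is meaningless for a binary column. A constant
feature yields a degenerate all-zero curve with a warning. `tol` for the
"non-zero ALE" driver list defaults to 1e-6 for exact-zero detection on
tree models; on finite samples a tolerance reflecting the model's noise
floor (e.g. 0.02 on a probability scale) is more informative, and the
examples use that.

## Synthetic cohort generator

Per sample: age and sex from class-specific distributions, a baseline
composition from a Dirichlet, then additive log-scale shifts — class effect
(default on the six "fucosylated-like" peaks GP1, GP4, GP8, GP11, GP14,
GP15; the naming is a convention, not a structural claim), per-decade age
slopes, a sex shift, batch shifts — plus Gaussian noise, a positivity floor
at 1e-6 and renormalisation to unit sum. Ground truth is returned with the
cohort.

Defaults and the reasoning behind them:

* Base composition: a plausible adult IgG profile (a few dominant peaks
  near 16–18%, many minor ones), Dirichlet concentration 1000 with a
  per-peak parameter floor of 8. Without the floor the 0.2%-abundance
  peaks would have log-sd ≈ 1 (a ~30-fold 95% range), far beyond realistic
  UPLC inter-individual variation; the floor caps minor-peak CV near 35%.
* Noise sd 0.12 on the log scale (≈ 12% CV), year-level variance inflation
  up to 1.15.
* Batch shifts are modulated by a fixed zero-mean ±1 pattern across the 24
  peaks: a shift common to all peaks cancels exactly under compositional
  closure and would be unidentifiable by construction; real batch effects
  are peak-specific.
* Age structure: both classes share a truncated-normal "young" component
  (mean 50, sd 9, range 25–60); controls add a small (7%) geometrically
  decaying tail over 61–74 and nothing above 74; cases add a large old tail
  (normal mean 70, sd 7, range 61–90) whose fraction is derived so the
  expected young counts of the two classes are equal — the design in which
  the classes are comparable below 60 and the imbalance lives entirely
  above it, which is exactly the situation the matching strategy assumes.
  Both classes share the male proportion (0.47): the emulated study is
  sex-comparable by design and only age needs repair.
* Default class effect sizes put the oracle linear discriminant near AUC
  0.76 — the moderate-separability regime this kind of framework targets;
  `strong_signal_spec` (×1.45, oracle ≈ 0.85) and `weak_signal_spec`
  (×0.45, oracle ≈ 0.62) scale it for the recovery and ordering checks, and
  `null_spec` removes it entirely for the leakage sentinel.

`bayes_auc` reports the Monte-Carlo AUC (with a Hanley-McNeil standard
error) of the score δᵀ log x built from the true class-shift vector δ.
The exact density ratio of the generative model (Dirichlet × log-normal
shifts, renormalised) has no closed form; this oracle linear discriminant
is a *lower bound* on the true ceiling — pipelines exploiting covariance
structure can and do exceed it — which is the conservative direction for a
yardstick.

What the generator does **not** emulate: chromatographic peak shapes or raw
UPLC signal, missing values, plate-layout spatial effects, non-linear
age trajectories, or label noise. Passing tests therefore demonstrate that
the machinery recovers planted effects of realistic size under clean
compositional noise — not that any particular clinical performance level
will be met on real cohorts.

## Problem sizes used by the tests and the acceptance script

The heavy end-to-end checks run at deliberately chosen desk scales: signal
recovery on 800-sample cohorts with 10 search trials per outer fold; the
null-calibration sentinel on twenty 200-sample cohorts with 3 trials over a
reduced (LR-only) grid — the exchangeability property it checks does not
depend on the grid; batch recovery at 200 samples per batch; calibration
scenarios at 2000 scores. These sizes give stable statistics while keeping
a full run in minutes on one CPU.

## Known limitations

* The parametric EB batch model assumes roughly normal log-scale features
  and at least two samples per batch level; no non-parametric variant, no
  reference-batch mode, no missing-value handling.
* The sampler is a simplified multi-objective TPE; it shares the contract
  but not the internals of the full published algorithm.
* Venn-Abers queries are O(calibration size) each; fine at cohort scale,
  not tuned for millions of queries.
* The decision threshold is an adjustable scalar; cost-sensitive threshold
  optimisation is intentionally out of scope.
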