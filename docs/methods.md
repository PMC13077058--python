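# Methods

## The screening model

`tailsel` scores each feature X_j against a binary outcome Y by a
Gumbel-copula-implied upper-tail concordance coefficient. Both variables are
reduced to pseudo-observations u_i = rank(x_i)/(n+1) with average ranks for
ties (the binary label is treated identically), Kendall's τ-b is computed
between them, and τ̂ is pushed through the Gumbel closed forms θ = 1/(1−τ)
and λ_U = 2 − 2^(1/θ). Because the Gumbel family has λ_L = 0 and admits no
negative dependence, a non-positive τ̂ is mapped to λ_U := 0: the score
deliberately ignores protective (anti-concordant) structure. λ_U is a
strictly increasing function of τ on τ > 0, so the induced ranking equals
the ranking by max(τ̂, 0); the λ scale is kept because it reads as a joint
upper-tail co-occurrence probability and because its bootstrap interval
("strictly above 0") is the natural evidence statement for a tail signal.

Assumptions worth stating plainly:

* the score is *marginal* — each feature is scored alone, so features that
  are informative only through interactions can be under-ranked;
* the score is rank-based and therefore invariant to any strictly
  increasing transform of a feature, but discreteness (heavy ties) shrinks
  τ-b toward 0, so binary features carry attenuated scores relative to an
  equally informative continuous version;
* λ_U here is a concordance transform, not an estimate of an asymptotic
  tail probability; no generative copula is fit and no goodness-of-fit is
  claimed.

## Estimator and numerical conventions

* **τ variant.** τ-b (tie-corrected denominator). With a binary label the
  label-side tie correction is essential; the untied alternative (τ-a)
  would deflate every score as a function of prevalence. The production
  path delegates to `scipy.stats.kendalltau(variant="b")`; an instrumented
  merge-sort (Knight) implementation with an operation counter ships in
  `tailsel.copula.kendall_tau_counted` so the O(n log n) behaviour is
  verifiable by op counting, and the two paths are cross-checked against an
  O(n²) all-pairs oracle in the tests.
* **Degenerate inputs.** A constant feature has undefined τ; it is scored
  τ = 0, λ_U = 0 and flagged `degenerate=True` instead of raising, so a
  screen over real survey data never aborts on one bad column. A constant
  *label* raises, since no screening question remains.
* **Clamping.** τ̂ ≥ 1 − 1e−12 is clamped before the 1/(1−τ) map so
  finite-sample perfect concordance yields a large finite θ.
* **Tie-breaks in ranking.** λ_U descending, then τ descending, then
  original column order — fully deterministic.
* **Closed-form tolerance.** All identity checks in the tests use 1e−12
  relative tolerance.

## Bootstrap uncertainty

The training rows are resampled with replacement B = 1000 times (plain,
unstratified). Pseudo-observations and τ are recomputed inside every
resample, since ranks change under resampling. A resample that draws a
single class is scored λ = 0 for every feature and counted (the count is
returned and logged). Intervals are 2.5–97.5 percentiles; the reported
criterion for a positive tail association is an interval strictly above 0.

## Baseline selectors

* **MI** — `mutual_info_classif` (kNN/Kraskov estimator, 3 neighbours,
  features treated as continuous, fixed `random_state`; the estimator's own
  internal jitter breaks discrete ties).
* **mRMR** — greedy: first pick maximizes MI with the label; subsequent
  picks maximize MI minus the mean absolute Pearson correlation with the
  already-chosen set. Correlation against a constant column is defined 0;
  greedy ties break by column order; the greedy run continues to exhaustion
  so the output is a full permutation with k marking the selected prefix.
* **ReliefF** — binary variant: features z-scored on the split, 10 nearest
  hits and 10 nearest misses per instance (all training rows, Euclidean
  distance over all features, neighbour counts clipped to availability),
  score = mean |difference| to misses minus mean |difference| to hits.
* **L1EN** — elastic-net logistic regression on standardized features
  (saga, l1_ratio 0.5, C = 1/strength with strength 1.0, balanced class
  weights, iteration cap 4000; non-convergence warns and uses the last
  iterate). Features are ranked by |β̂_j|, exact zeros after all nonzeros in
  column order. The mixing/strength defaults are package choices — they are
  conventional midpoints, not values dictated by the protocol.

## Evaluation protocol

One 80/20 stratified outer split; 20% of the training rows are held out as
a validation subset used solely to choose the decision threshold. Stage 1
fits on the inner training rows and scans the 999 quantile levels
0.001…0.999 of the validation scores, keeping the *smallest* cutoff that
maximizes F1 (the fine-grid scan keeps operating points comparable across
prevalences; smallest-cutoff tie-break for determinism). Stage 2 refits the
identical configuration on train+validation — scalers and calibrators
re-fit — scores the untouched test rows once, and applies the frozen
threshold. Metrics are positive-class accuracy/precision/recall/F1 plus
ROC-AUC (midrank implementation) with a 1000-resample percentile bootstrap
interval on test rows (single-class resamples redrawn and logged).

Classifier families and their policies: logistic regression (standardized,
balanced class weights, uncalibrated), random forest (balanced class
weights), gradient boosting (per-sample weights proportional to inverse
class frequency, normalized to sum to n), and XGBoost
(`scale_pos_weight` = negatives/positives on the training rows). The three
tree families are calibrated by 5-fold stratified isotonic regression via
`CalibratedClassifierCV`, which averages the per-fold (estimator,
calibrator) pairs at predict time. Classifier hyperparameters are library
defaults under a fixed seed — the harness, not the learners, is the
contribution.

Permutation importance permutes one test column at a time (500 repeats by
default) and reports the mean and SD of the AUC drop, scoring through the
full fitted path (scaling + calibration).

## Paired tests

DeLong's test uses midrank structural components, the 2×2 covariance of the
paired components, and a two-sided normal tail; tied scores are handled by
the midranks, and a zero-variance difference (e.g. identical score vectors)
returns z = 0, p = 1 by convention. McNemar's test uses the
continuity-corrected statistic (|b−c|−1)²/(b+c) with a χ²(1) upper tail and
the convention χ² = 0, p = 1 when b + c = 0. Extreme p-values are reported
exactly; any "< 0.001" formatting is left to presentation layers.

## Perturbations

Label flips and MCAR masks use exact counts (`round(frac·n)` distinct
positions) rather than Bernoulli draws, so perturbation sizes are
reproducible; the wording of the protocol permits either. Feature-noise SDs
and imputation medians are fit on training rows only and applied to both
splits; test labels are never perturbed. Zeros-as-missing imputation (for
clinical tables where literal zeros encode missing physiological readings)
fits its median on the nonzero training-row values only. Masking is applied
after the train/test split, consistent with the train-only median fit.

## Synthetic generators

`sample_gumbel` draws exact Gumbel-copula pairs by the Marshall–Olkin
positive-stable mixture with the Chambers–Mallows–Stuck stable transform —
exact and constant-time per draw; θ = 1 short-circuits to independent
uniforms.

`make_cdc_like` emulates the *structure* of a large risk-factor survey, not
any real data distribution: independent latent normals combine through
planted weights into a risk score; the label thresholds the noisy risk at
the (1 − prevalence) quantile, which guarantees the planted concordance
signs in expectation (a latent-threshold rather than logistic-sampling
construction, chosen for exactly that guarantee). Observed features are
monotone cuts of the latents — mostly binary, some ordinal, occasional
continuous — mirroring survey data. Defaults: n = 5000, d = 21 with 8
risk-increasing features (weights 1.0 → 0.5), 5 protective (weight −0.25,
strong enough that their negative τ is detected essentially always at
n = 5000), 8 nulls, prevalence 0.14. A second frozen configuration,
`sufficiency_spec`, plants *only* positive-tail signal (8 risk + 13 null)
and is used where the question is whether the selected set is sufficient —
with protective features present, dropping them necessarily costs some
discrimination, which is a property of the scoring rule, not a bug, and is
measured on the first fixture instead.

`make_pima_like` emulates a small clinical table: eight continuous
physiological features with a glucose-dominant weight profile, prevalence
≈ 0.35, and literal zeros injected into five designated columns at the
rates seen in the classic 768-row benchmark.

What passing on these fixtures does *not* show: real survey features are
mutually correlated (the generators use independent latents), real
marginals are not Gaussian cuts, and real missingness is rarely MCAR.
Results on fixtures validate the machinery and its contracts, not field
performance.

## Problem sizes

The test suite and the acceptance script use n = 5000 fixtures, B = 1000
for the λ_U bootstrap where intervals are the object under test and smaller
B where they are incidental, 100 seeds per θ* for parameter recovery, and
1000 replicates for the DeLong null calibration — sizes at which every
targeted effect is comfortably resolved on a single CPU in a few minutes.

## Known limitations

* Marginal screening: interaction-driven features can be missed.
* Protective factors are zeroed by design; a lower-tail (e.g. Clayton) or
  two-sided criterion would be needed to rank them, and is out of scope.
* Only the Gumbel family is implemented; other upper-tail families (Joe,
  Student-t, BB1) would give different λ_U scales but — being monotone in a
  concordance measure — broadly similar rankings.
* The evaluation harness fixes learner hyperparameters at library defaults;
  it is a comparison protocol, not an AutoML system.
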