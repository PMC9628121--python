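# Methods

This note documents the models, calibrations and design choices behind
`survbench`, in the order data flow through the pipeline.

## Synthetic registry cohorts

The two presets emulate the published structure of real MCI registries:
a small memory-clinic cohort (`prompt_like`: n = 273, 30 predictors,
40% three-year conversion) and a large community cohort (`nacc_like`:
n = 967, 35 predictors, 23% conversion). Neither the real covariate
distributions nor their missingness patterns are modelled — only the
cohort sizes, the mixed-type predictor battery, the conversion rates
and the overall discrimination level, which is what the downstream
model comparison is sensitive to.

**Covariates.** A Gaussian copula: latent multivariate normal with
exchangeable correlation (default 0.2, a typical registry-scale
between-predictor association), thresholded to binaries at the normal
quantile of each prevalence, cut at equal-probability quantiles for
ordinal scores, identity for continuous columns (hence exactly
standardized). Ordinal predictors enter models as numeric scores, as
registries usually handle graded scales.

**Outcomes.** Weibull proportional hazards,
`S(t|x) = exp(-(t/λ)^k e^{η(x)})`, with shape k = 1.2 (mildly
increasing conversion hazard after MCI diagnosis) and a 3-year
administrative horizon τ. The linear predictor η adds two pairwise
interactions and two nonlinear transforms (centred square and absolute
value of continuous predictors) scaled to 10% of the total
linear-predictor variance, so a forest-based data-generating process
has genuine signal beyond the linear part.

**Censoring.** Random censoring uniform on (0, τ] for a fraction q of
subjects, administrative censoring at τ for the rest, independent of
covariates. The expected event fraction is linear in q, namely
(1−q)·A + q·B with A the mean failure probability at τ and B its
average over a uniform censoring time (both computed by Gauss–Legendre
quadrature over the realized covariates), so q solves exactly for the
target rate; the generator reports an explicit achievable range [B, A]
if the target lies outside it.

**Calibration of the presets** (computed once, cached, on a fixed
100 000-subject draw with an internal seed independent of user seeds):

1. the Weibull scale λ is solved by bisection so the target event rate
   sits at the midpoint of [B, A] (i.e. q = 1/2) — placing the target
   mid-range keeps the censoring solve feasible at any coefficient
   scale;
2. q is then solved exactly as above;
3. an outer bisection on a single multiplier of the whole linear
   predictor drives the oracle c-index (risk = true η, estimated from
   two million sampled comparable pairs) to 0.70 ± 0.01, the
   discrimination level a well-specified model reaches on large MCI
   registries. Held-out checks give c ≈ 0.696 (small preset) and 0.698
   (large preset).

## Model-conditional data-generating processes

A base model — Cox regression (Breslow baseline) or a random survival
forest (150 trees, minimum leaf 20; curves via exp(−ensemble CHF)) —
is fitted to a seed cohort. From then on only covariates and
predictions are used. Per-subject curves are step functions on the
estimator's native grid (the unique observed training times; both base
models are constant between events).

Each simulated subject takes two independent uniform draws:

* **event indicator** δ ~ Bernoulli(p̂) with p̂ = 1 − Ŝ(τ) by step
  evaluation;
* **event time** by discrete inverse transform,
  T = inf{t_j : Ŝ(t_j) ≤ u}; probability mass beyond the last grid
  point belongs to the last grid point (extrapolating past the fitted
  curve would be unsupported). When δ = 1 the draw is restricted to
  u ∈ (Ŝ(τ), 1), i.e. conditioned on T ≤ τ.

**Censored subjects are recorded at τ.** This is a deliberate choice
among assembly rules the Bernoulli-plus-time formulation leaves open.
With censoring at τ the simulated data are exactly self-consistent:
the observed event intensity at t is the subject's f(t) and the
at-risk probability is S(t), so the hazard — and any proportional-
hazards refit — recovers the base model. The alternative of censoring
at min(T′, τ) for an independent draw T′ makes the censoring time
depend on the subject's own risk; we measured a systematic upward bias
of ≈ 10% in refitted Cox coefficients under that rule (0.055 absolute
on a coefficient of 0.5 at n = 10⁴, versus 0.014 for censoring at τ).
Censoring at τ also matches how the emulated registries censor: the
only stated mechanism is the 3-year observation window. The
alternative remains available as `censor_rule="min_tau"`.

Conservation (mean simulated event fraction = mean p̂) and fidelity
(pooled simulated Kaplan–Meier within 0.03 of the mean source curve on
[0, τ]) are asserted in the test suite.

## Model zoo

Fitters are the established implementations: scikit-survival for Cox
(`alpha` gives the ridge variant), elastic-net Cox (coordinate
descent; lasso is the l1_ratio = 1 edge), survival tree, random
survival forest and the survival SVM (regression objective,
rank_ratio = 0, per the formulation that handles survival times as a
regression problem); xgboost with `objective="survival:cox"`. Margin-
only models (xgboost, the neural network) get survival curves by
attaching a Breslow baseline estimated on their training margins. The
SSVM predicts a survival-time score only — its risk is the negated
score, and it deliberately reports "no curves" rather than a fake
probability, so ICI/IBS records for it are flagged missing.

The neural adapter is a DeepSurv-style multilayer perceptron (ReLU,
dropout, Adam, full-batch negative Breslow partial likelihood). It is
an optional extra behind a lazy `torch` import; everything else runs
without it and the harness records it as unavailable.

**Tuning** is random grid search over spaces declared in
`search_spaces.yaml` (log-uniform penalties 10⁻³–10³ for ridge,
10⁻⁴–10 for lasso/EN, tree depth 2–8, forest size 50–150 with leaf
10–40, SSVM regularization 2⁻¹²–2⁶, boosting depth/learning-rate/
rounds/subsampling), scored by mean 5-fold event-stratified
cross-validated Harrell c-index, ties to the earliest sampled point,
failed candidates scored −∞ and logged. The default budget is 50
evaluations — a desk-scale stand-in for the 1000-evaluation budget of
full-scale studies; the budget is a pure scale parameter.

## Metrics

**Harrell's c-index.** Comparable pairs are (i, j) with
time_i < time_j and subject i an event; tied risks count 1/2; pairs
tied in time are not comparable. No comparable pairs raises an
explicit error rather than returning 0.5. The implementation is
block-vectorised and is property-tested against brute-force pair
enumeration.

**ICI.** Predicted failure probabilities at t* = 3 are clipped to
[10⁻⁶, 1 − 10⁻⁶] (the cloglog transform diverges at 0 and 1; the
clip bound is recorded in the fit), rounded to 12 significant digits,
and reduced to unique values. A Cox model with the 3-knot restricted
cubic spline of cloglog(p̂) as its only covariate (knots at the
10th/50th/90th percentiles, the standard placement when only "three
knots" is specified) smooths observed against predicted risk; the ICI
is the unweighted mean absolute difference over unique predictions.
Evaluation is at the single horizon t*; no time-varying calibration.

**IBS.** Evaluation grid = unique observed event times ≤ τ. Weights
follow the Graf convention — events before t* weighted 1/G(t⁻ᵢ),
survivors 1/G(t*), with G the Kaplan–Meier estimate of the censoring
distribution (left limits where the subject's own event time enters).
A `weighting="literal"` variant divides both terms by G(tᵢ) for
sensitivity analysis, since published formula summaries sometimes
print that simplification. A zero censoring-survival weight at a
required point raises an error naming the time point.

## Experiment harness

Per replicate: simulate a cohort from the condition's DGP, split into
3 event-stratified folds, fit each model on two folds and predict the
third, pool the out-of-fold predictions and compute each metric once.
Pooling is the lower-variance convention; per-fold averaging is
available (`fold_agg="per_fold"`) and every record carries its
aggregation tag. Tuning happens once per condition on a pilot
replicate and is reused across replicates.

Seeds derive from the master seed through a CRC-hashed
(condition, replicate, model) tree, so reruns are bit-identical and
adding a model or replicate never changes existing records. Tables
are long-format CSV, written incrementally and resumable; duplicate
keys on resume raise an integrity error.

**Problem sizes.** The default study profile is 50 replicates and
50 tuning evaluations; the full-scale profile (500 replicates,
1000 evaluations) is a config choice away. The package's own
scaled-down study (two presets × two DGPs × 50 replicates with Cox,
lasso-Cox, RSF and XGBoost) reproduces the qualitative orderings the
benchmark is about: uniformly higher discrimination under the Cox DGP
than the RSF DGP, the correctly specified base model within 0.02 of
the best mean c-index under its own DGP, and the forest above chance
under the forest DGP even in the small cohort.

## What passing tests do and do not show

The generator reproduces registry-scale structure (sizes, mixed
predictor battery, conversion rates, discrimination level), not any
real registry's joint covariate distribution, missingness, informative
censoring or competing mortality risk. Conclusions transfer to real
data only to the extent those features do not dominate; competing
risks in particular are out of scope. Metric implementations, by
contrast, are exact against their oracles regardless of data source.

## Numerical details

* Survival curves are clipped to [0, 1] and forced nonincreasing
  (cumulative minimum) before validation, absorbing ensemble-averaging
  jitter at the 10⁻¹² level.
* Step evaluation is right-continuous: S(t) = value at the largest
  grid point ≤ t, 1 before the first point.
* Inverse-transform draws at u below the curve's final value take the
  last grid time (tail rule).
* Observed times are floored at 10⁻¹² to guard against floating
  underflow in extreme hazard draws.
* Cohort tables round-trip through CSV at 17 significant digits.
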