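# Methods

This note records the models, algorithms and numerical choices behind
`fairpost`, the assumptions they make, and what the synthetic experiments
can and cannot show.

## Synthetic data model

The generator draws a two-class, two-feature dataset from class-conditional
bivariate Gaussians: the favorable class (Y=1) from mean (2, 2+s) with
covariance [[5,1],[1,5]], the unfavorable class from mean (−2, −(2+s)) with
covariance [[10,1],[1,3]]. The shift `s` (unitless, default 0; −1/0/+1 give
low/medium/high separation) moves only the second-feature means, changing
task difficulty without touching the group structure. The protected
attribute is `a = sgn(x0)`; `x0 = 0`, a probability-zero event under the
continuous model, maps to the privileged group by a documented tie-break.

Group coding: unprivileged = A=0 = {x0 < 0}, because under the model that
group holds the smaller share of the favorable class — analytically
Φ(−2/√5) ≈ 0.186 of the favorable and Φ(2/√10) ≈ 0.736 of the unfavorable
class. Empirical shares from 1000-draw samples scatter around those values
with binomial noise (≈ ±0.012 SE), which is why composition checks compare
within standard errors rather than exactly.

What the generator emulates: the two axes along which real clinical
datasets vary most — favorable-class proportion (here held at exactly 1/2)
and unprivileged group representation (controlled by resampling) — plus a
protected attribute correlated with the features. What it does not emulate:
more than two features, non-Gaussian marginals, label noise, measurement
artifacts, or several correlated protected attributes in the base
generator (a separate fixture plants attribute correlations). Passing tests
therefore show that the methods behave as designed under controlled bias,
not that they will behave identically on any particular clinical dataset.

## Group-rate resampling (class balance + nesting)

For a target unprivileged group rate r, the planner finds the largest even
total m such that the per-class unprivileged demand u = round(r·m/2)
(round-half-up) and privileged demand p = m/2 − u fit into all four
(group, class) cells; m is searched by decrementing in steps of 2, which is
deterministic and exact. Two constraints (exact class balance, target rate)
leave the split of unprivileged rows across classes free; we impose
within-group class balance (equal unprivileged counts per class), the most
symmetric choice. Achieved rate differs from the target by at most 1/m.

Resampling draws one seeded permutation per cell and takes every demanded
count as a prefix, so within any cell the rows selected for a smaller
demand are a subset of those for a larger demand (cell-wise nesting),
verifiable by set inclusion on row identifiers. Whole-dataset nesting
across rates is impossible in general: as the target rate grows, privileged
demands shrink, so the privileged side of a higher-rate subset cannot
contain the privileged side of a lower-rate one. Cell-wise nesting is the
strongest property the constraints admit, and is what the package
guarantees and tests.

A practical consequence worth knowing: the feasible total m can be much
smaller than the source data. On the 2000-row s=0 dataset, a 5-fold
training fold (1600 rows) supports only ≈470 rows at rate 0.1 — the
privileged-negative cell runs out first. Experiments at extreme rates are
therefore small-sample experiments by construction.

## Metrics

EOp = |TPR0 − TPR1|; EOd = (|TPR0 − TPR1| + |FPR0 − FPR1|)/2; both in
[0,1], 0 = parity, invariant to group relabeling. Undefined group rates
(empty denominators) raise rather than silently returning 0, because a
fairness comparison against an undefined rate is meaningless. Balanced
accuracy is pooled over groups ((TPR+TNR)/2 of the whole sample), treating
it as a global performance metric. F1 with zero predicted positives is 0
with a warning — the usual convention under severe imbalance. Cliff's δ is
computed by sorted-rank counting (O((n+m)log) — identical to the O(n²)
pairwise definition, which the tests verify), with |δ| ≥ 0.428 flagged as a
large effect. Spearman p-values default to the asymptotic approximation; a
seeded permutation test is available and recommended below n ≈ 30.

Fold metrics are averaged per fold first and changes computed from fold
pairs, so "mean absolute change" always refers to a mean over paired
fold-level measurements.

## The seven policies

All methods share one contract: fit on a validation `GroupedScores`
(scores, truth, group), return a JSON-serializable `DecisionPolicy`, apply
with `score ≥ threshold → favorable` tie-breaking everywhere; randomized
policies read an explicit seeded stream and are reproducible.

- **CPP** mixes the lower-cost group's calibrated score toward its
  base-rate constant predictor with the probability that equates
  generalized false-negative rates (mean 1−score over positives); the FN
  variant is the default (recall prioritized), the FP variant is behind a
  flag. The mixing probability has a closed form (linear interpolation,
  clamped to [0,1]).
- **EPP** solves a 4-variable linear program over conditional output
  probabilities P(output 1 | group, base prediction), minimizing expected
  misclassification subject to exact post-policy TPR and FPR equality. The
  program is always feasible (constant predictors satisfy it); a 1e-9
  objective nudge prefers the identity among ties.
- **ROC** scans margins 0..0.5 in 0.01 steps and returns the smallest whose
  flip-region policy (unprivileged → favorable, privileged → unfavorable
  inside the margin) brings validation EOp inside a band (default 0.05);
  if none reaches the band, the EOp-minimizing margin is returned.
- **PSTA** keeps the privileged threshold at 0.5 and picks the unprivileged
  threshold from the sorted unique validation scores that brings the
  unprivileged TPR closest to the population TPR at 0.5, subject to the
  unprivileged FPR staying within a slack (default +0.10) of the population
  FPR — our reading of "acceptable false-positive rates"; the slack is
  configurable. Ties prefer the threshold closest to 0.5, then the larger.
- **FACT** optimizes per-group per-prediction flip rates on the confusion
  tensor, minimizing expected error + λ·|TPR gap| (λ default 1). The
  objective is piecewise-linear in the rates, so the exact minimizer comes
  from a small LP with an epigraph variable for the absolute value; a
  microscopic flip-mass penalty prefers the identity among equivalent
  optima. (A least-squares relaxation would only approximate the same
  piecewise-linear objective; the LP solves it exactly.)
- **GSTAR** picks one threshold per group minimizing smoothed error +
  λ·smoothed EOd, where group-conditional score distributions are
  Gaussian-kernel smoothed with Silverman bandwidths (floored at 1e-3).
  A full grid over empirical scores (thinned to ≤80 per axis) seeds a
  Nelder-Mead refinement; the refined point is kept only if it improves on
  the grid optimum.
- **MAB** iterates: fit a ridge auditor (α=1) on the features to the
  residuals (truth − score); treat the auditor prediction h as a soft
  region indicator and measure the violation as |E[h·r]| / E[|h|] — the
  mean absolute residual over the region the auditor points at; while it
  exceeds the tolerance (default 0.01), add η·h (default 0.1) to the score
  logits, accepting a round only if the violation strictly decreases; stop
  after 50 rounds. The audit has a sampling noise floor of order
  σ·√(d/n), so on small validation sets corrections may chase noise until
  the acceptance rule halts them — consistent with the method's observed
  tendency to degrade performance on small imbalanced data. The protected
  attribute is never an input.

Optimizer equivalence is enforced by tests: every threshold/rate method is
compared against an exhaustive brute-force search on small validation sets
(for EPP, a grid over the feasible manifold defined by its equality
constraints; for FACT, a vectorized 4-D grid at resolution 0.05).

## Benchmark protocol

Stratified k-fold CV (stratified by class × group; label-only fallback when
strata are thinner than k). The test set of each fold is fixed; training
folds are optionally resampled to target group rates. Models are pluggable
adapters emitting class-1 probabilities (shipped: L2 logistic regression,
XGBoost). Policies are fit on the training fold's own model predictions by
default. A held-out calibration split (`calibration_frac`) is available
and preferable for large folds, but it is deliberately not the default: at
rate 0.1 a 25% split of the ≈470-row training fold holds about 12
unprivileged rows, and group-rate estimates from a dozen points are
unusable — measured across seeds, policies fit that way frequently
*increase* held-out EOp, while full-fold fitting reproduces the expected
improvements.

Every after-measurement is paired with a before-measurement from the same
fold, model and seed; randomized policies are applied 10 times and their
metrics averaged. All randomness derives from one run seed through named,
CRC-hashed substreams (folds, resampling, calibration, policies, mutation
trials), so runs replay bit-identically.

Fold-level caveat: on 400-row test folds the unprivileged-positive cell
holds ≈36 instances, giving per-fold EOp sampling noise of roughly ±0.07 —
comparable to the methods' effect. Directional fold-level checks therefore
average EOp across the three separation levels before comparing, which is
stable across seeds; single-level per-fold win counts are close to coin
flips and should not be read as method failures.

## Trade-off baseline and regions

The reference curve mutates a uniformly chosen fraction d ∈ {0.1,…,1.0} of
the unmitigated predictions to the majority class of the true labels (the
dominant single-strategy choice; 50 trials per degree by default), and
joins the per-degree mean (fairness, performance) points and the
unmitigated origin into a polyline (linear interpolation, flat
extrapolation). At d = 1 predictions are constant, so the fairness gap is
exactly 0 and accuracy equals the majority proportion — closed forms used
as self-checks. Region labels: win-win (both strictly improve), inverted
(performance improves, fairness does not), lose-lose (neither improves),
and for fairness-improving performance-dropping points good vs poor by
lying on/above vs below the polyline at the point's fairness value. Good
splits at the healthcare factor (default 0.9, configurable up to 0.99 for
high-stakes settings): retaining at least that fraction of the origin
performance is the stricter sub-region. Ties are conservative: equality
with the origin counts as not-improved on fairness and not-worsened on
performance, so a do-nothing method never counts as beating the baseline.

## Imbalance stratification

Favorable-class proportion maps to low/medium/high via [0, 0.25),
[0.25, 0.75), [0.75, 1]; unprivileged group rate via [0, 0.20),
[0.20, 0.50), [0.50, 1] — half-open as written, boundary values landing in
the right-hand interval. Because an *extreme* favorable-class proportion in
either direction means severe class imbalance, the profile also exposes a
severity view (outer intervals → high severity, middle → medium); both
views are available since tables indexed by "class imbalance degree" and by
"FCP level" are not the same thing.

## Known limitations

- The seven methods are re-implementations from their one-paragraph
  descriptions with stated defaults (PSTA's FPR slack, GSTAR's λ and
  bandwidth rule, MAB's auditor class and steps are our choices, all
  configurable); numbers need not match any original implementation
  exactly.
- Change tables exclude relative changes when the baseline magnitude is
  below 1e-6 (count reported); absolute and relative means can rank methods
  differently because they are averaged separately.
- Trade-off baselines need in-memory predictions; a results store reloaded
  from CSV supports change and untreated-attribute tables but not region
  classification.
- Multi-attribute joint debiasing, pre-/in-processing methods, and deep
  model training are out of scope; model adapters make classifiers
  pluggable.
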