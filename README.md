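# fairpost

Post-processing bias mitigation benchmark for clinical risk prediction.

Risk models used in healthcare routinely show group disparities: patients in
one demographic group are flagged for intervention less reliably than
patients in another. Post-processing debiasing adjusts a *trained* model's
scores or decisions — without retraining — to shrink those disparities, and
every method pays for fairness with some predictive performance. `fairpost`
is a library for studying that trade-off systematically: it generates
synthetic biased tabular data with controllable class separation and group
representation, implements seven post-processing debiasing methods behind a
single fit/apply policy interface, scores results with the standard group
fairness and performance metrics, and classifies each outcome against a
mutation-derived trade-off baseline. It is aimed at researchers and
practitioners evaluating which mitigation method suits a given imbalance
regime.

## The model and metrics

**Synthetic biased data.** Features are drawn from class-conditional
bivariate Gaussians

```
X | Y=1 ~ N( (2, 2+s),   [[5, 1], [1, 5]] )
X | Y=0 ~ N( (-2, -(2+s)), [[10, 1], [1, 3]] )
```

with the favorable label Y=1 and a separation shift `s` (−1 low, 0 medium,
+1 high). The binary protected attribute is `a = sgn(x0)`, so group
membership is coupled to the class structure: at `s = 0` about 18% of the
favorable class but 73% of the unfavorable class is unprivileged (`x0 < 0`).
A stratified resampler then produces exactly class-balanced training sets at
any target unprivileged group rate (UGR), nested cell-wise across targets.

**Fairness** is measured by the equal opportunity difference
`EOp = |TPR0 − TPR1|` and the equalized odds difference
`EOd = (|TPR0 − TPR1| + |FPR0 − FPR1|) / 2` (0 = fair); **performance** by
accuracy, balanced accuracy and F1. Effect sizes use Cliff's δ with
|δ| ≥ 0.428 flagged as large.

**Methods.** Seven post-processing debiasers, each returning a serializable
`DecisionPolicy`: CPP (calibrated score mixing equalizing generalized
false-negative rates), EPP (randomized derived predictor solving the
equalized-odds linear program), ROC (reject-option flipping in a margin
around the decision boundary), PSTA (population-sensitivity-guided threshold
for the unprivileged group), FACT (confusion-tensor flip rates trading
accuracy against EOp), GSTAR (group-specific thresholds minimizing smoothed
error + λ·EOd), and MAB (multiaccuracy boosting from auditor residuals — the
only method that never sees the protected attribute).

**Trade-off regions.** A reference polyline is built by mutating a growing
fraction of the unmitigated predictions to the majority label; every
mitigation outcome lands in exactly one region — win-win, good (split at a
healthcare factor, default 90% retained performance), poor, inverted, or
lose-lose.

## Worked example

`examples/02_debias_and_evaluate.py` trains a logistic model on half of the
2000-row `s = 0` dataset, fits each policy on the training scores and
evaluates on the held-out half:

```
method       acc   bacc     f1    eop    eod
identity   0.879  0.879  0.880  0.280  0.281
cpp        0.824  0.822  0.845  0.360  0.661
epp        0.737  0.737  0.737  0.039  0.021
roc        0.872  0.873  0.871  0.166  0.159
psta       0.864  0.863  0.871  0.117  0.159
fact       0.772  0.775  0.740  0.003  0.093
gstar      0.833  0.835  0.819  0.052  0.061
mab        0.879  0.879  0.880  0.280  0.281
```

`identity` is the unmitigated 0.5-threshold rule (EOp 0.28: the privileged
group's true-positive rate is 28 points higher). ROC and PSTA roughly halve
the gap for ~1 point of accuracy; EPP removes it almost entirely but costs
14 points; CPP worsens fairness here; MAB's auditor finds nothing to correct
on an already multiaccurate model. `examples/03_tradeoff_regions.py`
classifies the same outcomes: ROC, PSTA, FACT and GSTAR land in the good
region above the 90% healthcare line, EPP below it, CPP and MAB in
lose-lose. The other examples cover data generation/resampling and the
untreated-attribute spillover analysis; the `fairpost` CLI
(`simulate | run | report | fixtures`) drives full YAML-configured runs.

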