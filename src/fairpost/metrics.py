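"""Group-fairness and predictive-performance metrics.

Fairness is assessed with the two group-difference metrics used throughout
the package: the equal opportunity difference,

.. math:: \\mathrm{EOp} = |\\mathrm{TPR}_0 - \\mathrm{TPR}_1|,

and the equalized odds difference,

.. math:: \\mathrm{EOd} = \\tfrac12\\bigl(|\\mathrm{FPR}_0-\\mathrm{FPR}_1|
          + |\\mathrm{TPR}_0-\\mathrm{TPR}_1|\\bigr),

both zero under perfect group parity.  Performance is summarized by
accuracy, pooled balanced accuracy, and F1 of the favorable class.  The
module also provides Cliff's delta (the nonparametric dominance effect
size, with the conventional |delta| >= 0.428 large-effect flag) and
pairwise Spearman correlations between protected attributes, which the
benchmark uses to study spillover of debiasing onto untreated attributes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateGroupError,
    InvalidArgumentError,
    UndefinedCorrelationError,
    UndefinedMetricError,
    UndefinedRateError,
)
from .synth import TabularDataset

__all__ = [
    "GroupedScores",
    "GroupConfusion",
    "FairnessReport",
    "Performance",
    "CliffsDelta",
    "AttrCorrelation",
    "LARGE_EFFECT",
    "confusion_by_group",
    "eop",
    "eod",
    "performance",
    "evaluate",
    "cliffs_delta",
    "spearman_attr_corr",
]

#: Conventional threshold above which |Cliff's delta| marks a large effect.
LARGE_EFFECT = 0.428


@dataclass
class GroupedScores:
    """Per-instance scores, labels and group membership for one attribute.

    ``score`` holds class-1 probabilities in [0, 1]; ``predicted_label`` is
    optional until a decision policy has been applied.  ``features`` is an
    optional feature matrix carried along for policies that operate on
    features rather than groups (the multiaccuracy auditor); it must never
    contain the protected attribute itself — that exclusion is the caller's
    contract.
    """

    score: np.ndarray
    true_label: np.ndarray
    group: np.ndarray
    predicted_label: np.ndarray | None = None
    features: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        self.true_label = np.asarray(self.true_label, dtype=int)
        self.group = np.asarray(self.group, dtype=int)
        n = len(self.score)
        if len(self.true_label) != n or len(self.group) != n:
            raise InvalidArgumentError("score/true_label/group lengths differ")
        if n and (self.score.min() < 0 or self.score.max() > 1):
            raise InvalidArgumentError("scores must lie in [0, 1]")
        for name, vec in (("true_label", self.true_label), ("group", self.group)):
            if not np.isin(vec, (0, 1)).all():
                raise InvalidArgumentError(f"{name} must be binary 0/1")
        if self.predicted_label is not None:
            self.predicted_label = np.asarray(self.predicted_label, dtype=int)
            if len(self.predicted_label) != n:
                raise InvalidArgumentError("predicted_label length differs")
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=float)
            if self.features.shape[0] != n:
                raise InvalidArgumentError("features row count differs")

    @property
    def n(self) -> int:
        return len(self.score)

    def with_labels(self, labels: np.ndarray) -> "GroupedScores":
        return GroupedScores(
            score=self.score,
            true_label=self.true_label,
            group=self.group,
            predicted_label=np.asarray(labels, dtype=int),
            features=self.features,
        )


@dataclass(frozen=True)
class GroupConfusion:
    """Per-group confusion counts with derived rates."""

    counts: dict[int, dict[str, int]]  # group -> {"tp","fp","tn","fn"}

    def _rate(self, g: int, num: str, den: tuple[str, str]) -> float:
        c = self.counts[g]
        total = c[den[0]] + c[den[1]]
        if total == 0:
            raise UndefinedRateError(
                f"rate {num} undefined for group {g}: empty denominator"
            )
        return c[num] / total

    def tpr(self, g: int) -> float:
        return self._rate(g, "tp", ("tp", "fn"))

    def fpr(self, g: int) -> float:
        return self._rate(g, "fp", ("fp", "tn"))

    def fnr(self, g: int) -> float:
        return 1.0 - self.tpr(g)


class Performance(NamedTuple):
    acc: float
    bacc: float
    f1: float


@dataclass(frozen=True)
class FairnessReport:
    """The five benchmark metrics for one evaluated prediction set."""

    acc: float
    bacc: float
    f1: float
    eop: float
    eod: float

    def to_row(self, **keys) -> dict:
        """Flatten to a dict suitable for one CSV/DataFrame row."""
        row = dict(keys)
        row.update(acc=self.acc, bacc=self.bacc, f1=self.f1, eop=self.eop, eod=self.eod)
        return row


def confusion_by_group(data: GroupedScores) -> GroupConfusion:
    """Count TP/FP/TN/FN separately for each protected group."""
    if data.predicted_label is None:
        raise InvalidArgumentError("predicted labels are required")
    counts: dict[int, dict[str, int]] = {}
    for g in (0, 1):
        mask = data.group == g
        if not mask.any():
            raise DegenerateGroupError(g)
        y = data.true_label[mask]
        p = data.predicted_label[mask]
        counts[g] = {
            "tp": int(np.sum((y == 1) & (p == 1))),
            "fp": int(np.sum((y == 0) & (p == 1))),
            "tn": int(np.sum((y == 0) & (p == 0))),
            "fn": int(np.sum((y == 1) & (p == 0))),
        }
    return GroupConfusion(counts)


def eop(conf: GroupConfusion) -> float:
    """Equal opportunity difference |TPR0 - TPR1|."""
    return abs(conf.tpr(0) - conf.tpr(1))


def eod(conf: GroupConfusion) -> float:
    """Equalized odds difference, the mean of the TPR and FPR gaps."""
    tpr_gap = abs(conf.tpr(0) - conf.tpr(1))
    fpr_gap = abs(conf.fpr(0) - conf.fpr(1))
    return 0.5 * (tpr_gap + fpr_gap)


def performance(data: GroupedScores) -> Performance:
    """Accuracy, pooled balanced accuracy and favorable-class F1.

    Balanced accuracy is pooled over groups, ``(TPR + TNR) / 2`` of the
    whole sample.  F1 with zero predicted positives is defined as 0 (with a
    warning), the common convention under severe imbalance.  A single-class
    truth vector leaves balanced accuracy and F1 undefined and raises.
    """
    if data.predicted_label is None:
        raise InvalidArgumentError("predicted labels are required")
    y, p = data.true_label, data.predicted_label
    acc = float(np.mean(y == p))
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            "balanced accuracy and F1 are undefined for single-class truth"
        )
    tpr = np.sum((y == 1) & (p == 1)) / n_pos
    tnr = np.sum((y == 0) & (p == 0)) / n_neg
    bacc = float(0.5 * (tpr + tnr))
    pred_pos = int(np.sum(p == 1))
    if pred_pos == 0:
        warnings.warn("no predicted positives; F1 set to 0", stacklevel=2)
        f1 = 0.0
    else:
        precision = np.sum((y == 1) & (p == 1)) / pred_pos
        recall = tpr
        f1 = 0.0 if precision + recall == 0 else float(
            2 * precision * recall / (precision + recall)
        )
    return Performance(acc=acc, bacc=bacc, f1=f1)


def evaluate(data: GroupedScores) -> FairnessReport:
    """All five benchmark metrics in one report."""
    conf = confusion_by_group(data)
    perf = performance(data)
    return FairnessReport(
        acc=perf.acc, bacc=perf.bacc, f1=perf.f1, eop=eop(conf), eod=eod(conf)
    )


@dataclass(frozen=True)
class CliffsDelta:
    delta: float
    large: bool


def cliffs_delta(before, after, threshold: float = LARGE_EFFECT) -> CliffsDelta:
    """Cliff's dominance effect size between two samples.

    delta = (#{pairs x > y} - #{pairs x < y}) / (n_x * n_y) over all pairs
    with x drawn from ``before`` and y from ``after``; positive delta means
    the first sample tends to exceed the second.  ``large`` flags
    |delta| >= ``threshold`` (default 0.428).  Runs in O((n+m) log(n+m))
    via sorted-rank counting rather than explicit pair enumeration.
    """
    x = np.asarray(before, dtype=float)
    y = np.asarray(after, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidArgumentError("both samples must be non-empty")
    ys = np.sort(y)
    greater = np.searchsorted(ys, x, side="left").sum()  # pairs with x > y
    less = (len(ys) - np.searchsorted(ys, x, side="right")).sum()  # x < y
    delta = float(greater - less) / (x.size * y.size)
    return CliffsDelta(delta=delta, large=abs(delta) >= threshold)


@dataclass(frozen=True)
class AttrCorrelation:
    """Pairwise Spearman correlations between protected attributes."""

    rho: pd.DataFrame
    pvalue: pd.DataFrame


def spearman_attr_corr(
    dataset: TabularDataset,
    pvalue_method: str = "asymptotic",
    n_resamples: int = 9999,
    seed: int = 0,
) -> AttrCorrelation:
    """Symmetric tables of rank correlations between protected attributes.

    ``pvalue_method="asymptotic"`` uses the t approximation of
    :func:`scipy.stats.spearmanr`; ``"permutation"`` (recommended for
    n < 30) uses a seeded permutation test of the same statistic.
    Constant attribute columns leave the correlation undefined and raise.
    """
    names = list(dataset.protected)
    if len(names) < 2:
        raise InvalidArgumentError("need at least two protected attributes")
    for name in names:
        if len(np.unique(dataset.protected[name])) < 2:
            raise UndefinedCorrelationError(
                f"attribute {name!r} is constant; correlation undefined"
            )
    rho = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    pval = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    for a, b in combinations(names, 2):
        xa, xb = dataset.protected[a], dataset.protected[b]
        if pvalue_method == "permutation":
            res = stats.permutation_test(
                (xa, xb),
                lambda u, v: stats.spearmanr(u, v).statistic,
                permutation_type="pairings",
                n_resamples=n_resamples,
                rng=np.random.default_rng(seed),
            )
            r, p = float(stats.spearmanr(xa, xb).statistic), float(res.pvalue)
        elif pvalue_method == "asymptotic":
            out = stats.spearmanr(xa, xb)
            r, p = float(out.statistic), float(out.pvalue)
        else:
            raise InvalidArgumentError(f"unknown pvalue_method {pvalue_method!r}")
        rho.loc[a, b] = rho.loc[b, a] = r
        pval.loc[a, b] = pval.loc[b, a] = p
    return AttrCorrelation(rho=rho, pvalue=pval)
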