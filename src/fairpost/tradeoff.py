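"""Mutation-based fairness–performance baseline and region classification.

A reference trade-off curve is constructed by progressively replacing a
random fraction (the *mutation degree*) of a model's predictions with the
majority label and recording the resulting (fairness, performance) points.
The polyline through these points, anchored at the unmitigated model's
origin point, partitions the plane into five mitigation regions:

* **win-win** — fairness and performance both strictly improve;
* **good** — fairness improves, performance drops but stays on/above the
  baseline polyline; split at a configurable *healthcare factor* (default
  0.9) into **good-2.2** (performance retained above the factor times the
  origin performance) and **good-2.1** (below it);
* **poor** — fairness improves but performance falls below the baseline;
* **inverted** — performance improves while fairness worsens;
* **lose-lose** — both worsen.

Fairness is smaller-better (EOp/EOd), performance larger-better.  Ties are
conservative: equality with the origin on fairness counts as *not
improved*; equality on performance counts as *not worsened*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError
from .metrics import GroupedScores, confusion_by_group, eod, eop, performance

__all__ = [
    "TradeoffBaseline",
    "MitigationOutcome",
    "build_baseline",
    "classify_region",
    "REGIONS",
]

REGIONS = ("win-win", "good-2.1", "good-2.2", "poor", "inverted", "lose-lose")

_FAIRNESS = {"eop": eop, "eod": eod}


def _point(labels: np.ndarray, data: GroupedScores, fairness: str, perf: str):
    scored = data.with_labels(labels)
    f = _FAIRNESS[fairness](confusion_by_group(scored))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # heavy mutation can zero out positives
        p = getattr(performance(scored), perf)
    return f, p


@dataclass(frozen=True)
class TradeoffBaseline:
    """The mutation polyline in (fairness, performance) space."""

    origin: tuple[float, float]
    degrees: tuple[float, ...]
    points: tuple[tuple[float, float, float], ...]  # (degree, fairness, perf)
    fairness_metric: str = "eop"
    performance_metric: str = "acc"
    healthcare_factor: float = 0.9

    def performance_at(self, fairness: float) -> float:
        """Baseline performance at a fairness value (linear interpolation).

        The polyline runs through the origin and the mean point of every
        mutation degree, sorted by fairness; outside the covered fairness
        range the curve is extended flat.
        """
        pts = [(self.origin[0], self.origin[1])] + [(f, p) for _, f, p in self.points]
        pts.sort()
        xs = np.array([f for f, _ in pts])
        ys = np.array([p for _, p in pts])
        return float(np.interp(fairness, xs, ys))


@dataclass(frozen=True)
class MitigationOutcome:
    region: str
    point: tuple[float, float]


def build_baseline(
    preds: GroupedScores,
    degrees=tuple(np.round(np.arange(0.1, 1.01, 0.1), 2)),
    n_trials: int = 50,
    seed: int = 0,
    fairness_metric: str = "eop",
    performance_metric: str = "acc",
    healthcare_factor: float = 0.9,
) -> TradeoffBaseline:
    """Build the mutation baseline from unmitigated predictions.

    For each degree ``d``, over ``n_trials`` seeded trials, a uniformly
    chosen fraction ``d`` of the predicted labels is replaced by the
    majority class of the true labels; the mean fairness and performance
    per degree form the polyline.  At degree 1.0 the predictions are
    constant, so the fairness gap is exactly 0 and the accuracy equals the
    majority-class proportion.
    """
    if preds.predicted_label is None:
        raise InvalidArgumentError("unmitigated predicted labels are required")
    degrees = tuple(float(d) for d in degrees)
    if len(degrees) == 0:
        raise InvalidArgumentError("degrees must be non-empty")
    if any(not 0.0 < d <= 1.0 for d in degrees):
        raise InvalidArgumentError("degrees must lie in (0, 1]")
    if list(degrees) != sorted(set(degrees)):
        raise InvalidArgumentError("degrees must be strictly increasing")
    majority = int(np.bincount(preds.true_label, minlength=2).argmax())
    origin = _point(preds.predicted_label, preds, fairness_metric, performance_metric)
    rng = np.random.default_rng(seed)
    n = preds.n
    points = []
    for d in degrees:
        k = int(round(d * n))
        fs, ps = [], []
        for _ in range(n_trials):
            labels = preds.predicted_label.copy()
            idx = rng.choice(n, size=k, replace=False)
            labels[idx] = majority
            f, p = _point(labels, preds, fairness_metric, performance_metric)
            fs.append(f)
            ps.append(p)
        points.append((d, float(np.mean(fs)), float(np.mean(ps))))
    return TradeoffBaseline(
        origin=origin,
        degrees=degrees,
        points=tuple(points),
        fairness_metric=fairness_metric,
        performance_metric=performance_metric,
        healthcare_factor=healthcare_factor,
    )


def classify_region(
    point: tuple[float, float], baseline: TradeoffBaseline
) -> MitigationOutcome:
    """Assign a mitigated (fairness, performance) point to its region.

    See the module docstring for the region definitions and tie rules.
    Every point in [0, 1]^2 receives exactly one label.
    """
    f, p = float(point[0]), float(point[1])
    if not (0.0 <= f <= 1.0 and 0.0 <= p <= 1.0):
        raise InvalidArgumentError(f"point {point} outside [0, 1]^2")
    f0, p0 = baseline.origin
    fairness_better = f < f0
    perf_better = p > p0
    if fairness_better and perf_better:
        region = "win-win"
    elif not fairness_better:
        region = "inverted" if perf_better else "lose-lose"
    else:  # fairness improved, performance did not
        if p >= baseline.performance_at(f):
            if p >= baseline.healthcare_factor * p0:
                region = "good-2.2"
            else:
                region = "good-2.1"
        else:
            region = "poor"
    return MitigationOutcome(region=region, point=(f, p))
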