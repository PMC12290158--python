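"""Post-processing debiasing policies behind one fit/apply interface.

Every method consumes a :class:`FitContext` — held-out validation scores
with true labels and group membership — and returns a
:class:`DecisionPolicy`, a serializable description of how raw scores are
turned into decisions.  Policies come in six kinds:

``identity``
    Threshold scores at 0.5 (the unmitigated decision rule).
``group_thresholds``
    One decision threshold per group (PSTA, GSTAR).
``flip_region``
    A symmetric margin around the 0.5 boundary inside which low-confidence
    decisions are flipped in favor of the unprivileged group (ROC).
``mixing_rates``
    With a per-group probability, replace the score by that group's
    base-rate constant predictor (calibrated equalized odds, CPP).
``flip_rates``
    Per-group, per-predicted-label randomized label flips (the derived
    equalized-odds predictor, EPP, and the confusion-tensor method, FACT).
``score_corrections``
    An ordered list of additive logit corrections learned from residuals by
    a feature-space auditor (multiaccuracy boosting, MAB); the only kind
    that never sees the protected attribute.

The tie rule used everywhere is ``score >= threshold -> favorable``.
Randomized policies draw from an explicit seeded stream, so applying a
policy twice with the same seed yields identical labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize, stats
from sklearn.linear_model import Ridge

from .errors import (
    ConvergenceError,
    FitError,
    InvalidArgumentError,
    SchemaError,
)
from .metrics import GroupedScores, confusion_by_group, eod, eop

__all__ = [
    "DecisionPolicy",
    "FitContext",
    "apply_policy",
    "expected_group_rates",
    "expected_eod",
    "fit_identity",
    "fit_cpp",
    "fit_epp",
    "fit_roc",
    "fit_psta",
    "fit_fact",
    "fit_gstar",
    "fit_mab",
    "METHODS",
    "RANDOMIZED_KINDS",
]

#: Policy kinds whose applied labels depend on the application seed.
RANDOMIZED_KINDS = frozenset({"mixing_rates", "flip_rates"})


@dataclass(frozen=True)
class DecisionPolicy:
    """A learned post-processing transform from scores to labels.

    ``params`` is JSON-serializable (group keys are strings), so a policy
    round-trips exactly through :meth:`to_json` / :meth:`from_json` for
    replay.
    """

    kind: str
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"kind": self.kind, "params": self.params}, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DecisionPolicy":
        obj = json.loads(text)
        return cls(kind=obj["kind"], params=obj["params"])


@dataclass
class FitContext:
    """Validation data plus optimizer settings for fitting a policy.

    The validation set must contain both groups and both classes; the fit
    functions raise :class:`FitError` otherwise.  ``settings`` carries
    method-specific knobs (grids, tolerances, lambda weights); unknown keys
    are ignored by methods that do not use them.
    """

    data: GroupedScores
    fairness_metric: str = "eop"
    performance_metric: str = "acc"
    settings: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fairness_metric not in ("eop", "eod"):
            raise InvalidArgumentError("fairness_metric must be 'eop' or 'eod'")
        for g in (0, 1):
            if not np.any(self.data.group == g):
                raise FitError(f"validation data has no instances of group {g}")
        for c in (0, 1):
            if not np.any(self.data.true_label == c):
                raise FitError(f"validation data has no instances of class {c}")


# ---------------------------------------------------------------------------
# applying policies


def _base_labels(score: np.ndarray) -> np.ndarray:
    return (score >= 0.5).astype(int)


def apply_policy(
    policy: DecisionPolicy, data: GroupedScores, seed: int = 0
) -> np.ndarray:
    """Apply a policy to scores, returning 0/1 labels.

    Deterministic policy kinds ignore ``seed``; randomized kinds
    (``mixing_rates``, ``flip_rates``) draw from ``default_rng(seed)`` and
    are reproducible for a fixed seed.
    """
    s, g = data.score, data.group
    kind, p = policy.kind, policy.params
    if kind == "identity":
        return _base_labels(s)
    if kind == "group_thresholds":
        thr = np.array([p["thresholds"][str(gi)] for gi in g])
        return (s >= thr).astype(int)
    if kind == "flip_region":
        m = p["margin"]
        labels = _base_labels(s)
        region = (s >= 0.5 - m) & (s <= 0.5 + m)
        labels[region & (g == 0)] = 1
        labels[region & (g == 1)] = 0
        return labels
    if kind == "mixing_rates":
        rng = np.random.default_rng(seed)
        labels = _base_labels(s)
        draw = rng.random(len(s))
        for gi in (0, 1):
            prob = p["mix_prob"][str(gi)]
            base_label = 1 if p["base_rate"][str(gi)] >= 0.5 else 0
            mask = (g == gi) & (draw < prob)
            labels[mask] = base_label
        return labels
    if kind == "flip_rates":
        rng = np.random.default_rng(seed)
        labels = _base_labels(s)
        draw = rng.random(len(s))
        out = labels.copy()
        for gi in (0, 1):
            for yhat in (0, 1):
                prob = p["flip"][str(gi)][str(yhat)]
                mask = (g == gi) & (labels == yhat) & (draw < prob)
                out[mask] = 1 - yhat
        return out
    if kind == "score_corrections":
        if data.features is None:
            raise SchemaError("score_corrections policy requires features")
        eps = p.get("logit_clip", 1e-6)
        sc = np.clip(s, eps, 1 - eps)
        logit = np.log(sc / (1 - sc))
        for step in p["steps"]:
            h = data.features @ np.asarray(step["coef"]) + step["intercept"]
            logit = logit + step["eta"] * h
        corrected = 1 / (1 + np.exp(-logit))
        return _base_labels(corrected)
    raise InvalidArgumentError(f"unknown policy kind {policy.kind!r}")


def _group_rates(data: GroupedScores, labels: np.ndarray) -> dict[int, tuple[float, float]]:
    """(TPR, FPR) per group of a label vector against the data's truth."""
    conf = confusion_by_group(data.with_labels(labels))
    return {g: (conf.tpr(g), conf.fpr(g)) for g in (0, 1)}


def expected_group_rates(
    policy: DecisionPolicy, data: GroupedScores
) -> dict[int, tuple[float, float]]:
    """Expected per-group (TPR, FPR) under a policy.

    For randomized kinds this is the exact expectation over the policy's
    random stream (no sampling); for deterministic kinds it equals the
    rates of the applied labels.
    """
    kind, p = policy.kind, policy.params
    if kind not in RANDOMIZED_KINDS:
        return _group_rates(data, apply_policy(policy, data))
    base = _group_rates(data, _base_labels(data.score))
    out: dict[int, tuple[float, float]] = {}
    for g in (0, 1):
        tpr, fpr = base[g]
        if kind == "mixing_rates":
            prob = p["mix_prob"][str(g)]
            const = 1.0 if p["base_rate"][str(g)] >= 0.5 else 0.0
            out[g] = (
                (1 - prob) * tpr + prob * const,
                (1 - prob) * fpr + prob * const,
            )
        else:  # flip_rates
            q0 = p["flip"][str(g)]["0"]  # P(flip | predicted 0)
            q1 = p["flip"][str(g)]["1"]  # P(flip | predicted 1)
            out[g] = (
                tpr * (1 - q1) + (1 - tpr) * q0,
                fpr * (1 - q1) + (1 - fpr) * q0,
            )
    return out


def expected_eod(policy: DecisionPolicy, data: GroupedScores) -> float:
    """Expected equalized-odds difference of a policy on ``data``."""
    rates = expected_group_rates(policy, data)
    return 0.5 * (
        abs(rates[0][0] - rates[1][0]) + abs(rates[0][1] - rates[1][1])
    )


# ---------------------------------------------------------------------------
# shared fitting helpers


def _cell_masses(data: GroupedScores) -> dict[tuple[int, int], float]:
    """Fraction of instances in each (group, class) cell."""
    n = data.n
    return {
        (g, c): float(np.sum((data.group == g) & (data.true_label == c))) / n
        for g in (0, 1)
        for c in (0, 1)
    }


def _base_group_rates(data: GroupedScores) -> dict[int, tuple[float, float]]:
    return _group_rates(data, _base_labels(data.score))


def _require_cells(data: GroupedScores) -> None:
    for g in (0, 1):
        for c in (0, 1):
            if not np.any((data.group == g) & (data.true_label == c)):
                raise FitError(f"validation cell (group={g}, class={c}) is empty")


def fit_identity(ctx: FitContext) -> DecisionPolicy:
    """The unmitigated policy: threshold scores at 0.5."""
    return DecisionPolicy(kind="identity", params={})


# ---------------------------------------------------------------------------
# CPP — calibrated score mixing equalizing generalized false-negative rates


def _generalized_fnr(scores: np.ndarray) -> float:
    """Mean (1 - score) over positives: the calibrated-score FN cost."""
    return float(np.mean(1.0 - scores))


def fit_cpp(ctx: FitContext, variant: str = "fnr") -> DecisionPolicy:
    """Calibrated score mixing that equalizes generalized FN (or FP) rates.

    The group with the lower generalized false-negative rate is mixed, with
    probability ``p``, toward its base-rate constant predictor (whose
    generalized FNR is ``1 - base_rate``); ``p`` solves the linear
    interpolation that matches the other group's rate, clamped to [0, 1].
    The false-negative variant is the default (recall prioritized to
    minimize missed at-risk cases); ``variant="fpr"`` equalizes generalized
    false-positive rates instead.
    """
    data = ctx.data
    _require_cells(data)
    if variant not in ("fnr", "fpr"):
        raise InvalidArgumentError("variant must be 'fnr' or 'fpr'")
    cost: dict[int, float] = {}
    trivial: dict[int, float] = {}
    base_rate: dict[int, float] = {}
    for g in (0, 1):
        mask = data.group == g
        mu = float(np.mean(data.true_label[mask]))
        base_rate[g] = mu
        if variant == "fnr":
            pos = mask & (data.true_label == 1)
            cost[g] = _generalized_fnr(data.score[pos])
            trivial[g] = 1.0 - mu
        else:
            neg = mask & (data.true_label == 0)
            cost[g] = float(np.mean(data.score[neg]))
            trivial[g] = mu
    mix = {0: 0.0, 1: 0.0}
    lo = 0 if cost[0] < cost[1] else 1
    hi = 1 - lo
    if cost[lo] != cost[hi]:
        denom = trivial[lo] - cost[lo]
        if abs(denom) < 1e-12:
            # mixing cannot move the rate; fall back to no mixing
            p = 0.0
        else:
            p = (cost[hi] - cost[lo]) / denom
        mix[lo] = float(np.clip(p, 0.0, 1.0))
    return DecisionPolicy(
        kind="mixing_rates",
        params={
            "mix_prob": {"0": mix[0], "1": mix[1]},
            "base_rate": {"0": base_rate[0], "1": base_rate[1]},
            "variant": variant,
        },
    )


# ---------------------------------------------------------------------------
# EPP — derived equalized-odds predictor (linear program)


def fit_epp(ctx: FitContext) -> DecisionPolicy:
    """Randomized derived predictor achieving equalized odds.

    Solves the linear program over the four conditional output
    probabilities p(g, yhat) = P(output 1 | group g, base prediction yhat):
    minimize expected misclassification subject to the post-policy TPR and
    FPR being exactly equal across groups.  The program is always feasible
    (constant predictors satisfy the constraints).  The returned policy
    stores the equivalent flip probabilities.
    """
    data = ctx.data
    _require_cells(data)
    rates = _base_group_rates(data)
    w = _cell_masses(data)
    # variables x = [p00, p01, p10, p11], p[g, yhat]
    c = np.zeros(4)
    for g in (0, 1):
        tpr, fpr = rates[g]
        c[2 * g + 0] = -w[(g, 1)] * (1 - tpr) + w[(g, 0)] * (1 - fpr)
        c[2 * g + 1] = -w[(g, 1)] * tpr + w[(g, 0)] * fpr
    # tiny preference for the identity (p_g0=0, p_g1=1) among ties
    c = c + 1e-9 * np.array([1.0, -1.0, 1.0, -1.0])
    tpr0, fpr0 = rates[0]
    tpr1, fpr1 = rates[1]
    a_eq = np.array(
        [
            [1 - tpr0, tpr0, -(1 - tpr1), -tpr1],
            [1 - fpr0, fpr0, -(1 - fpr1), -fpr1],
        ]
    )
    res = optimize.linprog(
        c, A_eq=a_eq, b_eq=np.zeros(2), bounds=[(0.0, 1.0)] * 4, method="highs"
    )
    if not res.success:
        raise ConvergenceError(
            "equalized-odds linear program failed", {"status": res.status, "message": res.message}
        )
    p00, p01, p10, p11 = np.clip(res.x, 0.0, 1.0)
    flip = {
        "0": {"0": float(p00), "1": float(1 - p01)},
        "1": {"0": float(p10), "1": float(1 - p11)},
    }
    return DecisionPolicy(kind="flip_rates", params={"flip": flip, "method": "epp"})


# ---------------------------------------------------------------------------
# ROC — reject-option flipping inside a margin around the boundary


def fit_roc(ctx: FitContext) -> DecisionPolicy:
    """Reject-option classification guided by the equal opportunity gap.

    Scans a margin grid (default 0 to 0.5 in steps of 0.01) and returns the
    smallest margin whose flip-region policy brings the validation EOp
    inside the target band (default 0.05).  If no margin reaches the band,
    the EOp-minimizing margin is returned (smallest among ties).
    """
    data = ctx.data
    _require_cells(data)
    band = float(ctx.settings.get("eop_band", 0.05))
    step = float(ctx.settings.get("margin_step", 0.01))
    margins = np.arange(0.0, 0.5 + step / 2, step)
    best_m, best_gap = 0.0, np.inf
    for m in margins:
        policy = DecisionPolicy(kind="flip_region", params={"margin": float(m)})
        try:
            gap = eop(confusion_by_group(data.with_labels(apply_policy(policy, data))))
        except ZeroDivisionError:  # pragma: no cover - cells checked above
            continue
        if gap <= band:
            return DecisionPolicy(kind="flip_region", params={"margin": float(m)})
        if gap < best_gap - 1e-12:
            best_gap, best_m = gap, float(m)
    return DecisionPolicy(kind="flip_region", params={"margin": best_m})


# ---------------------------------------------------------------------------
# PSTA — population-sensitivity-guided threshold adjustment


def _tpr_fpr_at(data: GroupedScores, mask: np.ndarray, thr: float) -> tuple[float, float]:
    pred = data.score[mask] >= thr
    y = data.true_label[mask]
    pos, neg = y == 1, y == 0
    tpr = float(np.mean(pred[pos])) if pos.any() else np.nan
    fpr = float(np.mean(pred[neg])) if neg.any() else np.nan
    return tpr, fpr


def fit_psta(ctx: FitContext) -> DecisionPolicy:
    """Align unprivileged-group sensitivity with the whole population.

    The privileged threshold stays at 0.5.  The unprivileged threshold is
    chosen from the sorted unique validation scores (plus 0.5) to bring the
    unprivileged TPR closest to the population TPR at 0.5, subject to the
    unprivileged FPR staying below the population FPR plus a slack
    (default 0.10, ``settings["fpr_slack"]``).  Ties prefer the threshold
    closest to 0.5, then the larger threshold (least intervention).
    """
    data = ctx.data
    _require_cells(data)
    slack = float(ctx.settings.get("fpr_slack", 0.10))
    all_mask = np.ones(data.n, dtype=bool)
    pop_tpr, pop_fpr = _tpr_fpr_at(data, all_mask, 0.5)
    unpriv = data.group == 0
    candidates = np.unique(np.concatenate([data.score[unpriv], [0.5]]))
    best = None
    for thr in candidates:
        tpr, fpr = _tpr_fpr_at(data, unpriv, float(thr))
        if fpr > pop_fpr + slack + 1e-12:
            continue
        key = (abs(tpr - pop_tpr), abs(thr - 0.5), -thr)
        if best is None or key < best[0]:
            best = (key, float(thr))
    if best is None:
        # every candidate violates the FPR ceiling; keep the unmitigated rule
        best = (None, 0.5)
    return DecisionPolicy(
        kind="group_thresholds",
        params={"thresholds": {"0": best[1], "1": 0.5}, "method": "psta"},
    )


# ---------------------------------------------------------------------------
# FACT — confusion-tensor flip rates trading accuracy against EOp


def fit_fact(ctx: FitContext) -> DecisionPolicy:
    """Optimize per-group per-prediction flip rates on the confusion tensor.

    Minimizes expected misclassification plus ``lambda_`` times the
    post-policy equal opportunity gap over the four flip probabilities
    q(g, yhat).  The objective is piecewise linear in the rates, so the
    exact minimizer is found with a small linear program (the |TPR gap|
    enters through an epigraph variable).  A microscopic penalty on the
    total flip mass prefers the identity among equivalent optima.
    """
    data = ctx.data
    _require_cells(data)
    lam = float(ctx.settings.get("lambda", 1.0))
    rates = _base_group_rates(data)
    w = _cell_masses(data)
    # variables x = [q00, q01, q10, q11, t]; q[g, yhat] flip probabilities
    # postTPR_g = tpr_g (1 - q_g1) + (1 - tpr_g) q_g0
    # postFPR_g = fpr_g (1 - q_g1) + (1 - fpr_g) q_g0
    c = np.zeros(5)
    for g in (0, 1):
        tpr, fpr = rates[g]
        # d err / d q_g0 and q_g1
        c[2 * g + 0] = -w[(g, 1)] * (1 - tpr) + w[(g, 0)] * (1 - fpr)
        c[2 * g + 1] = w[(g, 1)] * tpr - w[(g, 0)] * fpr
    c[4] = lam
    c[:4] += 1e-9  # prefer fewer flips among ties
    tpr0, _ = rates[0]
    tpr1, _ = rates[1]
    # dTPR = postTPR0 - postTPR1 = (tpr0 - tpr1) + a . q
    a = np.array([1 - tpr0, -tpr0, -(1 - tpr1), tpr1])
    d0 = tpr0 - tpr1
    a_ub = np.vstack([np.append(a, -1.0), np.append(-a, -1.0)])
    b_ub = np.array([-d0, d0])
    bounds = [(0.0, 1.0)] * 4 + [(0.0, None)]
    res = optimize.linprog(c, A_ub=a_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if not res.success:
        raise ConvergenceError(
            "confusion-tensor program failed", {"status": res.status, "message": res.message}
        )
    q = np.clip(res.x[:4], 0.0, 1.0)
    flip = {
        "0": {"0": float(q[0]), "1": float(q[1])},
        "1": {"0": float(q[2]), "1": float(q[3])},
    }
    return DecisionPolicy(kind="flip_rates", params={"flip": flip, "method": "fact"})


# ---------------------------------------------------------------------------
# GSTAR — smoothed group-specific thresholds trading error against EOd


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = len(x)
    if n < 2:
        return 1e-3
    std = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    scale = min(std, iqr / 1.34) if iqr > 0 else std
    if scale <= 0:
        return 1e-3
    return max(0.9 * scale * n ** (-1 / 5), 1e-3)


class _SmoothedRates:
    """Kernel-smoothed group-conditional exceedance curves.

    For each (group, class) cell the empirical score sample is smoothed
    with a Gaussian kernel (Silverman bandwidth), giving differentiable
    surrogates of TPR_g(theta) and FPR_g(theta).
    """

    def __init__(self, data: GroupedScores):
        self.samples: dict[tuple[int, int], np.ndarray] = {}
        self.bandwidth: dict[tuple[int, int], float] = {}
        for g in (0, 1):
            for cls in (0, 1):
                s = data.score[(data.group == g) & (data.true_label == cls)]
                self.samples[(g, cls)] = s
                self.bandwidth[(g, cls)] = _silverman_bandwidth(s)
        self.mass = _cell_masses(data)

    def exceed(self, g: int, cls: int, theta) -> np.ndarray:
        """Smoothed P(score >= theta | group g, class cls)."""
        s = self.samples[(g, cls)]
        h = self.bandwidth[(g, cls)]
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        z = (s[None, :] - theta[:, None]) / h
        return stats.norm.cdf(z).mean(axis=1)

    def objective(self, theta0, theta1, lam: float) -> np.ndarray:
        """Smoothed classification error + lam * smoothed EOd."""
        theta0 = np.atleast_1d(theta0)
        theta1 = np.atleast_1d(theta1)
        tpr0 = self.exceed(0, 1, theta0)
        fpr0 = self.exceed(0, 0, theta0)
        tpr1 = self.exceed(1, 1, theta1)
        fpr1 = self.exceed(1, 0, theta1)
        err = (
            self.mass[(0, 1)] * (1 - tpr0)
            + self.mass[(0, 0)] * fpr0
            + self.mass[(1, 1)] * (1 - tpr1)
            + self.mass[(1, 0)] * fpr1
        )
        eod_s = 0.5 * (np.abs(tpr0 - tpr1) + np.abs(fpr0 - fpr1))
        return err + lam * eod_s


def fit_gstar(ctx: FitContext) -> DecisionPolicy:
    """Group-specific thresholds minimizing smoothed error + lambda * EOd.

    Group-conditional score distributions are kernel-smoothed (Gaussian,
    Silverman bandwidth) so the error and equalized-odds surrogates are
    smooth in the thresholds.  A full grid over the empirical scores of
    each group seeds a Nelder-Mead refinement.  ``settings["lambda"]``
    (default 1.0) weighs fairness against error; ``lambda=0`` recovers the
    per-group error-minimizing thresholds.
    """
    data = ctx.data
    _require_cells(data)
    lam = float(ctx.settings.get("lambda", 1.0))
    sm = _SmoothedRates(data)

    def grid_for(g: int) -> np.ndarray:
        s = np.unique(data.score[data.group == g])
        cand = np.unique(np.concatenate([s, [0.5]]))
        if len(cand) > 80:  # thin dense grids; refinement recovers precision
            cand = cand[np.linspace(0, len(cand) - 1, 80).round().astype(int)]
        return cand

    g0, g1 = grid_for(0), grid_for(1)
    t0, t1 = np.meshgrid(g0, g1, indexing="ij")
    obj = sm.objective(t0.ravel(), t1.ravel(), lam).reshape(t0.shape)
    i, j = np.unravel_index(np.argmin(obj), obj.shape)
    start = np.array([g0[i], g1[j]])
    res = optimize.minimize(
        lambda th: float(sm.objective(th[0], th[1], lam)[0]),
        start,
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 400},
    )
    theta = np.clip(res.x if res.fun <= obj[i, j] else start, 0.0, 1.0)
    return DecisionPolicy(
        kind="group_thresholds",
        params={
            "thresholds": {"0": float(theta[0]), "1": float(theta[1])},
            "method": "gstar",
            "lambda": lam,
        },
    )


# ---------------------------------------------------------------------------
# MAB — multiaccuracy boosting via an auditor on residuals


def fit_mab(ctx: FitContext) -> DecisionPolicy:
    """Iterative multiplicative-logit corrections from a residual auditor.

    Each round fits a ridge-regression auditor on the features to the
    current residuals (truth minus score).  The auditor's prediction h(x)
    acts as a soft region indicator; the detected violation is the
    |h|-weighted mean residual |E[h r]| / E[|h|], i.e. the mean absolute
    residual over the region the auditor points at.  While the violation
    exceeds the tolerance ``alpha`` (default 0.01), the scores receive a
    logit-space correction of step ``eta`` (default 0.1) in the auditor's
    direction; a round is accepted only if it strictly reduces the
    violation.  Stops after ``max_rounds`` (default 50) or when no
    violation remains.  Note the audit has a sampling noise floor of order
    sigma * sqrt(d/n), so on small validation sets corrections may chase
    noise until the acceptance rule halts them.  The protected attribute
    is never an input: the auditor sees only ``ctx.data.features``.
    """
    data = ctx.data
    if data.features is None:
        raise FitError("multiaccuracy boosting requires features in the fit context")
    for c in (0, 1):
        if not np.any(data.true_label == c):
            raise FitError(f"validation data has no instances of class {c}")
    alpha = float(ctx.settings.get("alpha", 0.01))
    eta = float(ctx.settings.get("eta", 0.1))
    max_rounds = int(ctx.settings.get("max_rounds", 50))
    ridge_alpha = float(ctx.settings.get("ridge_alpha", 1.0))
    eps = 1e-6
    x = data.features
    y = data.true_label.astype(float)
    score = np.clip(data.score, eps, 1 - eps)
    logit = np.log(score / (1 - score))

    def audit(cur_logit: np.ndarray):
        s = 1 / (1 + np.exp(-cur_logit))
        r = y - s
        model = Ridge(alpha=ridge_alpha).fit(x, r)
        h = model.predict(x)
        mass = float(np.mean(np.abs(h)))
        violation = 0.0 if mass < 1e-12 else abs(float(np.mean(h * r))) / mass
        return model, violation

    steps: list[dict] = []
    model, violation = audit(logit)
    for _ in range(max_rounds):
        if violation <= alpha:
            break
        h = model.predict(x)
        cand_logit = logit + eta * h
        cand_model, cand_violation = audit(cand_logit)
        if cand_violation >= violation:  # correction no longer helps
            break
        steps.append(
            {
                "coef": [float(v) for v in np.ravel(model.coef_)],
                "intercept": float(model.intercept_),
                "eta": eta,
            }
        )
        logit = cand_logit
        model, violation = cand_model, cand_violation
    return DecisionPolicy(
        kind="score_corrections",
        params={"steps": steps, "logit_clip": eps, "method": "mab"},
    )


#: Registry of fit functions by their field acronyms (plus the identity).
METHODS: dict[str, Callable[[FitContext], DecisionPolicy]] = {
    "identity": fit_identity,
    "cpp": fit_cpp,
    "epp": fit_epp,
    "roc": fit_roc,
    "psta": fit_psta,
    "fact": fit_fact,
    "gstar": fit_gstar,
    "mab": fit_mab,
}
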