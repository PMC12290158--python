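"""Model adapters: anything that emits class-1 probabilities in [0, 1].

The benchmark is model-agnostic; debiasing is pure post-processing.  An
adapter needs two methods::

    fit(X, y)            # train on a feature matrix and 0/1 labels
    predict_scores(X)    # class-1 probabilities, shape (n,), in [0, 1]

Shipped adapters wrap regularized logistic regression (the default linear
model) and gradient-boosted trees via XGBoost (optional; imported lazily so
the dependency stays optional).
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import LogisticRegression

from .errors import AdapterContractError

__all__ = ["LogisticAdapter", "XGBoostAdapter", "MODEL_REGISTRY", "validate_scores"]


def validate_scores(scores: np.ndarray) -> np.ndarray:
    """Enforce the adapter contract: a (n,) vector of probabilities."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or not np.isfinite(scores).all():
        raise AdapterContractError("adapter must emit a finite 1-D score vector")
    if scores.size and (scores.min() < 0 or scores.max() > 1):
        raise AdapterContractError("adapter scores must lie in [0, 1]")
    return scores


class LogisticAdapter:
    """L2-regularized logistic regression (scikit-learn, lbfgs)."""

    def __init__(self, C: float = 1.0, max_iter: int = 1000, seed: int = 0):
        self._model = LogisticRegression(
            C=C, max_iter=max_iter, random_state=seed, solver="lbfgs"
        )

    def fit(self, X, y) -> "LogisticAdapter":
        self._model.fit(X, y)
        return self

    def predict_scores(self, X) -> np.ndarray:
        return validate_scores(self._model.predict_proba(X)[:, 1])


class XGBoostAdapter:
    """Gradient-boosted trees via XGBoost (optional dependency)."""

    def __init__(self, n_estimators: int = 100, max_depth: int = 3, seed: int = 0, **kw):
        import xgboost  # deferred: optional extra

        self._model = xgboost.XGBClassifier(
            n_estimators=n_estimators,
            max_depth=max_depth,
            random_state=seed,
            eval_metric="logloss",
            **kw,
        )

    def fit(self, X, y) -> "XGBoostAdapter":
        self._model.fit(X, y)
        return self

    def predict_scores(self, X) -> np.ndarray:
        return validate_scores(self._model.predict_proba(X)[:, 1])


MODEL_REGISTRY = {
    "logistic": LogisticAdapter,
    "xgboost": XGBoostAdapter,
}
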