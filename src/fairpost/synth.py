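"""Synthetic biased tabular data and unprivileged-group-rate resampling.

The generator draws a two-feature, two-class dataset from class-conditional
bivariate Gaussians,

.. math::

    X \\mid Y=1 \\sim \\mathcal N\\!\\left((2,\\,2+s),
        \\begin{pmatrix}5&1\\\\1&5\\end{pmatrix}\\right), \\qquad
    X \\mid Y=0 \\sim \\mathcal N\\!\\left((-2,\\,-(2+s)),
        \\begin{pmatrix}10&1\\\\1&3\\end{pmatrix}\\right),

where the shift ``s`` moves the class means apart along the second feature
and therefore controls the separability of the learning task (``s=-1`` low,
``s=0`` medium, ``s=+1`` high separation).  The binary protected attribute is
the sign of the first feature, ``a = sgn(x0)``, which couples group
membership to the class structure: under ``s=0`` roughly 18.6% of the
favorable class but 73.6% of the unfavorable class fall in the unprivileged
group (``x0 < 0``), producing a structurally biased dataset without any
explicit label noise.

The second half of the module resamples such a dataset to a target
unprivileged group rate (UGR) while keeping the classes exactly balanced,
with cell-wise *nesting*: the rows drawn for a smaller demand in any
(group, class) cell are a prefix of the rows drawn for a larger demand, so
training sets at different UGR levels share as many rows as the cell
demands permit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .errors import InfeasiblePlanError, InvalidArgumentError, SchemaError

__all__ = [
    "SyntheticConfig",
    "TabularDataset",
    "UgrPlan",
    "simulate_dataset",
    "assign_protected",
    "plan_ugr",
    "resample_to_ugr",
    "make_cv_folds",
]

#: Covariance of the favorable (Y=1) class-conditional Gaussian.
POSITIVE_COV = np.array([[5.0, 1.0], [1.0, 5.0]])
#: Covariance of the unfavorable (Y=0) class-conditional Gaussian.
NEGATIVE_COV = np.array([[10.0, 1.0], [1.0, 3.0]])


def class_means(s: float) -> tuple[np.ndarray, np.ndarray]:
    """Class-conditional mean vectors (positive, negative) for shift ``s``."""
    return np.array([2.0, 2.0 + s]), np.array([-2.0, -(2.0 + s)])


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic generator.

    Parameters
    ----------
    s
        Separation shift applied to the second-feature mean of both classes
        (positive class up, negative class down).  Unitless.
    n_per_class
        Number of rows drawn per class; the output has ``2 * n_per_class``
        rows and is exactly class balanced.
    seed
        Seed for the random draw; the same config always yields the same
        dataset.
    """

    s: float = 0.0
    n_per_class: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise InvalidArgumentError(
                f"n_per_class must be >= 1, got {self.n_per_class}"
            )
        # The covariances are fixed constants of the model; both are
        # positive definite (checked once here as a guard against edits).
        for cov in (POSITIVE_COV, NEGATIVE_COV):
            if np.any(np.linalg.eigvalsh(cov) <= 0):  # pragma: no cover
                raise InvalidArgumentError("class covariance not positive definite")


@dataclass
class TabularDataset:
    """Features, binary labels and named binary protected attributes.

    Labels use 1 for the favorable outcome.  Protected attributes use 0 for
    the unprivileged group.  ``ids`` are stable row identifiers that survive
    subsetting, which is what makes nesting checks on resampled training
    sets possible.
    """

    features: np.ndarray
    labels: np.ndarray
    protected: dict[str, np.ndarray]
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    feature_names: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise InvalidArgumentError("features must be a 2-D matrix")
        n = self.features.shape[0]
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (n,):
            raise InvalidArgumentError("labels length must match features")
        if not np.isin(self.labels, (0, 1)).all():
            raise InvalidArgumentError("labels must be binary 0/1")
        clean: dict[str, np.ndarray] = {}
        for name, col in self.protected.items():
            col = np.asarray(col, dtype=int)
            if col.shape != (n,):
                raise InvalidArgumentError(f"protected column {name!r} has wrong length")
            if not np.isin(col, (0, 1)).all():
                raise InvalidArgumentError(f"protected column {name!r} must be binary 0/1")
            clean[name] = col
        self.protected = clean
        if self.ids is None:
            self.ids = np.arange(n)
        else:
            self.ids = np.asarray(self.ids, dtype=int)
            if self.ids.shape != (n,):
                raise InvalidArgumentError("ids length must match features")
            if len(np.unique(self.ids)) != n:
                raise InvalidArgumentError("row identifiers must be unique")
        if self.feature_names is None:
            self.feature_names = [f"x{j}" for j in range(self.features.shape[1])]

    @property
    def n(self) -> int:
        return self.features.shape[0]

    def subset(self, index: np.ndarray) -> "TabularDataset":
        """Positional subset preserving row identifiers."""
        index = np.asarray(index)
        return TabularDataset(
            features=self.features[index],
            labels=self.labels[index],
            protected={k: v[index] for k, v in self.protected.items()},
            ids=self.ids[index],
            feature_names=list(self.feature_names),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df["y"] = self.labels
        for name, col in self.protected.items():
            df[name] = col
        df.index = pd.Index(self.ids, name="id")
        return df

    def to_csv(self, path, schema_path=None) -> None:
        from .io import save_tabular

        save_tabular(self, path, schema_path=schema_path)

    @classmethod
    def from_csv(cls, path, schema) -> "TabularDataset":
        from .io import load_tabular

        return load_tabular(path, schema)


def assign_protected(x0):
    """Protected group from the sign of the first feature.

    ``x0 < 0`` maps to the unprivileged group (0); ``x0 > 0`` maps to the
    privileged group (1).  ``x0 == 0`` — a probability-zero event under the
    continuous model — is mapped to the privileged group by convention.
    Accepts scalars or arrays.
    """
    arr = np.asarray(x0, dtype=float)
    if not np.isfinite(arr).all():
        raise InvalidArgumentError("x0 must be finite")
    out = np.where(arr < 0, 0, 1)
    if np.isscalar(x0) or arr.ndim == 0:
        return int(out)
    return out


def simulate_dataset(config: SyntheticConfig) -> TabularDataset:
    """Draw a class-balanced biased dataset from the two Gaussians.

    Returns ``2 * config.n_per_class`` rows (favorable class first), with
    the protected attribute column ``"A"`` derived from the sign of ``x0``.
    """
    rng = np.random.default_rng(config.seed)
    mean_pos, mean_neg = class_means(config.s)
    n = config.n_per_class
    x_pos = rng.multivariate_normal(mean_pos, POSITIVE_COV, size=n)
    x_neg = rng.multivariate_normal(mean_neg, NEGATIVE_COV, size=n)
    features = np.vstack([x_pos, x_neg])
    labels = np.concatenate([np.ones(n, dtype=int), np.zeros(n, dtype=int)])
    protected = {"A": assign_protected(features[:, 0])}
    return TabularDataset(features=features, labels=labels, protected=protected)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class UgrPlan:
    """Demanded per-cell counts realizing a target unprivileged group rate.

    ``cells`` maps ``(group, label)`` to the demanded count.  The plan keeps
    the two classes exactly balanced and, within each group, splits rows
    evenly across classes, so the four demands are determined by the total
    size ``m`` and the target rate alone.
    """

    target_ugr: float
    cells: Mapping[tuple[int, int], int]
    m: int
    feasible: bool

    @property
    def achieved_ugr(self) -> float:
        if self.m == 0:
            return float("nan")
        return (self.cells[(0, 0)] + self.cells[(0, 1)]) / self.m


def _cell_supply(dataset: TabularDataset, attribute: str) -> dict[tuple[int, int], int]:
    a = dataset.protected[attribute]
    y = dataset.labels
    return {
        (g, c): int(np.sum((a == g) & (y == c))) for g in (0, 1) for c in (0, 1)
    }


def plan_ugr(
    dataset: TabularDataset, target_ugr: float, attribute: str = "A"
) -> UgrPlan:
    """Find the largest class-balanced subset size hitting a target UGR.

    The search decrements the even total ``m`` from the dataset size until
    the per-class unprivileged demand ``u = round(target_ugr * m / 2)`` and
    privileged demand ``p = m/2 - u`` both fit into the available
    (group, class) cells.  Rounding is half-up, so the achieved UGR differs
    from the target by at most ``1/m``.
    """
    if not 0.0 < target_ugr < 1.0:
        raise InvalidArgumentError(f"target_ugr must be in (0, 1), got {target_ugr}")
    if attribute not in dataset.protected:
        raise SchemaError(f"dataset has no protected attribute {attribute!r}")
    supply = _cell_supply(dataset, attribute)
    m_max = dataset.n - (dataset.n % 2)
    for m in range(m_max, 3, -2):
        u = _round_half_up(target_ugr * m / 2)
        p = m // 2 - u
        if u < 0 or p < 0:
            continue
        if (
            u <= supply[(0, 1)]
            and u <= supply[(0, 0)]
            and p <= supply[(1, 1)]
            and p <= supply[(1, 0)]
        ):
            cells = {(0, 1): u, (0, 0): u, (1, 1): p, (1, 0): p}
            return UgrPlan(target_ugr=target_ugr, cells=cells, m=m, feasible=True)
    return UgrPlan(
        target_ugr=target_ugr,
        cells={(0, 1): 0, (0, 0): 0, (1, 1): 0, (1, 0): 0},
        m=0,
        feasible=False,
    )


def resample_to_ugr(
    dataset: TabularDataset,
    plans: Sequence[UgrPlan],
    seed: int = 0,
    attribute: str = "A",
) -> list[TabularDataset]:
    """Materialize nested subsets for a sorted sequence of UGR plans.

    One seeded permutation is drawn per (group, class) cell; every plan
    takes its demanded count as a prefix of that permutation.  Consequently,
    within any cell, the row-identifier set selected for a smaller demand is
    a subset of the set selected for a larger demand (cell-wise nesting),
    regardless of plan order.
    """
    if attribute not in dataset.protected:
        raise SchemaError(f"dataset has no protected attribute {attribute!r}")
    targets = [p.target_ugr for p in plans]
    if targets != sorted(targets):
        raise InvalidArgumentError("plans must be sorted by target_ugr")
    for plan in plans:
        if not plan.feasible:
            raise InfeasiblePlanError(
                f"plan for target {plan.target_ugr} is infeasible"
            )
    a = dataset.protected[attribute]
    y = dataset.labels
    perms: dict[tuple[int, int], np.ndarray] = {}
    for g in (0, 1):
        for c in (0, 1):
            cell_idx = np.flatnonzero((a == g) & (y == c))
            rng = np.random.default_rng(np.random.SeedSequence([seed, g, c]))
            perms[(g, c)] = rng.permutation(cell_idx)
    out = []
    for plan in plans:
        parts = []
        for cell, demand in plan.cells.items():
            if demand > len(perms[cell]):
                raise InfeasiblePlanError(
                    f"cell {cell} demand {demand} exceeds supply {len(perms[cell])}"
                )
            parts.append(perms[cell][:demand])
        index = np.sort(np.concatenate(parts))
        out.append(dataset.subset(index))
    return out


def make_cv_folds(
    dataset: TabularDataset, k: int = 5, seed: int = 0
) -> list[np.ndarray]:
    """Stratified k-fold test index sets, stratified by (class, group).

    Strata combine the label with every protected attribute; if any stratum
    is smaller than ``k`` the stratification falls back to the label alone.
    Returns ``k`` pairwise-disjoint positional index arrays covering all
    rows; reproducible for a given seed.
    """
    if k < 2:
        raise InvalidArgumentError(f"k must be >= 2, got {k}")
    if k > dataset.n:
        raise InvalidArgumentError(f"k={k} exceeds dataset size {dataset.n}")
    key = dataset.labels.astype(str)
    for name in dataset.protected:
        key = np.char.add(np.char.add(key, "|"), dataset.protected[name].astype(str))
    _, counts = np.unique(key, return_counts=True)
    if counts.min() < k:
        key = dataset.labels.astype(str)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(dataset.n), key)]
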