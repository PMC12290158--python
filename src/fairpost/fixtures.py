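"""Deterministic small datasets used by the test suite and examples.

Every fixture is generated programmatically (synthetic throughout — no
real data is bundled) and written as CSV plus a YAML schema, byte-identical
across calls with the same parameters.

Registered fixtures
-------------------
``toy-scores``
    24 handcrafted score/label/group triples with a known fairness gap.
``two-attr-correlated``
    A dataset with two protected attributes whose Spearman correlation is
    planted (default rho = -0.5), for spillover analyses.
``planted-bias``
    One informative feature plus a subgroup indicator; the score column
    carries a +0.3 bias on the indicated subgroup, the target the
    multiaccuracy auditor must find and remove.
``paper-synthetic``
    The 2000-row class-balanced Gaussian dataset (1000 per class, s = 0)
    that anchors the attribute-imbalance experiments.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidArgumentError
from .io import save_tabular
from .synth import SyntheticConfig, TabularDataset, simulate_dataset

__all__ = ["generate_fixture", "FIXTURES", "toy_scores_frame", "planted_bias_data", "two_attr_dataset"]


def toy_scores_frame() -> pd.DataFrame:
    """24 deterministic (score, y, group) rows with unequal group TPRs."""
    rows = []
    # group 1 (privileged): well-separated scores, TPR 5/6 at 0.5
    g1_pos = [0.92, 0.85, 0.77, 0.66, 0.58, 0.42]
    g1_neg = [0.45, 0.38, 0.31, 0.22, 0.15, 0.08]
    # group 0 (unprivileged): depressed scores, TPR 3/6 at 0.5
    g0_pos = [0.81, 0.63, 0.55, 0.47, 0.36, 0.28]
    g0_neg = [0.52, 0.41, 0.33, 0.24, 0.18, 0.05]
    for g, y, scores in (
        (1, 1, g1_pos),
        (1, 0, g1_neg),
        (0, 1, g0_pos),
        (0, 0, g0_neg),
    ):
        rows += [{"score": s, "y": y, "group": g} for s in scores]
    return pd.DataFrame(rows)


def two_attr_dataset(rho: float = -0.5, n: int = 1000, seed: int = 7) -> TabularDataset:
    """Two binary protected attributes with planted Spearman correlation.

    Both attributes are symmetric Bernoulli(1/2); the second equals the
    first with probability (1 + rho) / 2, which yields a phi (and hence
    Spearman) coefficient of ``rho`` in expectation.
    """
    if not -1.0 <= rho <= 1.0:
        raise InvalidArgumentError("rho must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    a1 = rng.integers(0, 2, size=n)
    agree = rng.random(n) < (1 + rho) / 2
    a2 = np.where(agree, a1, 1 - a1)
    x = rng.normal(size=(n, 2)) + np.column_stack([a1, a2]) * 1.5
    logits = 0.8 * x[:, 0] + 0.8 * x[:, 1] - 1.2
    y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
    # guard against degenerate draws at small n
    if y.min() == y.max():  # pragma: no cover
        y[0] = 1 - y[0]
    return TabularDataset(
        features=x, labels=y, protected={"A1": a1, "A2": a2}
    )


def planted_bias_data(n: int = 600, bias: float = 0.3, seed: int = 11):
    """Features, labels and scores with a planted subgroup score bias.

    The truth is Bernoulli(0.5) independent of the features; the score is
    the calibrated 0.5 everywhere except the subgroup flagged by the
    second feature, where ``bias`` is added.  Returns (features, y, score).
    """
    rng = np.random.default_rng(seed)
    x0 = rng.uniform(-2, 2, size=n)
    flag = (x0 > 1).astype(float)
    features = np.column_stack([x0, flag])
    y = rng.integers(0, 2, size=n)
    score = np.clip(0.5 + bias * flag, 0.0, 1.0)
    return features, y, score


def _write_paper_synthetic(outdir: Path, seed: int = 42, **kw) -> list[Path]:
    ds = simulate_dataset(SyntheticConfig(s=0.0, n_per_class=1000, seed=seed))
    csv, schema = outdir / "paper-synthetic.csv", outdir / "paper-synthetic.schema.yaml"
    save_tabular(ds, csv, schema_path=schema)
    return [csv, schema]


def _write_toy_scores(outdir: Path, **kw) -> list[Path]:
    path = outdir / "toy-scores.csv"
    toy_scores_frame().to_csv(path, index=False)
    return [path]


def _write_two_attr(outdir: Path, rho: float = -0.5, n: int = 1000, seed: int = 7, **kw):
    ds = two_attr_dataset(rho=rho, n=n, seed=seed)
    csv = outdir / "two-attr-correlated.csv"
    schema = outdir / "two-attr-correlated.schema.yaml"
    save_tabular(ds, csv, schema_path=schema)
    return [csv, schema]


def _write_planted_bias(outdir: Path, n: int = 600, bias: float = 0.3, seed: int = 11, **kw):
    features, y, score = planted_bias_data(n=n, bias=bias, seed=seed)
    df = pd.DataFrame({"x0": features[:, 0], "x1": features[:, 1], "y": y, "score": score})
    path = outdir / "planted-bias.csv"
    df.to_csv(path, index=False)
    return [path]


FIXTURES = {
    "toy-scores": _write_toy_scores,
    "two-attr-correlated": _write_two_attr,
    "planted-bias": _write_planted_bias,
    "paper-synthetic": _write_paper_synthetic,
}


def generate_fixture(name: str, outdir, **params) -> list[Path]:
    """Write a registered fixture to ``outdir``; returns the paths written."""
    if name not in FIXTURES:
        raise InvalidArgumentError(
            f"unknown fixture {name!r}; registered: {sorted(FIXTURES)}"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return FIXTURES[name](outdir, **params)
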