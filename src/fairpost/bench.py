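"""Benchmark orchestration: CV evaluation, change tables, imbalance strata,
untreated-attribute impact, and trade-off region proportions.

The harness runs every (dataset, protected attribute, model, method) cell
under stratified k-fold cross-validation with a paired design: each
post-debiasing measurement has an unmitigated measurement from the same
fold, model and seed, so change tables recompute exactly from the raw
results store.  Debiasing policies are fit on the training fold's own
model predictions (optionally on a held-out calibration split) and
applied to the fold's test set.
Optionally the training folds are resampled to target unprivileged group
rates (UGR) while the test sets stay fixed across all UGR settings.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import __version__ as _version
from .debias import (
    METHODS,
    RANDOMIZED_KINDS,
    DecisionPolicy,
    FitContext,
    apply_policy,
)
from .errors import InvalidArgumentError, SchemaError
from .metrics import (
    FairnessReport,
    GroupedScores,
    cliffs_delta,
    evaluate,
)
from .models import MODEL_REGISTRY, validate_scores
from .synth import TabularDataset, make_cv_folds, plan_ugr, resample_to_ugr
from .tradeoff import TradeoffBaseline, build_baseline, classify_region

__all__ = [
    "ImbalanceProfile",
    "ChangeTable",
    "UntreatedImpactSummary",
    "ResultsStore",
    "categorize_imbalance",
    "dataset_profile",
    "run_benchmark",
    "change_table",
    "untreated_impact",
    "correlation_vs_impact",
    "build_baselines",
    "regions_table",
    "proportion_over_baseline",
    "substream_seed",
]

METRICS = ("acc", "bacc", "f1", "eop", "eod")
FAIRNESS_METRICS = ("eop", "eod")


def substream_seed(seed: int, *keys) -> int:
    """Derive a named substream seed from the single run seed.

    Keys (strings or ints) are hashed with CRC-32 and folded into a
    SeedSequence, so every (stage, case) pair gets an independent,
    reproducible stream below 2**31.
    """
    parts = [int(seed)] + [zlib.crc32(str(k).encode()) for k in keys]
    return int(np.random.SeedSequence(parts).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# imbalance stratification


@dataclass(frozen=True)
class ImbalanceProfile:
    """Favorable-class proportion and unprivileged group rate with levels.

    ``class_level`` follows the FCP intervals [0, 0.25) low, [0.25, 0.75)
    medium, [0.75, 1] high; ``attr_level`` follows the UGR intervals
    [0, 0.20) low, [0.20, 0.50) medium, [0.50, 1] high.  ``class_severity``
    is the complementary view in which the *outer* FCP intervals (either a
    rare or a dominant favorable class) count as high class imbalance and
    the middle interval as medium.
    """

    fcp: float
    ugr: float
    class_level: str
    attr_level: str

    @property
    def class_severity(self) -> str:
        return "high" if self.class_level in ("low", "high") else "medium"


def categorize_imbalance(fcp: float, ugr: float) -> ImbalanceProfile:
    """Map FCP and UGR onto the printed half-open interval levels."""
    for name, v in (("fcp", fcp), ("ugr", ugr)):
        if not 0.0 <= v <= 1.0:
            raise InvalidArgumentError(f"{name}={v} outside [0, 1]")
    if fcp < 0.25:
        class_level = "low"
    elif fcp < 0.75:
        class_level = "medium"
    else:
        class_level = "high"
    if ugr < 0.20:
        attr_level = "low"
    elif ugr < 0.50:
        attr_level = "medium"
    else:
        attr_level = "high"
    return ImbalanceProfile(fcp=fcp, ugr=ugr, class_level=class_level, attr_level=attr_level)


def dataset_profile(dataset: TabularDataset, attribute: str) -> ImbalanceProfile:
    """Imbalance profile of a dataset w.r.t. one protected attribute."""
    if attribute not in dataset.protected:
        raise SchemaError(f"no protected attribute {attribute!r}")
    fcp = float(np.mean(dataset.labels == 1))
    ugr = float(np.mean(dataset.protected[attribute] == 0))
    return categorize_imbalance(fcp, ugr)


# ---------------------------------------------------------------------------
# the results store


@dataclass
class ResultsStore:
    """Raw benchmark output: metric records, policies, predictions.

    ``records`` has one row per (dataset, treated attribute, evaluated
    attribute, model, method, UGR, fold, phase) with the five metrics.
    ``predictions`` keeps the per-fold test scores and unmitigated labels
    needed to build trade-off baselines; it is held in memory and not
    persisted by :meth:`save` (baselines are recomputed from a fresh run).
    """

    records: pd.DataFrame
    policies: dict[str, str] = field(default_factory=dict)
    predictions: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(outdir / "records.csv", index=False)
        (outdir / "policies.json").write_text(json.dumps(self.policies, indent=1))
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=1))

    @classmethod
    def load(cls, outdir) -> "ResultsStore":
        outdir = Path(outdir)
        records = pd.read_csv(outdir / "records.csv")
        policies = json.loads((outdir / "policies.json").read_text())
        manifest = json.loads((outdir / "manifest.json").read_text())
        return cls(records=records, policies=policies, manifest=manifest)


def _mean_report(reports: Sequence[FairnessReport]) -> FairnessReport:
    return FairnessReport(
        acc=float(np.mean([r.acc for r in reports])),
        bacc=float(np.mean([r.bacc for r in reports])),
        f1=float(np.mean([r.f1 for r in reports])),
        eop=float(np.mean([r.eop for r in reports])),
        eod=float(np.mean([r.eod for r in reports])),
    )


def run_benchmark(
    datasets: Mapping[str, TabularDataset],
    models: Mapping[str, Callable[..., object]] | Sequence[str] = ("logistic",),
    methods: Sequence[str] = ("identity",),
    k: int = 5,
    seed: int = 0,
    ugr_targets: Sequence[float] | None = None,
    fairness_metric: str = "eop",
    settings: dict | None = None,
    calibration_frac: float | None = None,
    n_policy_draws: int = 10,
) -> ResultsStore:
    """Run the full CV benchmark over datasets x attributes x models x methods.

    For every cell and fold the store receives a *before* (unmitigated,
    threshold 0.5) and an *after* (post-policy) metric row, evaluated on
    the treated attribute and on every other protected attribute of the
    dataset (``eval_attribute`` column), plus the serialized policy.
    Policies are fit on the model's own training-fold predictions by
    default; pass ``calibration_frac`` (e.g. 0.25) to instead hold a
    stratified calibration split out of model training and fit policies
    there — preferable for large folds, but with resampled minorities the
    split can leave too few unprivileged rows to estimate group rates.
    Randomized policies are applied ``n_policy_draws`` times with seeded
    streams and their metrics averaged.  ``ugr_targets`` resamples each
    training fold to the given unprivileged group rates (class balance
    preserved, cell-wise nesting across targets) while the test folds stay
    fixed.  The whole run is a pure function of its arguments: same seeds,
    same store.
    """
    settings = settings or {}
    if isinstance(models, Sequence) and not isinstance(models, Mapping):
        models = {name: MODEL_REGISTRY[name] for name in models}
    for m in methods:
        if m not in METHODS:
            raise InvalidArgumentError(f"unknown method {m!r}")
    rows: list[dict] = []
    policies: dict[str, str] = {}
    predictions: dict = {}
    ugr_list: list[float | None] = list(ugr_targets) if ugr_targets else [None]
    if ugr_targets:
        ugr_list = sorted(ugr_list)  # resampling requires sorted plans

    for ds_name, dataset in datasets.items():
        folds = make_cv_folds(dataset, k=k, seed=substream_seed(seed, "folds", ds_name))
        attr_names = list(dataset.protected)
        for fold_i, test_idx in enumerate(folds):
            train_mask = np.ones(dataset.n, dtype=bool)
            train_mask[test_idx] = False
            train_all = dataset.subset(np.flatnonzero(train_mask))
            test = dataset.subset(test_idx)
            # resample the training fold per UGR target (test set fixed)
            if ugr_targets:
                plans = [plan_ugr(train_all, r) for r in ugr_list]
                train_sets = resample_to_ugr(
                    train_all,
                    plans,
                    seed=substream_seed(seed, "ugr", ds_name, fold_i),
                )
            else:
                train_sets = [train_all]
            for ugr_t, train_ds in zip(ugr_list, train_sets):
                if calibration_frac is None:
                    fit_ds = cal_ds = train_ds
                else:
                    fit_idx, cal_idx = train_test_split(
                        np.arange(train_ds.n),
                        test_size=calibration_frac,
                        stratify=train_ds.labels,
                        random_state=substream_seed(seed, "cal", ds_name, fold_i, ugr_t),
                    )
                    fit_ds, cal_ds = train_ds.subset(fit_idx), train_ds.subset(cal_idx)
                for model_name, factory in models.items():
                    adapter = factory(seed=substream_seed(seed, "model", model_name))
                    adapter.fit(fit_ds.features, fit_ds.labels)
                    cal_scores = validate_scores(adapter.predict_scores(cal_ds.features))
                    test_scores = validate_scores(adapter.predict_scores(test.features))
                    before_labels = (test_scores >= 0.5).astype(int)
                    predictions[(ds_name, model_name, ugr_t, fold_i)] = {
                        "y": test.labels,
                        "score": test_scores,
                        "before": before_labels,
                        "groups": {a: test.protected[a] for a in attr_names},
                    }
                    for attribute in attr_names:
                        cal = GroupedScores(
                            score=cal_scores,
                            true_label=cal_ds.labels,
                            group=cal_ds.protected[attribute],
                            features=cal_ds.features,
                        )
                        test_gs = GroupedScores(
                            score=test_scores,
                            true_label=test.labels,
                            group=test.protected[attribute],
                            features=test.features,
                        )
                        ctx = FitContext(
                            data=cal,
                            fairness_metric=fairness_metric,
                            settings=settings,
                            seed=substream_seed(
                                seed, "policy", ds_name, attribute, model_name, fold_i, ugr_t
                            ),
                        )
                        for method in methods:
                            policy = METHODS[method](ctx)
                            case = dict(
                                dataset=ds_name,
                                attribute=attribute,
                                model=model_name,
                                method=method,
                                ugr=np.nan if ugr_t is None else ugr_t,
                                fold=fold_i,
                            )
                            key = "/".join(
                                str(case[c])
                                for c in ("dataset", "attribute", "model", "method", "ugr", "fold")
                            )
                            policies[key] = policy.to_json()
                            after_sets = _apply_with_draws(
                                policy, test_gs, ctx.seed, n_policy_draws
                            )
                            for eval_attr in attr_names:
                                eval_base = GroupedScores(
                                    score=test_scores,
                                    true_label=test.labels,
                                    group=test.protected[eval_attr],
                                )
                                with warnings.catch_warnings():
                                    warnings.simplefilter("ignore")
                                    before = evaluate(eval_base.with_labels(before_labels))
                                    after = _mean_report(
                                        [
                                            evaluate(eval_base.with_labels(lbl))
                                            for lbl in after_sets
                                        ]
                                    )
                                rows.append(
                                    before.to_row(
                                        **case, eval_attribute=eval_attr, phase="before"
                                    )
                                )
                                rows.append(
                                    after.to_row(
                                        **case, eval_attribute=eval_attr, phase="after"
                                    )
                                )
    records = pd.DataFrame(rows)
    manifest = {
        "version": _version,
        "seed": seed,
        "k": k,
        "datasets": list(datasets),
        "models": list(models),
        "methods": list(methods),
        "ugr_targets": None if not ugr_targets else list(ugr_list),
        "fairness_metric": fairness_metric,
        "calibration_frac": calibration_frac,
        "n_policy_draws": n_policy_draws,
    }
    return ResultsStore(
        records=records, policies=policies, predictions=predictions, manifest=manifest
    )


def _apply_with_draws(
    policy: DecisionPolicy, data: GroupedScores, seed: int, n_draws: int
) -> list[np.ndarray]:
    if policy.kind in RANDOMIZED_KINDS:
        return [
            apply_policy(policy, data, seed=substream_seed(seed, "draw", d))
            for d in range(n_draws)
        ]
    return [apply_policy(policy, data, seed=seed)]


# ---------------------------------------------------------------------------
# change tables


@dataclass
class ChangeTable:
    """Per-method absolute and relative metric changes.

    ``table`` is indexed by (method, metric) plus any extra grouping
    columns; ``abs_change`` is mean(after - before) over paired runs,
    ``rel_change_pct`` is mean(100 * (after - before) / before) over the
    pairs whose baseline magnitude exceeds ``denominator_floor`` (the
    excluded count is reported).  Negative values mean performance decline
    but fairness improvement.
    """

    table: pd.DataFrame
    denominator_floor: float = 1e-6

    def to_wide(self) -> pd.DataFrame:
        """Method rows x metric columns, formatted 'abs (rel%)'."""

        def fmt(r):
            if np.isnan(r["rel_change_pct"]):
                return f"{r['abs_change']:+.3f} (–)"
            return f"{r['abs_change']:+.3f} ({r['rel_change_pct']:+.1f}%)"

        flat = self.table.reset_index()
        flat["cell"] = flat.apply(fmt, axis=1)
        extra = [c for c in flat.columns if c not in
                 ("method", "metric", "abs_change", "rel_change_pct", "n", "n_rel_excluded", "cell")]
        return flat.pivot_table(
            index=["method"] + extra, columns="metric", values="cell", aggfunc="first"
        )


def change_table(
    store: ResultsStore,
    by: Sequence[str] = (),
    denominator_floor: float = 1e-6,
) -> ChangeTable:
    """Absolute and relative before/after changes averaged over paired runs.

    Only rows evaluated on the treated attribute enter (untreated-attribute
    spillover is :func:`untreated_impact`'s job).  ``by`` adds grouping
    columns, e.g. ``("ugr",)`` to stratify by unprivileged representation.
    Pairs whose baseline magnitude is below ``denominator_floor`` are
    excluded from the relative mean and counted.
    """
    df = store.records
    df = df[df["eval_attribute"] == df["attribute"]].copy()
    # NaN UGR (no resampling) would vanish from a pivot index; use a sentinel
    df["ugr"] = df["ugr"].fillna(-1.0)
    keys = ["dataset", "attribute", "model", "method", "ugr", "fold"]
    wide = df.pivot_table(index=keys, columns="phase", values=list(METRICS))
    out_rows = []
    group_cols = list(by)
    flat = wide.reset_index()
    for metric in METRICS:
        before = flat[(metric, "before")]
        after = flat[(metric, "after")]
        sub = flat[keys].copy()
        sub.columns = keys
        sub["metric"] = metric
        sub["abs"] = (after - before).to_numpy()
        denom_ok = before.abs().to_numpy() >= denominator_floor
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(
                denom_ok, 100.0 * sub["abs"].to_numpy() / before.to_numpy(), np.nan
            )
        sub["rel"] = rel
        sub["rel_excluded"] = ~denom_ok
        out_rows.append(sub)
    long = pd.concat(out_rows, ignore_index=True)
    grp = long.groupby(["method", "metric"] + group_cols, dropna=False)
    table = grp.agg(
        abs_change=("abs", "mean"),
        rel_change_pct=("rel", "mean"),
        n=("abs", "size"),
        n_rel_excluded=("rel_excluded", "sum"),
    )
    return ChangeTable(table=table, denominator_floor=denominator_floor)


# ---------------------------------------------------------------------------
# untreated-attribute impact


@dataclass
class UntreatedImpactSummary:
    """Spillover of debiasing onto protected attributes it did not treat.

    ``cases`` has one row per (method, fairness metric, dataset, treated,
    untreated, model, UGR) with the mean before/after values across folds,
    the direction of change, and the Cliff's-delta large-effect flag
    computed on the per-fold samples.  ``proportions`` aggregates per
    (method, metric): the shares of cases with increased, decreased and
    unchanged disparity sum to 1.
    """

    cases: pd.DataFrame
    proportions: pd.DataFrame


def untreated_impact(
    store: ResultsStore, effect_threshold: float = 0.428
) -> UntreatedImpactSummary:
    """Proportion of cases where debiasing shifts fairness of other attributes."""
    df = store.records
    df = df[df["eval_attribute"] != df["attribute"]].copy()
    if df.empty:
        raise InvalidArgumentError(
            "no multi-attribute cases in store; untreated impact undefined"
        )
    df["ugr"] = df["ugr"].fillna(-1.0)  # sentinel: NaN cannot live in a pivot index
    case_rows = []
    keys = ["method", "dataset", "attribute", "eval_attribute", "model", "ugr"]
    for metric in FAIRNESS_METRICS:
        wide = df.pivot_table(
            index=keys + ["fold"], columns="phase", values=metric
        ).reset_index()
        for case_key, grp in wide.groupby(keys, dropna=False):
            before = grp["before"].to_numpy()
            after = grp["after"].to_numpy()
            delta = float(np.mean(after) - np.mean(before))
            eff = cliffs_delta(after, before, threshold=effect_threshold)
            case_rows.append(
                dict(
                    zip(keys, case_key),
                    metric=metric,
                    before=float(np.mean(before)),
                    after=float(np.mean(after)),
                    delta=delta,
                    increased=delta > 0,
                    decreased=delta < 0,
                    significant=eff.large,
                    cliffs_delta=eff.delta,
                )
            )
    cases = pd.DataFrame(case_rows)
    cases["ugr"] = cases["ugr"].replace(-1.0, np.nan)
    grp = cases.groupby(["method", "metric"])
    proportions = grp.agg(
        increased=("increased", "mean"),
        decreased=("decreased", "mean"),
        significant_increase=(
            "significant",
            lambda s: float(np.mean(s & cases.loc[s.index, "increased"])),
        ),
        n_cases=("delta", "size"),
    )
    proportions["unchanged"] = 1.0 - proportions["increased"] - proportions["decreased"]
    return UntreatedImpactSummary(cases=cases, proportions=proportions)


def correlation_vs_impact(
    summary: UntreatedImpactSummary,
    corr_tables: Mapping[str, "pd.DataFrame | object"],
    min_cases: int = 3,
) -> pd.DataFrame:
    """Correlate attribute-pair rank correlations with worsening proportions.

    For each (method, fairness metric), the Spearman coefficient between
    the treated/untreated attribute correlation (from ``corr_tables``,
    keyed by dataset; either an :class:`~fairpost.metrics.AttrCorrelation`
    or a plain rho DataFrame) and the per-pair proportion of worsened
    cases.  Rows with fewer than ``min_cases`` pairs or a constant
    proportion are flagged undefined.
    """
    from scipy import stats

    rows = []
    pair_keys = ["dataset", "attribute", "eval_attribute"]
    for (method, metric), grp in summary.cases.groupby(["method", "metric"]):
        per_pair = grp.groupby(pair_keys)["increased"].mean().reset_index()
        xs, ys = [], []
        for _, row in per_pair.iterrows():
            table = corr_tables.get(row["dataset"])
            if table is None:
                continue
            rho = getattr(table, "rho", table)
            try:
                xs.append(float(rho.loc[row["attribute"], row["eval_attribute"]]))
            except KeyError:
                continue
            ys.append(float(row["increased"]))
        defined = len(xs) >= min_cases and len(set(ys)) > 1 and len(set(xs)) > 1
        if defined:
            res = stats.spearmanr(xs, ys)
            coeff, pval = float(res.statistic), float(res.pvalue)
        else:
            coeff, pval = np.nan, np.nan
        rows.append(
            dict(
                method=method,
                metric=metric,
                coefficient=coeff,
                pvalue=pval,
                n_cases=len(xs),
                defined=defined,
            )
        )
    return pd.DataFrame(rows).set_index(["method", "metric"])


# ---------------------------------------------------------------------------
# trade-off baselines and region proportions


def build_baselines(
    store: ResultsStore,
    fairness_metric: str = "eop",
    performance_metric: str = "acc",
    degrees=tuple(np.round(np.arange(0.1, 1.01, 0.1), 2)),
    n_trials: int = 50,
    seed: int = 0,
    healthcare_factor: float = 0.9,
) -> dict[tuple, TradeoffBaseline]:
    """One mutation baseline per (dataset, attribute, model, UGR, fold).

    Requires the in-memory predictions of a fresh :func:`run_benchmark`
    run (a store reloaded from disk has none).
    """
    if not store.predictions:
        raise InvalidArgumentError("store has no predictions; rerun the benchmark")
    baselines: dict[tuple, TradeoffBaseline] = {}
    for (ds, model, ugr_t, fold), pred in store.predictions.items():
        for attr, group in pred["groups"].items():
            gs = GroupedScores(
                score=pred["score"],
                true_label=pred["y"],
                group=group,
                predicted_label=pred["before"],
            )
            baselines[(ds, attr, model, ugr_t, fold)] = build_baseline(
                gs,
                degrees=degrees,
                n_trials=n_trials,
                seed=substream_seed(seed, "mutation", ds, attr, model, ugr_t, fold),
                fairness_metric=fairness_metric,
                performance_metric=performance_metric,
                healthcare_factor=healthcare_factor,
            )
    return baselines


def regions_table(
    store: ResultsStore,
    baselines: Mapping[tuple, TradeoffBaseline],
    fairness_metric: str = "eop",
    performance_metric: str = "acc",
) -> pd.DataFrame:
    """Trade-off region per (case, method, fold) after-measurement."""
    df = store.records
    df = df[(df["eval_attribute"] == df["attribute"]) & (df["phase"] == "after")]
    rows = []
    n_missing = 0
    for _, row in df.iterrows():
        ugr_t = row["ugr"]
        key = (
            row["dataset"],
            row["attribute"],
            row["model"],
            None if pd.isna(ugr_t) else ugr_t,
            row["fold"],
        )
        baseline = baselines.get(key)
        if baseline is None:
            n_missing += 1
            continue
        outcome = classify_region(
            (row[fairness_metric], row[performance_metric]), baseline
        )
        rows.append(
            dict(
                dataset=row["dataset"],
                attribute=row["attribute"],
                model=row["model"],
                method=row["method"],
                ugr=ugr_t,
                fold=row["fold"],
                fairness_metric=fairness_metric,
                performance_metric=performance_metric,
                region=outcome.region,
            )
        )
    table = pd.DataFrame(rows)
    table.attrs["n_missing_baseline"] = n_missing
    return table


def proportion_over_baseline(
    store: ResultsStore,
    baselines: Mapping[tuple, TradeoffBaseline],
    fairness_metric: str = "eop",
    performance_metric: str = "acc",
    healthcare_only: bool = False,
) -> pd.DataFrame:
    """Per-method fraction of cases beating the mutation baseline.

    A case beats the baseline when it lands in the win-win or good
    trade-off regions; with ``healthcare_only`` the good region is
    restricted to its sub-area retaining at least the healthcare factor of
    the origin performance (good-2.2).
    """
    table = regions_table(store, baselines, fairness_metric, performance_metric)
    if table.empty:
        raise InvalidArgumentError("no classifiable cases (missing baselines?)")
    winning = {"win-win", "good-2.2"} if healthcare_only else {
        "win-win",
        "good-2.1",
        "good-2.2",
    }
    out = (
        table.assign(over=table["region"].isin(winning))
        .groupby("method")
        .agg(fraction=("over", "mean"), n_cases=("over", "size"))
    )
    out.attrs["n_missing_baseline"] = table.attrs.get("n_missing_baseline", 0)
    return out
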