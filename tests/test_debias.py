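"""Policy application semantics and the seven fitters vs brute-force oracles."""

import numpy as np
import pytest

from fairpost import (
    DecisionPolicy,
    FitContext,
    GroupedScores,
    apply_policy,
    expected_eod,
    expected_group_rates,
    fit_cpp,
    fit_epp,
    fit_fact,
    fit_gstar,
    fit_mab,
    fit_psta,
    fit_roc,
)
from fairpost.debias import METHODS, _base_group_rates, _cell_masses
from fairpost.errors import FitError, SchemaError
from fairpost.fixtures import planted_bias_data
from fairpost.metrics import confusion_by_group, eop


def _gs(score, y, g, features=None):
    return GroupedScores(
        score=np.asarray(score, float),
        true_label=np.asarray(y, int),
        group=np.asarray(g, int),
        features=features,
    )


def _symmetric_gs():
    """Both groups share identical score/label patterns (already fair)."""
    score = [0.9, 0.8, 0.3, 0.2, 0.6, 0.4] * 2
    y = [1, 1, 1, 0, 0, 0] * 2
    g = [0] * 6 + [1] * 6
    return _gs(score, y, g)


class TestApplyPolicy:
    def test_identity_thresholds_at_half(self):
        data = _gs([0.7, 0.3], [1, 0], [0, 1])
        labels = apply_policy(DecisionPolicy("identity"), data)
        np.testing.assert_array_equal(labels, [1, 0])

    def test_group_thresholds(self):
        pol = DecisionPolicy(
            "group_thresholds", {"thresholds": {"0": 0.4, "1": 0.5}}
        )
        data = _gs([0.45, 0.45], [1, 1], [0, 1])
        np.testing.assert_array_equal(apply_policy(pol, data), [1, 0])

    def test_flip_region_directions(self):
        pol = DecisionPolicy("flip_region", {"margin": 0.1})
        data = _gs([0.45, 0.55, 0.9, 0.1], [1, 1, 1, 0], [0, 1, 1, 0])
        np.testing.assert_array_equal(apply_policy(pol, data), [1, 0, 1, 0])

    def test_mixing_saturated_gives_base_rate_labels(self):
        pol = DecisionPolicy(
            "mixing_rates",
            {"mix_prob": {"0": 1.0, "1": 1.0}, "base_rate": {"0": 0.7, "1": 0.2}},
        )
        data = _gs([0.1, 0.9], [1, 0], [0, 1])
        np.testing.assert_array_equal(apply_policy(pol, data, seed=1), [1, 0])

    def test_randomized_policies_deterministic_given_seed(self):
        pol = DecisionPolicy(
            "flip_rates",
            {"flip": {"0": {"0": 0.5, "1": 0.5}, "1": {"0": 0.5, "1": 0.5}}},
        )
        data = _gs(np.linspace(0.05, 0.95, 40), [0, 1] * 20, [0, 1] * 20)
        a = apply_policy(pol, data, seed=11)
        b = apply_policy(pol, data, seed=11)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, apply_policy(pol, data, seed=12))

    def test_deterministic_policy_reapplication_is_stable(self):
        pol = DecisionPolicy(
            "group_thresholds", {"thresholds": {"0": 0.3, "1": 0.6}}
        )
        data = _gs(np.linspace(0, 1, 21), [0, 1] * 10 + [1], [0, 1] * 10 + [0])
        np.testing.assert_array_equal(
            apply_policy(pol, data), apply_policy(pol, data)
        )

    def test_serialization_roundtrip(self, toy_scores):
        for name, fit in METHODS.items():
            if name == "mab":
                continue
            pol = fit(FitContext(data=toy_scores))
            clone = DecisionPolicy.from_json(pol.to_json())
            np.testing.assert_array_equal(
                apply_policy(pol, toy_scores, seed=3),
                apply_policy(clone, toy_scores, seed=3),
            )

    def test_score_corrections_require_features(self):
        pol = DecisionPolicy(
            "score_corrections", {"steps": [], "logit_clip": 1e-6}
        )
        with pytest.raises(SchemaError):
            apply_policy(pol, _gs([0.5], [1], [0]))


class TestCpp:
    def test_identity_when_already_equal(self):
        pol = fit_cpp(FitContext(data=_symmetric_gs()))
        assert pol.params["mix_prob"] == {"0": 0.0, "1": 0.0}

    def test_single_group_is_fit_error(self):
        data = _gs([0.6, 0.4], [1, 0], [1, 1])
        with pytest.raises(FitError):
            FitContext(data=data)

    def test_mixing_rate_matches_grid_oracle(self, toy_scores):
        """Exhaustive search over p in {0, 0.01, ..., 1} for the mixed group."""
        pol = fit_cpp(FitContext(data=toy_scores))
        mix = {g: pol.params["mix_prob"][str(g)] for g in (0, 1)}
        mixed_group = max(mix, key=mix.get)
        data = toy_scores
        cost, trivial = {}, {}
        for g in (0, 1):
            mask = data.group == g
            pos = mask & (data.true_label == 1)
            cost[g] = np.mean(1 - data.score[pos])
            trivial[g] = 1 - np.mean(data.true_label[mask])
        other = 1 - mixed_group
        best_p, best_gap = 0.0, np.inf
        for p in np.arange(0, 1.0001, 0.01):
            mixed_cost = (1 - p) * cost[mixed_group] + p * trivial[mixed_group]
            gap = abs(mixed_cost - cost[other])
            if gap < best_gap:
                best_gap, best_p = gap, p
        assert mix[mixed_group] == pytest.approx(best_p, abs=0.01)


class TestEpp:
    def test_fair_classifier_needs_no_flips(self):
        pol = fit_epp(FitContext(data=_symmetric_gs()))
        for g in ("0", "1"):
            for yhat in ("0", "1"):
                assert pol.params["flip"][g][yhat] == pytest.approx(0.0, abs=1e-6)

    def test_achieves_equalized_odds(self, toy_scores):
        pol = fit_epp(FitContext(data=toy_scores))
        assert expected_eod(pol, toy_scores) <= 1e-6

    def test_objective_matches_feasible_manifold_oracle(self, toy_scores):
        """Exhaustive scan of the equalized-odds-feasible set.

        Grid p(0, yhat) over [0,1]^2; the two equality constraints then fix
        p(1, yhat) in closed form.  The LP optimum must not exceed the best
        feasible grid objective.
        """
        data = toy_scores
        rates = _base_group_rates(data)
        w = _cell_masses(data)
        (tpr0, fpr0), (tpr1, fpr1) = rates[0], rates[1]
        A = np.array([[1 - tpr1, tpr1], [1 - fpr1, fpr1]])
        best = np.inf
        for p00 in np.arange(0, 1.0001, 0.01):
            for p01 in np.arange(0, 1.0001, 0.01):
                target = np.array(
                    [p00 * (1 - tpr0) + p01 * tpr0, p00 * (1 - fpr0) + p01 * fpr0]
                )
                try:
                    p1 = np.linalg.solve(A, target)
                except np.linalg.LinAlgError:
                    continue
                if p1.min() < -1e-9 or p1.max() > 1 + 1e-9:
                    continue
                post = {
                    0: (target[0], target[1]),
                    1: (
                        p1[0] * (1 - tpr1) + p1[1] * tpr1,
                        p1[0] * (1 - fpr1) + p1[1] * fpr1,
                    ),
                }
                err = sum(
                    w[(g, 1)] * (1 - post[g][0]) + w[(g, 0)] * post[g][1]
                    for g in (0, 1)
                )
                best = min(best, err)
        pol = fit_epp(FitContext(data=data))
        post = expected_group_rates(pol, data)
        lp_err = sum(
            w[(g, 1)] * (1 - post[g][0]) + w[(g, 0)] * post[g][1] for g in (0, 1)
        )
        assert lp_err <= best + 1e-6


class TestRoc:
    def test_zero_margin_when_already_in_band(self):
        pol = fit_roc(FitContext(data=_symmetric_gs()))
        assert pol.params["margin"] == 0.0

    def test_margin_matches_exhaustive_scan(self, toy_scores):
        data = toy_scores
        band = 0.05
        chosen = None
        for m in np.arange(0, 0.5001, 0.01):
            labels = (data.score >= 0.5).astype(int)
            region = (data.score >= 0.5 - m) & (data.score <= 0.5 + m)
            labels[region & (data.group == 0)] = 1
            labels[region & (data.group == 1)] = 0
            gap = eop(confusion_by_group(data.with_labels(labels)))
            if gap <= band:
                chosen = m
                break
        pol = fit_roc(FitContext(data=data))
        assert pol.params["margin"] == pytest.approx(chosen, abs=1e-9)


class TestPsta:
    def test_keeps_half_threshold_when_groups_equal(self):
        pol = fit_psta(FitContext(data=_symmetric_gs()))
        assert pol.params["thresholds"]["0"] == pytest.approx(0.5)
        assert pol.params["thresholds"]["1"] == 0.5

    def test_lowering_threshold_never_decreases_tpr(self, toy_scores):
        data = toy_scores
        unpriv = data.group == 0
        pos = unpriv & (data.true_label == 1)
        thresholds = np.sort(np.unique(data.score[unpriv]))[::-1]
        tprs = [np.mean(data.score[pos] >= t) for t in thresholds]
        assert all(b >= a - 1e-12 for a, b in zip(tprs, tprs[1:]))

    def test_threshold_matches_exhaustive_oracle(self, toy_scores):
        data = toy_scores
        slack = 0.10
        pop_pred = data.score >= 0.5
        pop_tpr = np.mean(pop_pred[data.true_label == 1])
        pop_fpr = np.mean(pop_pred[data.true_label == 0])
        unpriv = data.group == 0
        best = None
        for thr in np.unique(np.append(data.score[unpriv], 0.5)):
            pred = data.score[unpriv] >= thr
            y = data.true_label[unpriv]
            tpr = np.mean(pred[y == 1])
            fpr = np.mean(pred[y == 0])
            if fpr > pop_fpr + slack + 1e-12:
                continue
            key = (abs(tpr - pop_tpr), abs(thr - 0.5), -thr)
            if best is None or key < best[0]:
                best = (key, thr)
        pol = fit_psta(FitContext(data=data))
        assert pol.params["thresholds"]["0"] == pytest.approx(best[1])


class TestFact:
    def test_lambda_zero_keeps_accurate_classifier(self, toy_scores):
        pol = fit_fact(FitContext(data=toy_scores, settings={"lambda": 0.0}))
        for g in ("0", "1"):
            for yhat in ("0", "1"):
                assert pol.params["flip"][g][yhat] == pytest.approx(0.0, abs=1e-6)

    def test_large_lambda_enforces_eop(self, toy_scores):
        pol = fit_fact(FitContext(data=toy_scores, settings={"lambda": 1e3}))
        rates = expected_group_rates(pol, toy_scores)
        assert abs(rates[0][0] - rates[1][0]) <= 1e-6

    def test_objective_matches_coarse_grid_oracle(self, toy_scores):
        """Vectorized exhaustive 4-D grid at resolution 0.05."""
        lam = 1.0
        data = toy_scores
        rates = _base_group_rates(data)
        w = _cell_masses(data)
        (tpr0, fpr0), (tpr1, fpr1) = rates[0], rates[1]
        grid = np.arange(0, 1.0001, 0.05)
        q00, q01, q10, q11 = np.meshgrid(grid, grid, grid, grid, indexing="ij")
        post_tpr0 = tpr0 * (1 - q01) + (1 - tpr0) * q00
        post_fpr0 = fpr0 * (1 - q01) + (1 - fpr0) * q00
        post_tpr1 = tpr1 * (1 - q11) + (1 - tpr1) * q10
        post_fpr1 = fpr1 * (1 - q11) + (1 - fpr1) * q10
        err = (
            w[(0, 1)] * (1 - post_tpr0)
            + w[(0, 0)] * post_fpr0
            + w[(1, 1)] * (1 - post_tpr1)
            + w[(1, 0)] * post_fpr1
        )
        obj = err + lam * np.abs(post_tpr0 - post_tpr1)
        oracle_best = obj.min()
        pol = fit_fact(FitContext(data=data, settings={"lambda": lam}))
        post = expected_group_rates(pol, data)
        lp_err = sum(
            w[(g, 1)] * (1 - post[g][0]) + w[(g, 0)] * post[g][1] for g in (0, 1)
        )
        lp_obj = lp_err + lam * abs(post[0][0] - post[1][0])
        assert lp_obj <= oracle_best + 1e-9


class TestGstar:
    def test_identical_distributions_give_equal_thresholds(self):
        pol = fit_gstar(FitContext(data=_symmetric_gs()))
        t = pol.params["thresholds"]
        assert t["0"] == pytest.approx(t["1"], abs=1e-2)

    def test_lambda_zero_minimizes_error_per_group(self, toy_scores):
        from fairpost.debias import _SmoothedRates

        pol = fit_gstar(FitContext(data=toy_scores, settings={"lambda": 0.0}))
        sm = _SmoothedRates(toy_scores)
        ours = float(
            sm.objective(
                pol.params["thresholds"]["0"], pol.params["thresholds"]["1"], 0.0
            )[0]
        )
        grid = np.linspace(0, 1, 101)
        t0, t1 = np.meshgrid(grid, grid, indexing="ij")
        dense = sm.objective(t0.ravel(), t1.ravel(), 0.0).min()
        assert ours <= dense + 1e-6

    def test_objective_beats_exhaustive_pair_search(self, toy_scores):
        from fairpost.debias import _SmoothedRates

        lam = 1.0
        sm = _SmoothedRates(toy_scores)
        cand = np.unique(np.append(toy_scores.score, 0.5))
        t0, t1 = np.meshgrid(cand, cand, indexing="ij")
        oracle_best = sm.objective(t0.ravel(), t1.ravel(), lam).min()
        pol = fit_gstar(FitContext(data=toy_scores, settings={"lambda": lam}))
        ours = float(
            sm.objective(
                pol.params["thresholds"]["0"], pol.params["thresholds"]["1"], lam
            )[0]
        )
        assert ours <= oracle_best + 1e-9


class TestMab:
    def test_calibrated_scores_need_no_rounds(self):
        rng = np.random.default_rng(3)
        n = 10000
        x = rng.normal(size=(n, 2))
        p = 1 / (1 + np.exp(-x[:, 0]))
        y = (rng.random(n) < p).astype(int)
        data = _gs(p, y, (x[:, 1] > 0).astype(int), features=x)
        pol = fit_mab(FitContext(data=data))
        assert pol.params["steps"] == []

    def test_removes_planted_subgroup_bias(self):
        """The auditor finds and corrects a +0.3 score bias on a subgroup."""
        features, y, score = planted_bias_data()
        flag = features[:, 1] > 0
        data = _gs(score, y, flag.astype(int), features=features)
        pol = fit_mab(
            FitContext(
                data=data,
                settings={"eta": 0.5, "max_rounds": 200, "alpha": 0.005},
            )
        )
        assert len(pol.params["steps"]) > 0
        eps = pol.params["logit_clip"]
        sc = np.clip(score, eps, 1 - eps)
        logit = np.log(sc / (1 - sc))
        for st in pol.params["steps"]:
            logit = logit + st["eta"] * (
                features @ np.asarray(st["coef"]) + st["intercept"]
            )
        corrected = 1 / (1 + np.exp(-logit))
        assert abs(np.mean((y - corrected)[flag])) < 0.01

    def test_violation_decreases_each_accepted_round(self):
        features, y, score = planted_bias_data()
        data = _gs(score, y, (features[:, 1] > 0).astype(int), features=features)
        from sklearn.linear_model import Ridge

        pol = fit_mab(FitContext(data=data, settings={"eta": 0.5}))
        eps = pol.params["logit_clip"]
        logit = np.log(np.clip(score, eps, 1 - eps) / (1 - np.clip(score, eps, 1 - eps)))
        violations = []
        for st in [None] + pol.params["steps"]:
            if st is not None:
                logit = logit + st["eta"] * (
                    features @ np.asarray(st["coef"]) + st["intercept"]
                )
            s = 1 / (1 + np.exp(-logit))
            r = y - s
            h = Ridge(alpha=1.0).fit(features, r).predict(features)
            violations.append(abs(np.mean(h * r)) / np.mean(np.abs(h)))
        assert all(b < a for a, b in zip(violations, violations[1:]))

    def test_never_reads_protected_column(self):
        """Shuffling the group column cannot change the fitted policy."""
        features, y, score = planted_bias_data()
        g = (features[:, 1] > 0).astype(int)
        rng = np.random.default_rng(0)
        data = _gs(score, y, g, features=features)
        shuffled = _gs(score, y, rng.permutation(g), features=features)
        a = fit_mab(FitContext(data=data))
        b = fit_mab(FitContext(data=shuffled))
        assert a.to_json() == b.to_json()

    def test_requires_features(self):
        with pytest.raises(FitError):
            fit_mab(FitContext(data=_symmetric_gs()))


class TestFairnessImprovement:
    def test_each_method_reduces_its_target_metric(self, logistic_split):
        """EPP/ROC/PSTA/GSTAR reduce their objective on held-out scores."""
        from fairpost.metrics import eod as eod_fn

        data = logistic_split
        base_labels = (data.score >= 0.5).astype(int)
        base_conf = confusion_by_group(data.with_labels(base_labels))
        base = {"eop": eop(base_conf), "eod": eod_fn(base_conf)}
        targets = {"epp": "eod", "roc": "eop", "psta": "eop", "gstar": "eod"}
        ctx = FitContext(data=data)
        for method, metric in targets.items():
            pol = METHODS[method](ctx)
            rates = expected_group_rates(pol, data)
            tpr_gap = abs(rates[0][0] - rates[1][0])
            fpr_gap = abs(rates[0][1] - rates[1][1])
            value = tpr_gap if metric == "eop" else 0.5 * (tpr_gap + fpr_gap)
            assert value < base[metric], method
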