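"""Nested-LOO engine: AUC, threshold calibration, grid search, accounting."""

import numpy as np
import pytest

import radstab as rs
from radstab.data_model import LabelVector, ValidationError
from radstab.models import DEFAULT_GRIDS
from radstab.nested_loo import FoldRecord, internal_loo_optimize

from conftest import make_table


def brute_force_auc(scores, labels):
    """Exhaustive pair counting over all (positive, negative) pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestAucRoc:
    def test_perfect_ranking(self):
        assert rs.auc_roc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_is_half(self):
        assert rs.auc_roc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 15)
        scores = rng.integers(0, 5, n).astype(float)  # integer scores force ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert rs.auc_roc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels)
        )

    def test_single_class_is_error(self):
        with pytest.raises(ValidationError, match="both classes"):
            rs.auc_roc([0.1, 0.2], [1, 1])


def brute_force_threshold(scores, labels):
    """Exhaustive scan over the documented candidate list."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    distinct = np.unique(scores)
    span = max(distinct[-1] - distinct[0], 1.0)
    cands = (
        [distinct[0] - 0.5 * span]
        + [(a + b) / 2 for a, b in zip(distinct[:-1], distinct[1:])]
        + [distinct[-1] + 0.5 * span]
    )
    best, best_obj = None, -1.0
    for t in cands:  # ascending: first max is the smallest optimal threshold
        pred = scores >= t
        sens = np.sum(pred & (labels == 1)) / labels.sum()
        spec = np.sum(~pred & (labels == 0)) / (len(labels) - labels.sum())
        if sens + spec > best_obj + 1e-12:
            best_obj, best = sens + spec, t
    return best, best_obj


class TestSelectThreshold:
    def test_perfect_separation_reaches_two(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = [0, 0, 1, 1]
        t = rs.select_threshold(scores, labels)
        assert 0.2 < t < 0.8
        pred = np.asarray(scores) >= t
        assert pred.tolist() == [False, False, True, True]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = rng.integers(6, 20)
        scores = rng.normal(size=n)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        expect, _ = brute_force_threshold(scores, labels)
        assert rs.select_threshold(scores, labels) == pytest.approx(expect)

    def test_inverted_scores_pick_extreme_candidate(self):
        # all positives below all negatives: predicting everything positive
        # (or everything negative) is optimal; the oracle decides which
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = [1, 1, 0, 0]
        t = rs.select_threshold(scores, labels)
        expect, obj = brute_force_threshold(scores, labels)
        assert t == pytest.approx(expect)
        pred = np.asarray(scores) >= t
        assert pred.all() or not pred.any()

    def test_single_class_is_error(self):
        with pytest.raises(ValidationError):
            rs.select_threshold([0.1, 0.2], [0, 0])


class TestFitAndScore:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 3))
        y = np.array([0, 1] * 6)
        Xt = rng.normal(size=(4, 3))
        for family, hyper in [("rdf", {"n_trees": 50}), ("svm_poly3", {"cost": 2.0}),
                              ("logit", {})]:
            s1 = rs.fit_and_score(family, hyper, X, y, Xt, seed=5)
            s2 = rs.fit_and_score(family, hyper, X, y, Xt, seed=5)
            assert np.array_equal(s1, s2), family

    def test_logit_scores_separable_direction(self):
        X = np.linspace(-1, 1, 10).reshape(-1, 1)
        y = (X[:, 0] > 0).astype(int)
        s = rs.fit_and_score("logit", {}, X, y, np.array([[0.9], [-0.9]]))
        assert s[0] > 0.5 > s[1]

    def test_single_class_training_fold_is_error(self):
        X = np.random.default_rng(0).normal(size=(6, 2))
        with pytest.raises(ValidationError, match="single class"):
            rs.fit_and_score("logit", {}, X, np.ones(6, dtype=int), X)

    def test_rdf_improves_over_chance_for_planted_signal(self, small_cohort):
        es, labels, _ = small_cohort
        table, lab = rs.align(es.reference_table, labels)
        X, y = table.values, lab.labels
        for n_trees in (50, 250):
            scores = rs.fit_and_score("rdf", {"n_trees": n_trees}, X, y, X, seed=1)
            assert rs.auc_roc(scores, y) > 0.8  # resubstitution on strong signal


class TestInternalLOO:
    def test_logit_has_single_implicit_setting(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 2))
        y = np.array([0, 1] * 4)
        spec = rs.ModelSpec("logit", seed=0)
        best, scores, threshold, auc, n_fits = internal_loo_optimize(X, y, spec)
        assert best == {}
        assert n_fits == 8

    def test_duplicated_grid_setting_changes_nothing(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 2))
        y = np.array([0, 1] * 4)
        a = internal_loo_optimize(X, y, rs.ModelSpec(
            "svm_poly3", hyper_grid=({"cost": 1.0}, {"cost": 2.0}), seed=0))
        b = internal_loo_optimize(X, y, rs.ModelSpec(
            "svm_poly3", hyper_grid=({"cost": 1.0}, {"cost": 1.0}, {"cost": 2.0}),
            seed=0))
        assert a[0] == b[0]
        assert a[2] == b[2] and a[3] == b[3]

    def test_matches_longhand_loo_loops(self):
        # independently re-run the LOO grid search with explicit loops
        rng = np.random.default_rng(3)
        X = rng.normal(size=(9, 2))
        y = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0])
        grid = ({"cost": 1.0}, {"cost": 5.0})
        spec = rs.ModelSpec("svm_poly3", hyper_grid=grid, seed=4)
        best, best_scores, threshold, best_auc, _ = internal_loo_optimize(
            X, y, spec, fold_key=0
        )
        aucs = []
        for h_idx, hyper in enumerate(grid):
            scores = []
            for i in range(len(y)):
                keep = [j for j in range(len(y)) if j != i]
                seed = rs.nested_loo.derive_seed(4, 0, h_idx, i)
                s = rs.fit_and_score(
                    "svm_poly3", hyper, X[keep], y[keep], X[i : i + 1], seed
                )[0]
                scores.append(s)
            aucs.append(rs.auc_roc(scores, y))
        assert best_auc == pytest.approx(max(aucs))
        expect_best = grid[int(np.argmax(aucs))] if aucs[0] != aucs[1] else grid[0]
        assert best == expect_best


def _toy_table(n=8, d=2, seed=0, signal=2.0):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = rng.normal(size=(n, d))
    X[:, 0] += signal * y
    table = make_table(X)
    labels = LabelVector(lesion_ids=table.lesion_ids, labels=y)
    return table, labels


class TestNestedLOOEvaluate:
    def test_session_accounting_formula(self):
        table, labels = _toy_table(n=6)
        spec = rs.ModelSpec(
            "svm_poly3", hyper_grid=({"cost": 1.0}, {"cost": 2.0}), seed=0
        )
        res = rs.nested_loo_evaluate(table, labels, spec)
        assert res.training_sessions == 2 * 6 * 5
        assert res.refits == 6
        assert sorted(res.lesion_ids) == sorted(table.lesion_ids)

    def test_reproducible_given_seed(self):
        table, labels = _toy_table(n=8, d=3, seed=1)
        spec = rs.ModelSpec("rdf", hyper_grid=({"n_trees": 50},), seed=9)
        r1 = rs.nested_loo_evaluate(table, labels, spec)
        r2 = rs.nested_loo_evaluate(table, labels, spec)
        for f1, f2 in zip(r1.folds, r2.folds):
            assert f1 == f2

    def test_poisoned_held_out_row_leaves_fold_model_unchanged(self):
        # sentinel-poisoning the held-out lesion must not change its fold's
        # hyperparameters, threshold, internal AUC, or importance: the row
        # is never touched during optimization, calibration, or refit
        table, labels = _toy_table(n=8, d=2, seed=2)
        spec = rs.ModelSpec("logit", seed=3)
        base = rs.nested_loo_evaluate(table, labels, spec)
        for poisoned_idx in (0, 5):
            values = table.values.copy()
            values[poisoned_idx, :] = 1e9  # sentinel
            poisoned = make_table(values, lesion_ids=table.lesion_ids)
            res = rs.nested_loo_evaluate(poisoned, labels, spec)
            fb, fp = base.folds[poisoned_idx], res.folds[poisoned_idx]
            assert fb.best_hyper == fp.best_hyper
            assert fb.threshold == fp.threshold
            assert fb.internal_auc == fp.internal_auc
            assert fb.importance == fp.importance

    def test_group_loo_holds_out_whole_patients(self):
        table, labels = _toy_table(n=8, d=2, seed=4)
        labels.patient_ids = ["P0", "P0", "P1", "P1", "P2", "P2", "P3", "P3"]
        spec = rs.ModelSpec("logit", seed=0)
        res = rs.nested_loo_evaluate(table, labels, spec, group_by_patient=True)
        # both lesions of a patient share one fold model
        by_id = {f.held_out: f for f in res.folds}
        for pid in ("P0", "P1", "P2", "P3"):
            ids = [l for l, p in zip(labels.lesion_ids, labels.patient_ids) if p == pid]
            recs = [by_id[l] for l in ids]
            assert recs[0].threshold == recs[1].threshold
            assert recs[0].best_hyper == recs[1].best_hyper
        assert res.training_sessions == 1 * 4 * 6  # 4 groups, 6 training lesions

    def test_too_small_cohort_is_error(self):
        table, labels = _toy_table(n=4)
        with pytest.raises(ValidationError):
            rs.nested_loo_evaluate(table, labels, rs.ModelSpec("logit"))


class TestComputeMetrics:
    @staticmethod
    def _result_from(scores, thresholds, ids):
        folds = [
            FoldRecord(
                held_out=i, best_hyper={}, threshold=t, score=s,
                hard_prediction=int(s >= t), internal_auc=0.5, importance={},
            )
            for i, s, t in zip(ids, scores, thresholds)
        ]
        return rs.NestedLOOResult(
            folds=folds, model_spec=rs.ModelSpec("logit"),
            feature_names=["f0"], training_sessions=0, refits=0,
        )

    def test_all_correct_gives_ones(self):
        ids = [f"L{i}" for i in range(6)]
        labels = LabelVector(lesion_ids=ids, labels=[1, 1, 1, 0, 0, 0])
        res = self._result_from(
            [0.9, 0.8, 0.7, 0.1, 0.2, 0.3], [0.5] * 6, ids
        )
        m = rs.compute_metrics(res, labels)
        assert (m.auc_roc, m.accuracy, m.specificity, m.precision, m.recall) == (
            1.0, 1.0, 1.0, 1.0, 1.0,
        )

    def test_known_confusion_matrix(self):
        # TP=3, FP=1, TN=3, FN=1 -> every counting metric 0.75
        ids = [f"L{i}" for i in range(8)]
        labels = LabelVector(lesion_ids=ids, labels=[1, 1, 1, 1, 0, 0, 0, 0])
        scores = [0.9, 0.8, 0.7, 0.1, 0.6, 0.2, 0.3, 0.4]
        m = rs.compute_metrics(self._result_from(scores, [0.5] * 8, ids), labels)
        assert m.accuracy == 0.75
        assert m.precision == 0.75
        assert m.recall == 0.75
        assert m.specificity == 0.75

    def test_no_positive_calls_flags_precision_undefined(self):
        ids = [f"L{i}" for i in range(6)]
        labels = LabelVector(lesion_ids=ids, labels=[1, 1, 1, 0, 0, 0])
        res = self._result_from([0.1] * 6, [0.5] * 6, ids)
        m = rs.compute_metrics(res, labels)
        assert m.recall == 0.0
        assert np.isnan(m.precision)


def test_default_grids_match_declared_ranges():
    assert all(50 <= h["n_trees"] <= 250 for h in DEFAULT_GRIDS["rdf"])
    assert all(1 <= h["cost"] <= 10 for h in DEFAULT_GRIDS["svm_poly3"])
    with pytest.raises(ValidationError):
        rs.ModelSpec("rdf", hyper_grid=({"n_trees": 10},))
    with pytest.raises(ValidationError):
        rs.ModelSpec("svm_poly3", hyper_grid=())
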