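"""Nested leave-one-out cross-validation with per-fold threshold calibration.

An external LOO over the ``n`` lesions provides one held-out prediction per
lesion.  Inside each external fold, an internal LOO over the remaining
``n - 1`` lesions drives (i) a grid search for the hyperparameters that
maximize internal AUC-ROC and (ii) calibration of the classification
threshold that maximizes sensitivity + specificity on the internal held-out
scores.  The winning setting is then refitted on the full ``n - 1`` training
fold and applied, with its calibrated threshold, to the held-out lesion.

The held-out lesion never participates in standardization, grid search,
threshold calibration, or the refit for its own fold.  Internal training
sessions number exactly ``|grid| * n * (n - 1)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score

from .data_model import FeatureTable, LabelVector, ValidationError
from .models import (
    ModelSpec,
    fit_and_score,
    fit_model,
    fold_importance,
)

_REFIT_KEY = 1_000_003


def _constant_class_score(family: str, label: int) -> float:
    """Score emitted by a degenerate single-class model for any input."""
    if family == "svm_poly3":  # decision-value scale: the target margins
        return 1.0 if label else -1.0
    return float(label)  # probability / vote-fraction scale


def derive_seed(master: int, *keys: int) -> int:
    """Stable per-fold seed derivation; independent folds, reproducible runs."""
    entries = [int(master) & 0x7FFFFFFF] + [int(k) & 0x7FFFFFFF for k in keys]
    return int(np.random.SeedSequence(entries).generate_state(1)[0] & 0x7FFFFFFF)


def auc_roc(scores, labels) -> float:
    """AUC-ROC in its Mann-Whitney form (ties count one half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not np.all(np.isfinite(scores)):
        raise ValidationError("scores must be finite")
    if len(np.unique(labels)) < 2:
        raise ValidationError("AUC-ROC requires both classes")
    return float(roc_auc_score(labels, scores))


def select_threshold(scores, labels) -> float:
    """Threshold maximizing sensitivity + specificity (predict positive iff
    score >= threshold).

    Candidates are midpoints between consecutive distinct sorted scores plus
    one candidate below the minimum and one above the maximum; ties are broken
    toward the smallest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("threshold selection requires both classes")
    distinct = np.unique(scores)
    span = max(distinct[-1] - distinct[0], 1.0)
    candidates = np.concatenate(
        [
            [distinct[0] - 0.5 * span],
            (distinct[:-1] + distinct[1:]) / 2.0,
            [distinct[-1] + 0.5 * span],
        ]
    )
    best_t = candidates[0]
    best_obj = -np.inf
    for t in candidates:
        pred = scores >= t
        sens = np.sum(pred & (labels == 1)) / n_pos
        spec = np.sum(~pred & (labels == 0)) / n_neg
        obj = sens + spec
        if obj > best_obj + 1e-12:
            best_obj = obj
            best_t = t
    return float(best_t)


@dataclass
class FoldRecord:
    """One external-LOO fold: the held-out lesion and its optimized model."""

    held_out: str
    best_hyper: dict
    threshold: float
    score: float
    hard_prediction: int
    internal_auc: float
    importance: dict  # measure -> {feature -> value}

    def to_jsonable(self) -> dict:
        return asdict(self)


@dataclass
class NestedLOOResult:
    folds: list
    model_spec: ModelSpec
    feature_names: list
    training_sessions: int
    refits: int

    @property
    def lesion_ids(self) -> list[str]:
        return [f.held_out for f in self.folds]

    @property
    def scores(self) -> np.ndarray:
        return np.array([f.score for f in self.folds])

    @property
    def hard_predictions(self) -> np.ndarray:
        return np.array([f.hard_prediction for f in self.folds])

    def external_auc(self, labels: LabelVector) -> float:
        lab = labels.subset(self.lesion_ids)
        return auc_roc(self.scores, lab.labels)

    def to_jsonable(self) -> dict:
        return {
            "family": self.model_spec.family,
            "hyper_grid": list(self.model_spec.hyper_grid),
            "seed": self.model_spec.seed,
            "feature_names": list(self.feature_names),
            "training_sessions": self.training_sessions,
            "refits": self.refits,
            "folds": [f.to_jsonable() for f in self.folds],
        }

    @classmethod
    def from_jsonable(cls, obj: dict) -> "NestedLOOResult":
        spec = ModelSpec(
            family=obj["family"],
            hyper_grid=tuple(obj["hyper_grid"]),
            seed=obj["seed"],
        )
        folds = [FoldRecord(**f) for f in obj["folds"]]
        return cls(
            folds=folds,
            model_spec=spec,
            feature_names=list(obj["feature_names"]),
            training_sessions=int(obj["training_sessions"]),
            refits=int(obj["refits"]),
        )


@dataclass
class Metrics:
    """Confusion-derived metrics of the pooled external-LOO predictions.

    An undefined ratio (zero denominator) is reported as NaN, never as 0.
    """

    auc_roc: float
    accuracy: float
    specificity: float
    precision: float
    recall: float

    def to_jsonable(self) -> dict:
        return {k: (None if math.isnan(v) else v) for k, v in asdict(self).items()}


def internal_loo_optimize(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    fold_key: int = 0,
):
    """Grid search + threshold calibration via LOO over one training fold.

    Returns ``(best_hyper, internal_scores, threshold, internal_auc, n_fits)``.
    Ties in internal AUC are broken toward the simplest model (fewest trees,
    smallest cost), then toward grid order.
    """
    m = len(y)
    if m < 4:
        raise ValidationError(f"internal LOO needs >= 4 training lesions, got {m}")
    if len(np.unique(y)) < 2:
        raise ValidationError("internal LOO needs both classes in the training fold")
    n_fits = 0
    results = []
    for h_idx, hyper in enumerate(spec.hyper_grid):
        scores = np.empty(m)
        for i in range(m):
            keep = np.arange(m) != i
            y_tr = y[keep]
            seed = derive_seed(spec.seed, fold_key, h_idx, i)
            if y_tr.min() == y_tr.max():
                # single-class inner training fold (possible when a class has
                # only two members overall): the degenerate model predicts its
                # class with certainty
                scores[i] = _constant_class_score(spec.family, int(y_tr[0]))
            else:
                scores[i] = fit_and_score(
                    spec.family, hyper, X[keep], y_tr, X[i : i + 1], seed
                )[0]
            n_fits += 1
        results.append((hyper, scores, auc_roc(scores, y)))
    best = max(
        enumerate(results),
        key=lambda t: (t[1][2], -spec.complexity(t[1][0]), -t[0]),
    )[1]
    best_hyper, best_scores, best_auc = best
    threshold = select_threshold(best_scores, y)
    return best_hyper, best_scores, threshold, best_auc, n_fits


def nested_loo_evaluate(
    table: FeatureTable,
    labels: LabelVector,
    spec: ModelSpec,
    feature_subset: list[str] | None = None,
    group_by_patient: bool = False,
    compute_importance: bool = True,
) -> NestedLOOResult:
    """External LOO around internal grid search and threshold calibration.

    With ``group_by_patient`` (and labels carrying patient ids), the external
    loop leaves out whole patients, so that multi-lesion patients never have
    one lesion in training while another is evaluated.
    """
    if table.lesion_ids != labels.lesion_ids:
        raise ValidationError("table and labels must be aligned (see align())")
    if feature_subset is not None:
        table = table.subset_features(feature_subset)
    n = table.n_lesions
    if n < 5:
        raise ValidationError(f"nested LOO needs >= 5 lesions, got {n}")
    y = labels.labels
    if y.sum() < 2 or (n - y.sum()) < 2:
        raise ValidationError("each class needs >= 2 lesions for nested LOO")
    X = table.values

    if group_by_patient:
        if labels.patient_ids is None:
            raise ValidationError("group_by_patient requires patient ids in labels")
        groups = labels.patient_ids
        fold_groups = sorted(set(groups))
        fold_members = [
            [i for i, g in enumerate(groups) if g == fg] for fg in fold_groups
        ]
    else:
        fold_members = [[i] for i in range(n)]

    folds: list[FoldRecord] = []
    sessions = 0
    refits = 0
    for fold_idx, members in enumerate(fold_members):
        keep = np.ones(n, dtype=bool)
        keep[members] = False
        X_tr, y_tr = X[keep], y[keep]
        best_hyper, _, threshold, internal_auc, n_fits = internal_loo_optimize(
            X_tr, y_tr, spec, fold_key=fold_idx
        )
        sessions += n_fits
        refit_seed = derive_seed(spec.seed, fold_idx, _REFIT_KEY)
        model = fit_model(spec.family, best_hyper, X_tr, y_tr, refit_seed)
        refits += 1
        if compute_importance:
            imp = fold_importance(model, spec.family, table.feature_names)
        else:
            imp = {}
        test_scores = model.scores(X[members])
        for j, i in enumerate(members):
            s = float(test_scores[j])
            folds.append(
                FoldRecord(
                    held_out=table.lesion_ids[i],
                    best_hyper=dict(best_hyper),
                    threshold=threshold,
                    score=s,
                    hard_prediction=int(s >= threshold),
                    internal_auc=internal_auc,
                    importance=imp,
                )
            )
    folds.sort(key=lambda f: f.held_out)
    return NestedLOOResult(
        folds=folds,
        model_spec=spec,
        feature_names=list(table.feature_names),
        training_sessions=sessions,
        refits=refits,
    )


def compute_metrics(result: NestedLOOResult, labels: LabelVector) -> Metrics:
    """Table-style metrics from the pooled external predictions.

    AUC-ROC pools the continuous external scores; the counting metrics use the
    per-fold hard calls made with each fold's own calibrated threshold.
    """
    lab = labels.subset(result.lesion_ids)
    y = lab.labels
    pred = result.hard_predictions
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    return Metrics(
        auc_roc=result.external_auc(labels),
        accuracy=(tp + tn) / len(y),
        specificity=ratio(tn, tn + fp),
        precision=ratio(tp, tp + fp),
        recall=ratio(tp, tp + fn),
    )


def save_result(result: NestedLOOResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_jsonable(), fh, indent=1, sort_keys=True)


def load_result(path: str | Path) -> NestedLOOResult:
    with open(path) as fh:
        return NestedLOOResult.from_jsonable(json.load(fh))
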