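"""Classifier families used by the nested-LOO engine.

Three families: a random decision forest (``rdf``), a degree-3 polynomial
SVM (``svm_poly3``), and an unpenalized logistic model (``logit``).  Each
fitted model exposes a continuous score — vote fraction, signed decision
value, and predicted probability respectively — and its family-native
feature-importance measure(s):

* rdf: mean decrease Gini and out-of-bag mean decrease accuracy;
* svm_poly3: absolute pseudo-weight, ``|sum_j alpha_j y_j x_j|`` over the
  support vectors (per feature, on the standardized scale);
* logit: drop-one change in deviance on the training fold.

Features are z-scored with training-fold statistics for svm and logit; the
forest sees raw values (tree splits are monotone-invariant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .data_model import ValidationError
from .forest import RandomDecisionForest

FAMILIES = ("rdf", "svm_poly3", "logit")

DEFAULT_GRIDS = {
    "rdf": tuple({"n_trees": nt} for nt in (50, 100, 150, 200, 250)),
    "svm_poly3": tuple({"cost": c} for c in (1.0, 2.0, 5.0, 10.0)),
    "logit": ({},),
}

#: importance measure labels per family; the first is the family's
#: primary measure (used to order candidates in adaptive selection).
IMPORTANCE_MEASURES = {
    "rdf": ("mean_decrease_accuracy", "mean_decrease_gini"),
    "svm_poly3": ("svm_weight",),
    "logit": ("deviance_delta",),
}


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus its hyperparameter grid and master seed."""

    family: str
    hyper_grid: tuple = None  # type: ignore[assignment]
    seed: int = 0
    n_trees_range: tuple = (50, 250)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        grid = self.hyper_grid
        if grid is None:
            grid = DEFAULT_GRIDS[self.family]
        grid = tuple(dict(h) for h in grid)
        if self.family == "logit":
            if any(h for h in grid) or len(grid) != 1:
                grid = ({},)
        elif not grid:
            raise ValidationError(f"{self.family} requires a nonempty hyper_grid")
        if self.family == "rdf":
            lo, hi = self.n_trees_range
            for h in grid:
                nt = h.get("n_trees")
                if nt is None or not (lo <= nt <= hi):
                    raise ValidationError(
                        f"rdf n_trees must lie in [{lo}, {hi}], got {h}"
                    )
        if self.family == "svm_poly3":
            for h in grid:
                if "cost" not in h or not (h["cost"] > 0):
                    raise ValidationError(f"svm_poly3 needs a positive cost, got {h}")
        object.__setattr__(self, "hyper_grid", grid)

    def complexity(self, hyper: dict) -> float:
        """Simplicity key for tie-breaking (lower = simpler)."""
        if self.family == "rdf":
            return float(hyper["n_trees"])
        if self.family == "svm_poly3":
            return float(hyper["cost"])
        return 0.0


class _Standardizer:
    """Column z-score using training-fold statistics only."""

    def __init__(self, X: np.ndarray):
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.sd = np.where(sd > 0, sd, 1.0)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


class FittedModel:
    """A model fitted on one training fold."""

    def __init__(self, family: str, hyper: dict, seed: int):
        self.family = family
        self.hyper = dict(hyper)
        self.seed = int(seed)

    def scores(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def importance(self) -> dict[str, np.ndarray]:
        """Map measure label -> per-feature importance vector."""
        raise NotImplementedError


class _FittedRDF(FittedModel):
    def __init__(self, hyper, seed, X, y):
        super().__init__("rdf", hyper, seed)
        self.forest = RandomDecisionForest(n_trees=hyper["n_trees"], seed=seed).fit(X, y)

    def scores(self, X):
        return self.forest.predict_scores(X)

    def importance(self):
        return {
            "mean_decrease_accuracy": self.forest.oob_mean_decrease_accuracy(),
            "mean_decrease_gini": self.forest.mean_decrease_gini,
        }


class _FittedSVM(FittedModel):
    def __init__(self, hyper, seed, X, y):
        super().__init__("svm_poly3", hyper, seed)
        self.std = _Standardizer(X)
        self.clf = SVC(kernel="poly", degree=3, C=float(hyper["cost"]))
        self.clf.fit(self.std(X), y)

    def scores(self, X):
        return self.clf.decision_function(self.std(X))

    def importance(self):
        # dual_coef_ already carries the label signs (alpha_j * y_j)
        w = self.clf.dual_coef_ @ self.clf.support_vectors_
        return {"svm_weight": np.abs(np.asarray(w).ravel())}


class _FittedLogit(FittedModel):
    def __init__(self, hyper, seed, X, y):
        super().__init__("logit", hyper, seed)
        self.std = _Standardizer(X)
        self._Xs = self.std(X)
        self._y = y
        self.clf = _fit_logit(self._Xs, y)

    def scores(self, X):
        return self.clf.predict_proba(self.std(X))[:, 1]

    def importance(self):
        dev_full = _deviance(self.clf, self._Xs, self._y)
        d = self._Xs.shape[1]
        out = np.empty(d)
        for k in range(d):
            keep = [j for j in range(d) if j != k]
            if keep:
                sub = _fit_logit(self._Xs[:, keep], self._y)
                dev_k = _deviance(sub, self._Xs[:, keep], self._y)
            else:  # intercept-only null model
                p = self._y.mean()
                dev_k = -2.0 * (
                    self._y.sum() * np.log(max(p, 1e-12))
                    + (len(self._y) - self._y.sum()) * np.log(max(1 - p, 1e-12))
                )
            out[k] = dev_k - dev_full
        return {"deviance_delta": out}


def _fit_logit(X: np.ndarray, y: np.ndarray) -> LogisticRegression:
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=500)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    return clf


def _deviance(clf: LogisticRegression, X: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(clf.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_model(
    family: str, hyper: dict, X: np.ndarray, y: np.ndarray, seed: int
) -> FittedModel:
    """Fit one family member with fixed hyperparameters on a training fold."""
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValidationError("degenerate training fold: a single class present")
    if family == "rdf":
        return _FittedRDF(hyper, seed, np.asarray(X, float), y)
    if family == "svm_poly3":
        return _FittedSVM(hyper, seed, np.asarray(X, float), y)
    if family == "logit":
        return _FittedLogit(hyper, seed, np.asarray(X, float), y)
    raise ValidationError(f"unknown family {family!r}")


def fit_and_score(
    family: str,
    hyper: dict,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Fit on the training fold and return continuous scores for the test rows.

    rdf: fraction of trees voting malignant; svm_poly3: signed decision value;
    logit: predicted probability of malignancy.  Deterministic given the seed.
    """
    model = fit_model(family, hyper, X_train, y_train, seed)
    return model.scores(np.asarray(X_test, float))


def fold_importance(model: FittedModel, family: str, feature_names) -> dict[str, dict[str, float]]:
    """Family-native importances of a fitted fold model, keyed by measure.

    rdf carries two parallel measures (OOB mean decrease accuracy and mean
    decrease Gini); svm and logit carry one each.
    """
    if model.family != family:
        raise ValidationError(
            f"family mismatch: model is {model.family!r}, requested {family!r}"
        )
    vectors = model.importance()
    out: dict[str, dict[str, float]] = {}
    for measure, vec in vectors.items():
        if len(vec) != len(feature_names):
            raise ValidationError("importance vector length != number of features")
        out[measure] = {f: float(v) for f, v in zip(feature_names, vec)}
    return out
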