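"""Distributional feature importance and greedy adaptive selection.

The external LOO produces a *family* of n fitted models rather than a single
one, so each feature carries a sample of n importance values.  Summarizing
the sample by mean and interquartile range (rather than a single retrained
point estimate) both ranks the features and exposes how stable each ranking
is across folds.

Adaptive selection seeds a candidate model with the "most relevant" cluster
of an exact one-dimensional 2-means split of the mean importances, then
greedily offers the remaining features in descending importance, keeping a
feature only if it strictly increases the external nested-LOO AUC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import FeatureTable, LabelVector, ValidationError
from .models import IMPORTANCE_MEASURES, ModelSpec, fold_importance  # noqa: F401
from .nested_loo import NestedLOOResult, nested_loo_evaluate


@dataclass
class ImportanceDistribution:
    """Per-feature samples of fold importances with mean and IQR summaries.

    ``samples[measure]`` is a DataFrame (folds x features); ``summary`` has
    one row per (measure, feature) with mean, q1, q3.
    """

    samples: dict  # measure -> DataFrame (n_folds x n_features)
    summary: pd.DataFrame  # columns: measure, feature, mean, q1, q3

    @property
    def measures(self) -> list[str]:
        return list(self.samples)

    def means(self, measure: str) -> pd.Series:
        sub = self.summary[self.summary["measure"] == measure]
        return pd.Series(sub["mean"].to_numpy(), index=list(sub["feature"]))


@dataclass
class SelectionStep:
    feature: str
    auc_before: float
    auc_after: float
    kept: bool


@dataclass
class SelectionTrace:
    """Ordered log of the adaptive selection run."""

    seed_cluster: list
    steps: list
    final_set: list
    final_auc: float
    full_auc: float
    total_nested_evaluations: int
    universe: list
    seed: int
    family: str
    order_measure: str

    def to_jsonable(self) -> dict:
        out = asdict(self)
        return out

    @classmethod
    def from_jsonable(cls, obj: dict) -> "SelectionTrace":
        obj = dict(obj)
        obj["steps"] = [SelectionStep(**s) for s in obj["steps"]]
        return cls(**obj)


def distributional_importance(result: NestedLOOResult) -> ImportanceDistribution:
    """Assemble per-feature importance samples across the external-LOO folds.

    Quantiles use linear interpolation.  Every fold must carry an importance
    map (runs with ``compute_importance=False`` cannot be aggregated).
    """
    features = list(result.feature_names)
    if not result.folds:
        raise ValidationError("result has no folds")
    measures = list(result.folds[0].importance)
    if not measures:
        raise ValidationError("folds carry no importance maps")
    samples: dict[str, pd.DataFrame] = {}
    rows = []
    for measure in measures:
        mat = np.empty((len(result.folds), len(features)))
        for i, fold in enumerate(result.folds):
            if measure not in fold.importance:
                raise ValidationError(
                    f"fold {fold.held_out} missing importance measure {measure!r}"
                )
            imp = fold.importance[measure]
            for j, f in enumerate(features):
                if f not in imp:
                    raise ValidationError(
                        f"fold {fold.held_out} missing importance for {f!r}"
                    )
                mat[i, j] = imp[f]
        df = pd.DataFrame(mat, columns=features)
        samples[measure] = df
        q1 = df.quantile(0.25, interpolation="linear")
        q3 = df.quantile(0.75, interpolation="linear")
        mean = df.mean()
        for f in features:
            rows.append(
                {
                    "measure": measure,
                    "feature": f,
                    "mean": float(mean[f]),
                    "q1": float(q1[f]),
                    "q3": float(q3[f]),
                }
            )
    return ImportanceDistribution(samples=samples, summary=pd.DataFrame(rows))


def _exact_two_means_split(sorted_vals: np.ndarray) -> int:
    """Best split index k (low cluster = sorted_vals[:k]) minimizing WCSS."""
    n = len(sorted_vals)
    best_k, best_cost = 1, np.inf
    for k in range(1, n):
        lo, hi = sorted_vals[:k], sorted_vals[k:]
        cost = float(((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum())
        if cost < best_cost - 1e-15:
            best_cost = cost
            best_k = k
    return best_k


def cluster_relevant(
    dist: ImportanceDistribution, measure: str
) -> tuple[list[str], list[str]]:
    """Split features into (most relevant, rest) by exact 1-D 2-means.

    The split point over the sorted mean importances is found by exhaustive
    enumeration (no initialization randomness); the relevant cluster is the
    one with the larger center.  ``rest`` comes back ordered by descending
    mean importance.
    """
    if measure not in dist.samples:
        raise ValidationError(
            f"unknown measure {measure!r}; available: {dist.measures}"
        )
    means = dist.means(measure)
    if len(means) < 2:
        raise ValidationError("clustering needs >= 2 features")
    if float(means.max() - means.min()) == 0.0:
        raise ValidationError(
            "all mean importances identical: no meaningful 2-means split; "
            "inspect the importance distribution before selecting"
        )
    order = means.sort_values(ascending=False, kind="mergesort")
    vals_desc = order.to_numpy()
    sorted_asc = vals_desc[::-1]
    k = _exact_two_means_split(sorted_asc)
    n_relevant = len(means) - k  # high cluster = larger center
    relevant = list(order.index[:n_relevant])
    rest = list(order.index[n_relevant:])
    return relevant, rest


def adaptive_select(
    table: FeatureTable,
    labels: LabelVector,
    spec: ModelSpec,
    order_measure: str | None = None,
) -> SelectionTrace:
    """Greedy adaptive feature selection driven by nested-LOO AUC.

    Procedure: (1) nested-LOO on the full (redundancy-corrected) feature
    set; (2) distributional importance; (3) exact 2-means split -> seed set;
    (4) nested-LOO AUC of the seed set; (5) offer each remaining feature in
    descending mean importance, keeping it only on strict AUC improvement.
    Every AUC is the external nested-LOO AUC at the same master seed, so the
    trace can be replayed exactly.
    """
    if order_measure is None:
        order_measure = IMPORTANCE_MEASURES[spec.family][0]
    evaluations = 0

    full_result = nested_loo_evaluate(table, labels, spec)
    evaluations += 1
    full_auc = full_result.external_auc(labels)
    dist = distributional_importance(full_result)
    seed_cluster, rest = cluster_relevant(dist, order_measure)

    current = list(seed_cluster)
    seed_result = nested_loo_evaluate(
        table, labels, spec, feature_subset=current, compute_importance=False
    )
    evaluations += 1
    current_auc = seed_result.external_auc(labels)

    steps: list[SelectionStep] = []
    for feature in rest:
        cand = current + [feature]
        cand_result = nested_loo_evaluate(
            table, labels, spec, feature_subset=cand, compute_importance=False
        )
        evaluations += 1
        cand_auc = cand_result.external_auc(labels)
        kept = cand_auc > current_auc
        steps.append(
            SelectionStep(
                feature=feature,
                auc_before=current_auc,
                auc_after=cand_auc,
                kept=kept,
            )
        )
        if kept:
            current = cand
            current_auc = cand_auc
    return SelectionTrace(
        seed_cluster=list(seed_cluster),
        steps=steps,
        final_set=current,
        final_auc=current_auc,
        full_auc=full_auc,
        total_nested_evaluations=evaluations,
        universe=list(table.feature_names),
        seed=spec.seed,
        family=spec.family,
        order_measure=order_measure,
    )


def save_trace(trace: SelectionTrace, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(trace.to_jsonable(), fh, indent=1, sort_keys=True)


def load_trace(path: str | Path) -> SelectionTrace:
    with open(path) as fh:
        return SelectionTrace.from_jsonable(json.load(fh))
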