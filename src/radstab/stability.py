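"""Perturbation-based feature instability, redundancy correction, PCA check.

The instability score of feature *i* over an extraction grid with reference
variant *ref* (by default ``standard:25``) is

    Delta_i = 1/(V * n_p) * sum_{v, p} |f_i(v, p) - f_i(ref, p)| / range_ref(f_i)

where *V* counts all variants in the grid (reference included — its terms
are zero), *n_p* the lesions, and ``range_ref`` the cohort max-min of the
feature at the reference extraction.  A feature constant at the reference
has an undefined score (NaN flag), never silently 0 or infinite.

Redundancy correction drops, within every pair of features whose reference
Pearson correlation exceeds a threshold (|r| > 0.95 by default), the less
stable member (the one with the larger Delta).  A PCA component count at
99% cumulative variance before and after the drop verifies that only
redundant directions were removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .data_model import ExtractionSet, ExtractionVariant, FeatureTable, ValidationError


@dataclass
class StabilityReport:
    """Per-feature instability plus its per-variant decomposition.

    ``per_variant_deviation`` is the feature x variant matrix of
    lesion-averaged normalized absolute deviations (the heatmap content);
    ``delta`` is its row mean over variants.  NaN flags an undefined score.
    """

    delta: dict
    per_variant_deviation: pd.DataFrame
    reference: ExtractionVariant
    n_patients: int

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per feature, one column per variant, plus delta."""
        out = self.per_variant_deviation.copy()
        out["delta"] = pd.Series(self.delta)
        return out


@dataclass
class RedundancyResult:
    kept: list
    dropped: list  # (dropped_feature, retained_partner, correlation)
    pca_components_before: int
    pca_components_after: int
    variance_threshold: float
    r_threshold: float

    def to_jsonable(self) -> dict:
        return {
            "kept": list(self.kept),
            "dropped": [
                {"feature": d, "retained_partner": k, "correlation": float(r)}
                for d, k, r in self.dropped
            ],
            "pca_components_before": self.pca_components_before,
            "pca_components_after": self.pca_components_after,
            "variance_threshold": self.variance_threshold,
            "r_threshold": self.r_threshold,
        }


def _reference_range(es: ExtractionSet, feature: str) -> float:
    col = es.reference_table.column(feature)
    if len(col) < 2:
        raise ValidationError("instability needs >= 2 lesions (range undefined)")
    return float(col.max() - col.min())


def instability_score(es: ExtractionSet, feature: str) -> float:
    """Instability Delta of one feature over the full perturbation grid.

    Returns NaN (undefined flag) when the feature is constant at the
    reference extraction.
    """
    if feature not in es.feature_names:
        raise ValidationError(f"unknown feature {feature!r}")
    rng = _reference_range(es, feature)
    if rng == 0.0:
        return float("nan")
    ref = es.reference_table.column(feature)
    total = 0.0
    for var, tab in es.variants.items():
        total += float(np.abs(tab.column(feature) - ref).sum())
    n_p = es.reference_table.n_lesions
    return total / (len(es.variants) * n_p * rng)


def stability_table(es: ExtractionSet) -> StabilityReport:
    """Instability decomposed per extraction variant (heatmap table).

    ``per_variant_deviation[i, v]`` is the lesion-mean of
    ``|f_i(v, p) - f_i(ref, p)| / range_ref(f_i)``; its row mean over
    variants reproduces :func:`instability_score`.
    """
    ref_tab = es.reference_table
    if ref_tab.n_lesions < 2:
        raise ValidationError("instability needs >= 2 lesions (range undefined)")
    variants = es.sorted_variants()
    features = es.feature_names
    ref = ref_tab.values
    rng = ref.max(axis=0) - ref.min(axis=0)
    mat = np.empty((len(features), len(variants)))
    for j, var in enumerate(variants):
        dev = np.abs(es.variants[var].values - ref).mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            mat[:, j] = np.where(rng > 0, dev / np.where(rng > 0, rng, 1.0), np.nan)
    df = pd.DataFrame(mat, index=features, columns=[str(v) for v in variants])
    delta = {f: float(df.loc[f].mean()) for f in features}
    for f, r in zip(features, rng):
        if r == 0:
            delta[f] = float("nan")
    return StabilityReport(
        delta=delta,
        per_variant_deviation=df,
        reference=es.reference,
        n_patients=ref_tab.n_lesions,
    )


def pca_component_count(table: FeatureTable, variance_threshold: float = 0.99) -> int:
    """Principal components needed to reach the cumulative variance threshold.

    Columns are z-scored first; constant columns are excluded from the
    decomposition (they contribute no variance).
    """
    if not (0 < variance_threshold <= 1):
        raise ValidationError("variance_threshold must be in (0, 1]")
    if table.n_features < 2:
        raise ValidationError("PCA check needs >= 2 features")
    if table.n_lesions < 3:
        raise ValidationError("PCA check needs >= 3 lesions")
    X = table.values
    sd = X.std(axis=0, ddof=0)
    live = sd > 0
    if not live.any():
        raise ValidationError("all feature columns are constant")
    Z = (X[:, live] - X[:, live].mean(axis=0)) / sd[live]
    pca = PCA(svd_solver="full").fit(Z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    return int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)


def redundancy_correction(
    table: FeatureTable,
    delta: dict,
    r_threshold: float = 0.95,
    variance_threshold: float = 0.99,
) -> RedundancyResult:
    """Drop the less stable member of every highly correlated feature pair.

    Pairwise Pearson correlations are computed on the reference-variant
    table; pairs with |r| > ``r_threshold`` are processed in descending |r|
    (single pass, nothing recomputed).  In each pair the member with the
    larger Delta is dropped; an undefined Delta (NaN) counts as larger than
    any defined one, and an exact tie drops the lexicographically later
    name.  A pair with an already-dropped member is skipped.
    """
    features = table.feature_names
    missing = [f for f in features if f not in delta]
    if missing:
        raise ValidationError(f"delta map missing features: {missing}")
    X = table.values
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    pairs = []
    d = len(features)
    for a in range(d):
        for b in range(a + 1, d):
            r = corr[a, b]
            if np.isfinite(r) and abs(r) > r_threshold:
                pairs.append((a, b, float(r)))
    # descending |r|; deterministic tie-break on the name pair
    pairs.sort(key=lambda t: (-abs(t[2]), features[t[0]], features[t[1]]))

    dropped_set: set[str] = set()
    dropped: list[tuple[str, str, float]] = []
    for a, b, r in pairs:
        fa, fb = features[a], features[b]
        if fa in dropped_set or fb in dropped_set:
            continue
        da, db = delta[fa], delta[fb]
        nan_a, nan_b = math.isnan(da), math.isnan(db)
        if nan_a and not nan_b:
            victim, keeper = fa, fb
        elif nan_b and not nan_a:
            victim, keeper = fb, fa
        elif not nan_a and not nan_b and da > db:
            victim, keeper = fa, fb
        elif not nan_a and not nan_b and db > da:
            victim, keeper = fb, fa
        else:  # tie (both NaN or exactly equal): drop the later name
            victim, keeper = (fb, fa) if fb > fa else (fa, fb)
        dropped_set.add(victim)
        dropped.append((victim, keeper, r))
    kept = [f for f in features if f not in dropped_set]
    before = pca_component_count(table, variance_threshold)
    if len(kept) >= 2:
        after = pca_component_count(table.subset_features(kept), variance_threshold)
    else:  # a single surviving column spans one component (if non-constant)
        after = int(table.column(kept[0]).std() > 0) if kept else 0
    return RedundancyResult(
        kept=kept,
        dropped=dropped,
        pca_components_before=before,
        pca_components_after=after,
        variance_threshold=variance_threshold,
        r_threshold=r_threshold,
    )
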