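"""Synthetic lesion cohorts with known ground truth.

Real radiomic re-extractions are not shareable for this kind of study, so
every pipeline stage is exercised on generated cohorts that emulate the
relevant statistics: a benign/malignant cohort of configurable size, a mix
of geometric and texture features, class separation driven by a small
planted informative subset, highly correlated redundant clone pairs, and a
perturbation grid in which texture features react to bin width and mask
changes while geometric features stay quiet.

The default configuration mirrors the target study shape: 69 lesions with a
malignant majority (35/69), 25 features (5 geometric, 20 texture), a 3-mask
x 5-bin-width extraction grid referenced at ``standard:25``.

The generator is deliberately plain — additive Gaussian perturbations on
the feature scale — because it validates the statistics of the pipeline,
not radiology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .data_model import (
    ExtractionSet,
    ExtractionVariant,
    FeatureTable,
    LabelVector,
    REFERENCE_VARIANT,
    ValidationError,
)


@dataclass
class GeneratorConfig:
    """Ground-truth parameters of a synthetic cohort.

    ``informative_features`` lists ``(feature_index, effect_size)`` where the
    effect size *d* is the standardized mean shift of the malignant class.
    ``redundant_pairs`` lists ``(source_index, clone_index, target_r)``; the
    clone is an r-mixture of the standardized source plus independent noise.
    ``instability`` maps feature index to the scale of mask-perturbation
    noise (relative to the feature's cohort SD) and ``bw_sensitivity`` to
    the drift slope per unit of bin-width deviation from the reference
    (also relative to the cohort SD).  Geometric features must have zero
    bin-width sensitivity.
    """

    n_lesions: int = 69
    prevalence: float = 35 / 69
    n_geometric: int = 5
    n_texture: int = 20
    informative_features: tuple = ((1, 1.5), (5, 1.5), (6, 1.5))
    redundant_pairs: tuple = ((2, 10, 0.99), (6, 11, 0.97))
    instability: dict = field(default_factory=dict)
    bw_sensitivity: dict = field(default_factory=dict)
    masks: tuple = ("reduced", "standard", "increased")
    bin_widths: tuple = (15.0, 20.0, 25.0, 30.0, 35.0)
    reference: ExtractionVariant = REFERENCE_VARIANT
    seed: int = 0

    # default perturbation scales (used for any feature not explicitly mapped)
    sigma_geometric: float = 0.05
    sigma_texture: float = 0.25
    bw_slope_texture: float = 0.05

    @property
    def n_features(self) -> int:
        return self.n_geometric + self.n_texture

    def feature_names(self) -> list[str]:
        geo = [f"geo{i:02d}" for i in range(self.n_geometric)]
        tex = [f"tex{i:02d}" for i in range(self.n_texture)]
        return geo + tex

    def is_geometric(self, idx: int) -> bool:
        return idx < self.n_geometric

    def resolved_instability(self) -> np.ndarray:
        sig = np.array(
            [
                self.sigma_geometric if self.is_geometric(i) else self.sigma_texture
                for i in range(self.n_features)
            ]
        )
        for i, s in self.instability.items():
            sig[int(i)] = float(s)
        return sig

    def resolved_bw_sensitivity(self) -> np.ndarray:
        slope = np.array(
            [
                0.0 if self.is_geometric(i) else self.bw_slope_texture
                for i in range(self.n_features)
            ]
        )
        for i, s in self.bw_sensitivity.items():
            slope[int(i)] = float(s)
        return slope

    def validate(self) -> None:
        d = self.n_features
        if self.n_lesions < 2:
            raise ValidationError("n_lesions must be >= 2")
        if not (0 < self.prevalence < 1):
            raise ValidationError("prevalence must be in (0, 1)")
        n_pos = int(np.floor(self.prevalence * self.n_lesions))
        if n_pos == 0 or n_pos == self.n_lesions:
            raise ValidationError(
                f"prevalence {self.prevalence} yields an empty class at n={self.n_lesions}"
            )
        for idx, eff in self.informative_features:
            if not (0 <= idx < d):
                raise ValidationError(f"informative feature index {idx} out of range")
            if not np.isfinite(eff):
                raise ValidationError("effect sizes must be finite")
        clones = [c for _, c, _ in self.redundant_pairs]
        sources = [s for s, _, _ in self.redundant_pairs]
        for s, c, r in self.redundant_pairs:
            if not (0 <= s < d and 0 <= c < d):
                raise ValidationError(f"redundant pair ({s},{c}) out of range")
            if not (0 < r <= 1):
                raise ValidationError(f"target correlation must be in (0, 1], got {r}")
        if set(clones) & set(sources):
            raise ValidationError("clone indices must be distinct from source indices")
        if len(set(clones)) != len(clones):
            raise ValidationError("clone indices must be pairwise distinct")
        for i in self.instability:
            if not (0 <= int(i) < d):
                raise ValidationError(f"instability index {i} out of range")
            if self.instability[i] < 0:
                raise ValidationError("instability scales must be >= 0")
        for i in self.bw_sensitivity:
            if not (0 <= int(i) < d):
                raise ValidationError(f"bw_sensitivity index {i} out of range")
        slope = self.resolved_bw_sensitivity()
        for i in range(self.n_geometric):
            if slope[i] != 0.0:
                raise ValidationError(
                    f"geometric feature index {i} must have zero bw_sensitivity"
                )
        if self.reference.mask not in self.masks or self.reference.bin_width not in self.bin_widths:
            raise ValidationError("reference variant must lie on the generation grid")


@dataclass
class CohortTruth:
    """Immutable record of the planted structure of a generated cohort."""

    feature_names: tuple
    informative: dict  # feature name -> effect size
    redundant: dict  # clone name -> source name
    sigma_pert: dict  # feature name -> mask perturbation scale
    bw_sensitivity: dict  # feature name -> bin-width slope
    seed: int

    def to_jsonable(self) -> dict:
        out = asdict(self)
        out["feature_names"] = list(self.feature_names)
        return out

    @classmethod
    def from_jsonable(cls, obj: dict) -> "CohortTruth":
        obj = dict(obj)
        obj["feature_names"] = tuple(obj["feature_names"])
        return cls(**obj)


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[ExtractionSet, LabelVector, CohortTruth]:
    """Draw one synthetic cohort; same config and seed give identical output.

    Reference-variant values are the baseline matrix exactly (the zero
    perturbation terms leave them bit-identical); non-reference variants add
    ``mask_offset(m) * sigma_pert * sd_f * eps + bw_slope * (bw - bw_ref) * sd_f * eta``
    with independent standard-normal noise and ``mask_offset`` zero for the
    standard mask, one otherwise.
    """
    config.validate()
    rng = np.random.default_rng(int(config.seed) & 0x7FFFFFFF)
    n, d = config.n_lesions, config.n_features
    names = config.feature_names()

    # labels: exactly floor(prevalence * n) malignant, assigned by shuffling
    n_pos = int(np.floor(config.prevalence * n))
    y = np.zeros(n, dtype=int)
    y[:n_pos] = 1
    rng.shuffle(y)

    X = rng.standard_normal((n, d))
    for idx, eff in config.informative_features:
        X[y == 1, idx] += float(eff)
    for src, clone, r in config.redundant_pairs:
        s = X[:, src]
        s_std = (s - s.mean()) / s.std(ddof=0)
        X[:, clone] = r * s_std + np.sqrt(1.0 - r * r) * rng.standard_normal(n)

    sd = X.std(axis=0, ddof=0)
    sigma = config.resolved_instability()
    slope = config.resolved_bw_sensitivity()

    lesion_ids = [f"L{i:03d}" for i in range(n)]
    feature_class = {
        f: ("geometric" if config.is_geometric(i) else "texture")
        for i, f in enumerate(names)
    }

    variants: dict[ExtractionVariant, FeatureTable] = {}
    bw_ref = config.reference.bin_width
    for mask in config.masks:
        offset = 0.0 if mask == config.reference.mask else 1.0
        for bw in config.bin_widths:
            eps = rng.standard_normal((n, d))
            eta = rng.standard_normal((n, d))
            vals = (
                X
                + offset * (sigma * sd) * eps
                + (slope * sd) * (bw - bw_ref) * eta
            )
            variants[ExtractionVariant(mask, float(bw))] = FeatureTable(
                lesion_ids=lesion_ids,
                feature_names=names,
                values=vals,
                feature_class=feature_class,
            )

    es = ExtractionSet(variants=variants, reference=config.reference)
    labels = LabelVector(lesion_ids=lesion_ids, labels=y)
    truth = CohortTruth(
        feature_names=tuple(names),
        informative={names[i]: float(e) for i, e in config.informative_features},
        redundant={names[c]: names[s] for s, c, _ in config.redundant_pairs},
        sigma_pert={f: float(s) for f, s in zip(names, sigma)},
        bw_sensitivity={f: float(s) for f, s in zip(names, slope)},
        seed=int(config.seed),
    )
    return es, labels, truth


def recovery_report(trace, truth: CohortTruth) -> dict:
    """Precision/recall of a selection trace against the planted truth.

    Also reports whether any informative feature was dropped before the
    selection ever saw it (e.g., as the less stable member of a clone pair).
    """
    universe = set(trace.universe)
    known = set(truth.feature_names)
    if not universe <= known:
        raise ValidationError(
            f"trace features unknown to the truth: {sorted(universe - known)}"
        )
    selected = set(trace.final_set)
    informative = set(truth.informative)
    tp = len(selected & informative)
    precision = tp / len(selected) if selected else float("nan")
    recall = tp / len(informative) if informative else float("nan")
    dropped_informative = sorted(informative - universe)
    return {
        "selected": sorted(selected),
        "informative": sorted(informative),
        "precision": precision,
        "recall": recall,
        "informative_dropped_before_selection": dropped_informative,
    }


def save_truth(truth: CohortTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_jsonable(), fh, indent=1, sort_keys=True)


def load_truth(path: str | Path) -> CohortTruth:
    with open(path) as fh:
        return CohortTruth.from_jsonable(json.load(fh))
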