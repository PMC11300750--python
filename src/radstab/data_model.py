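"""Domain types and CSV readers/writers shared by all pipeline stages.

The unit of analysis is the *lesion*: every table is a lesion x feature numeric
matrix.  A radiomic extraction is repeated over a grid of segmentation-mask
variants (reduced / standard / increased) and gray-level bin widths; the
collection of per-variant tables, with a designated reference extraction,
is an :class:`ExtractionSet`.

Lesion order is canonicalized by lexicographic ``lesion_id`` sort everywhere,
so downstream fold indexing is reproducible regardless of input row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

MASKS = ("reduced", "standard", "increased")
FEATURE_CLASSES = ("geometric", "texture")


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass(frozen=True, order=True)
class ExtractionVariant:
    """One extraction setting: segmentation-mask variant plus gray-level bin width."""

    mask: str
    bin_width: float

    def __post_init__(self) -> None:
        if self.mask not in MASKS:
            raise ValidationError(
                f"mask must be one of {MASKS}, got {self.mask!r}"
            )
        if not (self.bin_width > 0):
            raise ValidationError(f"bin_width must be > 0, got {self.bin_width}")

    @classmethod
    def parse(cls, text: str) -> "ExtractionVariant":
        """Parse a ``mask:bin_width`` token such as ``standard:25``."""
        try:
            mask, bw = text.split(":")
            return cls(mask=mask.strip(), bin_width=float(bw))
        except ValidationError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raise as contract error
            raise ValidationError(f"cannot parse variant {text!r}: {exc}") from exc

    def __str__(self) -> str:
        bw = self.bin_width
        bw_txt = f"{int(bw)}" if float(bw).is_integer() else f"{bw}"
        return f"{self.mask}:{bw_txt}"


REFERENCE_VARIANT = ExtractionVariant("standard", 25.0)


@dataclass
class FeatureTable:
    """Lesion x feature matrix with identifiers and feature-class metadata.

    ``feature_class`` maps every feature name to ``"geometric"`` or
    ``"texture"``.  Geometric (shape) features are computed from the mask
    alone and are insensitive to the gray-level bin width; texture features
    are not.
    """

    lesion_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    feature_class: dict[str, str]

    def __post_init__(self) -> None:
        self.lesion_ids = [str(x) for x in self.lesion_ids]
        self.feature_names = [str(x) for x in self.feature_names]
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        if len(set(self.lesion_ids)) != len(self.lesion_ids):
            dupes = sorted({x for x in self.lesion_ids if self.lesion_ids.count(x) > 1})
            raise ValidationError(f"duplicate lesion_ids: {dupes}")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValidationError("duplicate feature_names")
        if self.values.shape != (len(self.lesion_ids), len(self.feature_names)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.lesion_ids)}, {len(self.feature_names)})"
            )
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                "non-finite feature value at lesion "
                f"{self.lesion_ids[r]!r}, feature {self.feature_names[c]!r}"
            )
        missing = [f for f in self.feature_names if f not in self.feature_class]
        if missing:
            raise ValidationError(f"features without a feature_class entry: {missing}")
        bad = {f: c for f, c in self.feature_class.items() if c not in FEATURE_CLASSES}
        if bad:
            raise ValidationError(f"invalid feature_class values: {bad}")

    @property
    def n_lesions(self) -> int:
        return len(self.lesion_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def column(self, feature: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(feature)]

    def subset_features(self, features: Sequence[str]) -> "FeatureTable":
        """Restrict to the given features, in the given order."""
        idx = [self.feature_names.index(f) for f in features]
        return FeatureTable(
            lesion_ids=list(self.lesion_ids),
            feature_names=list(features),
            values=self.values[:, idx].copy(),
            feature_class={f: self.feature_class[f] for f in features},
        )

    def subset_lesions(self, lesion_ids: Sequence[str]) -> "FeatureTable":
        idx = [self.lesion_ids.index(x) for x in lesion_ids]
        return FeatureTable(
            lesion_ids=list(lesion_ids),
            feature_names=list(self.feature_names),
            values=self.values[idx, :].copy(),
            feature_class=dict(self.feature_class),
        )

    def texture_features(self) -> list[str]:
        return [f for f in self.feature_names if self.feature_class[f] == "texture"]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.lesion_ids, name="lesion_id"),
            columns=self.feature_names,
        )


@dataclass
class ExtractionSet:
    """Per-variant feature tables over the perturbation grid, with a reference.

    All tables share identical lesion ids (same order) and feature names; the
    reference variant (by default ``standard:25``) is the extraction every
    other variant is compared against.
    """

    variants: dict[ExtractionVariant, FeatureTable]
    reference: ExtractionVariant

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.reference not in self.variants:
            raise ValidationError(
                f"reference variant {self.reference} absent from extraction set"
            )
        ref = self.variants[self.reference]
        for var, tab in self.variants.items():
            if tab.lesion_ids != ref.lesion_ids:
                only_ref = set(ref.lesion_ids) - set(tab.lesion_ids)
                only_var = set(tab.lesion_ids) - set(ref.lesion_ids)
                raise ValidationError(
                    f"lesion sets differ between {self.reference} and {var}: "
                    f"missing {sorted(only_ref)}, extra {sorted(only_var)}"
                )
            if tab.feature_names != ref.feature_names:
                raise ValidationError(
                    f"feature names differ between {self.reference} and {var}"
                )

    @property
    def reference_table(self) -> FeatureTable:
        return self.variants[self.reference]

    @property
    def lesion_ids(self) -> list[str]:
        return self.reference_table.lesion_ids

    @property
    def feature_names(self) -> list[str]:
        return self.reference_table.feature_names

    def sorted_variants(self) -> list[ExtractionVariant]:
        """Variants in canonical order: mask in grid order, then bin width."""
        return sorted(self.variants, key=lambda v: (MASKS.index(v.mask), v.bin_width))


@dataclass
class LabelVector:
    """Binary lesion labels; the positive class is *malignant*."""

    lesion_ids: list[str]
    labels: np.ndarray
    patient_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.lesion_ids = [str(x) for x in self.lesion_ids]
        self.labels = np.asarray(self.labels, dtype=int)
        self.validate()

    def validate(self) -> None:
        if len(set(self.lesion_ids)) != len(self.lesion_ids):
            raise ValidationError("duplicate lesion_id in labels")
        if self.labels.shape != (len(self.lesion_ids),):
            raise ValidationError("labels length does not match lesion_ids")
        if not np.all(np.isin(self.labels, (0, 1))):
            raise ValidationError("labels must be binary 0/1")
        if self.patient_ids is not None and len(self.patient_ids) != len(self.lesion_ids):
            raise ValidationError("patient_ids length does not match lesion_ids")

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    def require_both_classes(self) -> None:
        if self.n_positive in (0, len(self.labels)):
            raise ValidationError("both classes (benign and malignant) are required")

    def subset(self, lesion_ids: Sequence[str]) -> "LabelVector":
        idx = [self.lesion_ids.index(x) for x in lesion_ids]
        return LabelVector(
            lesion_ids=list(lesion_ids),
            labels=self.labels[idx],
            patient_ids=[self.patient_ids[i] for i in idx] if self.patient_ids else None,
        )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_ID_COLS = ("lesion_id", "mask", "bin_width")


def _meta_path_for(path: Path) -> Path:
    return path.with_name(path.name.removesuffix(".csv") + ".meta.yaml")


def read_feature_classes(meta_path: Path, feature_names: Sequence[str]) -> dict[str, str]:
    """Read the ``feature -> {class: geometric|texture}`` sidecar.

    If the sidecar is absent every feature defaults to ``texture``: geometric
    status must be declared explicitly because the texture-only mode depends
    on it, and silent guessing is forbidden.
    """
    if not Path(meta_path).exists():
        logger.warning(
            "no feature metadata at %s; treating all features as texture", meta_path
        )
        return {f: "texture" for f in feature_names}
    with open(meta_path) as fh:
        raw = yaml.safe_load(fh) or {}
    classes: dict[str, str] = {}
    for f in feature_names:
        entry = raw.get(f)
        if entry is None:
            classes[f] = "texture"
        elif isinstance(entry, dict):
            classes[f] = str(entry.get("class", "texture"))
        else:
            classes[f] = str(entry)
    bad = {f: c for f, c in classes.items() if c not in FEATURE_CLASSES}
    if bad:
        raise ValidationError(f"invalid feature classes in {meta_path}: {bad}")
    return classes


def read_extraction_set(
    path: str | Path,
    reference: ExtractionVariant = REFERENCE_VARIANT,
    meta_path: str | Path | None = None,
) -> ExtractionSet:
    """Read a long-format features CSV into a validated :class:`ExtractionSet`.

    The CSV has columns ``lesion_id, mask, bin_width`` followed by one column
    per feature; one row per (lesion, mask, bin width).  A sidecar
    ``<name>.meta.yaml`` assigns feature classes.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"lesion_id": str})
    for col in _ID_COLS:
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    feature_names = [c for c in df.columns if c not in _ID_COLS]
    if not feature_names:
        raise ValidationError(f"{path}: no feature columns")
    for col in feature_names:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()]
        if len(bad):
            row = int(bad[0])
            raise ValidationError(
                f"{path}: non-numeric value {df.loc[row, col]!r} in column "
                f"{col!r}, row {row + 2} (1-based, incl. header)"
            )
        if numeric.isna().any():
            row = int(df.index[numeric.isna()][0])
            raise ValidationError(
                f"{path}: missing value in column {col!r}, row {row + 2}"
            )
        df[col] = numeric

    meta = Path(meta_path) if meta_path is not None else _meta_path_for(path)
    feature_class = read_feature_classes(meta, feature_names)

    variants: dict[ExtractionVariant, FeatureTable] = {}
    all_ids = sorted(df["lesion_id"].unique())
    for (mask, bw), grp in df.groupby(["mask", "bin_width"], sort=True):
        var = ExtractionVariant(str(mask), float(bw))
        grp = grp.sort_values("lesion_id")
        ids = list(grp["lesion_id"])
        if ids != all_ids:
            missing = sorted(set(all_ids) - set(ids))
            extra = sorted({x for x in ids if ids.count(x) > 1})
            detail = f"missing lesions {missing}" if missing else f"duplicated lesions {extra}"
            raise ValidationError(f"{path}: variant {var} inconsistent: {detail}")
        variants[var] = FeatureTable(
            lesion_ids=ids,
            feature_names=feature_names,
            values=grp[feature_names].to_numpy(dtype=float),
            feature_class=feature_class,
        )
    if reference not in variants:
        raise ValidationError(f"{path}: reference variant {reference} absent")
    return ExtractionSet(variants=variants, reference=reference)


def write_extraction_set(
    es: ExtractionSet, path: str | Path, write_meta: bool = True
) -> None:
    """Write the long-format CSV (and the feature-class sidecar)."""
    path = Path(path)
    rows = []
    for var in es.sorted_variants():
        tab = es.variants[var]
        block = tab.to_dataframe().reset_index()
        block.insert(1, "mask", var.mask)
        block.insert(2, "bin_width", var.bin_width)
        rows.append(block)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    if write_meta:
        meta = {
            f: {"class": es.reference_table.feature_class[f]}
            for f in es.feature_names
        }
        with open(_meta_path_for(path), "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)


def split_extraction_set(es: ExtractionSet, out_dir: str | Path) -> list[Path]:
    """Utility: write one wide CSV per extraction variant."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for var in es.sorted_variants():
        p = out_dir / f"features_{var.mask}_{var.bin_width:g}.csv"
        es.variants[var].to_dataframe().to_csv(p)
        written.append(p)
    return written


def read_labels(path: str | Path) -> LabelVector:
    """Read ``lesion_id,label[,patient_id]``; label is benign/malignant (any case)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    for col in ("lesion_id", "label"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    if df["lesion_id"].duplicated().any():
        dupes = sorted(df.loc[df["lesion_id"].duplicated(), "lesion_id"].unique())
        raise ValidationError(f"{path}: duplicate lesion_id {dupes}")
    tokens = df["label"].str.strip().str.lower()
    known = {"benign": 0, "malignant": 1}
    bad = sorted(set(tokens) - set(known))
    if bad:
        raise ValidationError(f"{path}: unknown label token(s) {bad}")
    df = df.assign(_y=tokens.map(known)).sort_values("lesion_id")
    return LabelVector(
        lesion_ids=list(df["lesion_id"]),
        labels=df["_y"].to_numpy(dtype=int),
        patient_ids=list(df["patient_id"]) if "patient_id" in df.columns else None,
    )


def write_labels(labels: LabelVector, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "lesion_id": labels.lesion_ids,
            "label": np.where(labels.labels == 1, "malignant", "benign"),
        }
    )
    if labels.patient_ids is not None:
        df["patient_id"] = labels.patient_ids
    df.to_csv(path, index=False)


def align(table: FeatureTable, labels: LabelVector) -> tuple[FeatureTable, LabelVector]:
    """Restrict table and labels to their common lesions, identically ordered.

    The label set must cover the table (labels may carry extra lesions, which
    are dropped with a log message); a table lesion without a label is an error.
    """
    table_ids = set(table.lesion_ids)
    label_ids = set(labels.lesion_ids)
    unlabeled = sorted(table_ids - label_ids)
    if unlabeled:
        raise ValidationError(f"lesions without labels: {unlabeled}")
    common = sorted(table_ids & label_ids)
    if not common:
        raise ValidationError("no lesions in common between table and labels")
    extra = sorted(label_ids - table_ids)
    if extra:
        logger.info("dropping %d labeled lesions absent from table: %s", len(extra), extra)
    return table.subset_lesions(common), labels.subset(common)
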