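"""End-to-end workflow: simulate -> stability -> reduce -> evaluate -> select -> report.

Artifacts are plain CSV/JSON/Markdown so every run is diffable; each run
directory carries the configuration hash and master seed, and ``report.md``
is a pure view regenerated from the stored artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import importance as imp_mod
from . import nested_loo as nl
from .data_model import (
    ExtractionVariant,
    FeatureTable,
    LabelVector,
    REFERENCE_VARIANT,
    ValidationError,
    align,
    read_extraction_set,
    read_labels,
)
from .models import ModelSpec
from .stability import redundancy_correction, stability_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    features_path: str
    labels_path: str
    out_dir: str
    reference: str = str(REFERENCE_VARIANT)
    r_threshold: float = 0.95
    variance_threshold: float = 0.99
    families: tuple = ("rdf", "svm_poly3", "logit")
    rdf_grid: tuple = (50, 100, 150, 200, 250)
    svm_grid: tuple = (1.0, 2.0, 5.0, 10.0)
    select_family: str = "rdf"
    seed: int = 0
    feature_mode: str = "full"  # full | texture_only | explicit
    explicit_features: tuple = ()
    group_by_patient: bool = False

    def validate(self) -> None:
        if not (0 < self.r_threshold <= 1):
            raise ValidationError("r_threshold must be in (0, 1]")
        if not (0 < self.variance_threshold <= 1):
            raise ValidationError("variance_threshold must be in (0, 1]")
        if self.feature_mode not in ("full", "texture_only", "explicit"):
            raise ValidationError(f"unknown feature_mode {self.feature_mode!r}")
        if self.feature_mode == "explicit" and not self.explicit_features:
            raise ValidationError("explicit feature_mode needs explicit_features")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def model_spec(self, family: str) -> ModelSpec:
        if family == "rdf":
            grid = tuple({"n_trees": int(nt)} for nt in self.rdf_grid)
        elif family == "svm_poly3":
            grid = tuple({"cost": float(c)} for c in self.svm_grid)
        else:
            grid = ({},)
        return ModelSpec(family=family, hyper_grid=grid, seed=self.seed)


def select_modelling_features(
    table: FeatureTable, kept: list[str], delta: dict, config: RunConfig
) -> list[str]:
    """Feature set entering the models: redundancy-kept, defined-Delta,
    restricted by the configured feature mode."""
    feats = [f for f in kept if not math.isnan(delta.get(f, float("nan")))]
    undefined = [f for f in kept if f not in feats]
    if undefined:
        logger.warning("excluding features with undefined instability: %s", undefined)
    if config.feature_mode == "texture_only":
        feats = [f for f in feats if table.feature_class[f] == "texture"]
    elif config.feature_mode == "explicit":
        missing = [f for f in config.explicit_features if f not in table.feature_names]
        if missing:
            raise ValidationError(f"explicit features not in table: {missing}")
        feats = [f for f in config.explicit_features if f in feats]
    if not feats:
        raise ValidationError("no features remain after filtering")
    return feats


def concordance_report(
    result_a: nl.NestedLOOResult,
    result_b: nl.NestedLOOResult,
    labels: LabelVector,
    name_a: str = "A",
    name_b: str = "B",
) -> dict:
    """Per-lesion agreement of two evaluated models on the identical cohort.

    Classifies each lesion into both-correct / only-A-correct /
    only-B-correct / both-wrong; the four fractions sum to one.
    """
    if result_a.lesion_ids != result_b.lesion_ids:
        raise ValidationError("concordance requires identical lesion sets")
    lab = labels.subset(result_a.lesion_ids)
    y = lab.labels
    ok_a = result_a.hard_predictions == y
    ok_b = result_b.hard_predictions == y
    cats = {
        "both_correct": ok_a & ok_b,
        "only_a_correct": ok_a & ~ok_b,
        "only_b_correct": ~ok_a & ok_b,
        "both_wrong": ~ok_a & ~ok_b,
    }
    n = len(y)
    rows = []
    for i, lid in enumerate(result_a.lesion_ids):
        cat = next(k for k, v in cats.items() if v[i])
        rows.append(
            {
                "lesion_id": lid,
                "label": "malignant" if y[i] else "benign",
                "category": cat,
            }
        )
    return {
        "model_a": name_a,
        "model_b": name_b,
        "n": n,
        "counts": {k: int(v.sum()) for k, v in cats.items()},
        "fractions": {k: float(v.sum() / n) for k, v in cats.items()},
        "lesions": rows,
    }


def _fmt_pct(x) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "undefined"
    return f"{100 * x:.1f}%"


def write_report(run_dir: str | Path) -> Path:
    """Render ``report.md`` purely from the artifacts stored in ``run_dir``."""
    run_dir = Path(run_dir)
    lines = ["# Radiomic pipeline report", ""]
    manifest = run_dir / "run.json"
    if manifest.exists():
        meta = json.loads(manifest.read_text())
        lines += [
            f"- config hash: `{meta.get('config_hash')}`",
            f"- master seed: {meta.get('seed')}",
            "",
        ]
    red_path = run_dir / "reduction.json"
    if red_path.exists():
        red = json.loads(red_path.read_text())
        lines += [
            "## Redundancy correction",
            "",
            f"- kept {len(red['kept'])} features; dropped {len(red['dropped'])}",
            f"- PCA components at {red['variance_threshold']:.0%} variance: "
            f"{red['pca_components_before']} before, {red['pca_components_after']} after",
            "",
        ]
        for item in red["dropped"]:
            lines.append(
                f"  - dropped `{item['feature']}` "
                f"(r = {item['correlation']:.3f} with `{item['retained_partner']}`)"
            )
        lines.append("")
    metrics_rows = []
    for path in sorted(run_dir.glob("metrics_*.json")):
        m = json.loads(path.read_text())
        metrics_rows.append(m)
    if metrics_rows:
        lines += [
            "## Model performance (external nested-LOO)",
            "",
            "| Model | AUC-ROC | Accuracy | Specificity | Precision | Recall |",
            "|---|---|---|---|---|---|",
        ]
        for m in metrics_rows:
            lines.append(
                "| {model} | {auc} | {acc} | {spec} | {prec} | {rec} |".format(
                    model=m["model"],
                    auc=_fmt_pct(m["auc_roc"]),
                    acc=_fmt_pct(m["accuracy"]),
                    spec=_fmt_pct(m["specificity"]),
                    prec=_fmt_pct(m["precision"]),
                    rec=_fmt_pct(m["recall"]),
                )
            )
        lines.append("")
    imp_path = run_dir / "importance.csv"
    if imp_path.exists():
        df = pd.read_csv(imp_path)
        lines += ["## Distributional feature importance", ""]
        for measure, sub in df.groupby("measure", sort=True):
            sub = sub.sort_values("mean", ascending=False)
            lines += [
                f"### {measure}",
                "",
                "| Feature | Mean | Q1 | Q3 |",
                "|---|---|---|---|",
            ]
            for _, row in sub.iterrows():
                lines.append(
                    f"| {row['feature']} | {row['mean']:.4f} "
                    f"| {row['q1']:.4f} | {row['q3']:.4f} |"
                )
            lines.append("")
    trace_path = run_dir / "trace.json"
    if trace_path.exists():
        tr = json.loads(trace_path.read_text())
        lines += [
            "## Adaptive feature selection",
            "",
            f"- seed cluster: {', '.join(tr['seed_cluster'])}",
            f"- final set ({len(tr['final_set'])} features): {', '.join(tr['final_set'])}",
            f"- full-model AUC {_fmt_pct(tr['full_auc'])} -> reduced AUC {_fmt_pct(tr['final_auc'])}",
            f"- nested-LOO evaluations: {tr['total_nested_evaluations']}",
            "",
            "Note: the reduced-model AUC is selected on the same external folds it",
            "is reported on, so it is an optimistically biased estimate.",
            "",
        ]
    conc_path = run_dir / "concordance.json"
    if conc_path.exists():
        c = json.loads(conc_path.read_text())
        lines += [
            f"## Concordance: {c['model_a']} vs {c['model_b']}",
            "",
        ]
        for k in ("both_correct", "only_a_correct", "only_b_correct", "both_wrong"):
            lines.append(f"- {k.replace('_', ' ')}: {c['counts'][k]} ({_fmt_pct(c['fractions'][k])})")
        lines.append("")
    out = run_dir / "report.md"
    out.write_text("\n".join(lines))
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages in order and write the run artifacts.

    Any stage error aborts with the stage name; partial outputs are retained
    next to a ``FAILED`` marker naming the stage.
    """
    config.validate()
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    (run_dir / "run.json").write_text(json.dumps(manifest, indent=1, default=str))
    stage = "read_inputs"
    try:
        reference = ExtractionVariant.parse(config.reference)
        es = read_extraction_set(config.features_path, reference=reference)
        labels = read_labels(config.labels_path)
        table, labels = align(es.reference_table, labels)
        labels.require_both_classes()

        stage = "stability"
        report = stability_table(es)
        report.to_frame().to_csv(run_dir / "stability.csv", index_label="feature")

        stage = "reduce"
        red = redundancy_correction(
            es.reference_table,
            report.delta,
            r_threshold=config.r_threshold,
            variance_threshold=config.variance_threshold,
        )
        (run_dir / "reduction.json").write_text(
            json.dumps(red.to_jsonable(), indent=1)
        )
        feats = select_modelling_features(table, red.kept, report.delta, config)

        stage = "evaluate"
        results: dict[str, nl.NestedLOOResult] = {}
        for family in config.families:
            spec = config.model_spec(family)
            res = nl.nested_loo_evaluate(
                table,
                labels,
                spec,
                feature_subset=feats,
                group_by_patient=config.group_by_patient,
            )
            results[family] = res
            nl.save_result(res, run_dir / f"result_{family}.json")
            metrics = nl.compute_metrics(res, labels)
            payload = {"model": family, **metrics.to_jsonable()}
            (run_dir / f"metrics_{family}.json").write_text(
                json.dumps(payload, indent=1)
            )
            for name, value in metrics.to_jsonable().items():
                if value is None:
                    logger.warning("%s: metric %s undefined", family, name)

        stage = "importance"
        first = config.select_family if config.select_family in results else config.families[0]
        dist = imp_mod.distributional_importance(results[first])
        dist.summary.to_csv(run_dir / "importance.csv", index=False)

        stage = "select"
        if config.select_family in results:
            spec = config.model_spec(config.select_family)
            trace = imp_mod.adaptive_select(
                table.subset_features(feats), labels, spec
            )
            imp_mod.save_trace(trace, run_dir / "trace.json")

        stage = "concordance"
        fams = [f for f in config.families if f in results]
        if len(fams) >= 2:
            conc = concordance_report(
                results[fams[0]], results[fams[1]], labels,
                name_a=fams[0], name_b=fams[1],
            )
            (run_dir / "concordance.json").write_text(json.dumps(conc, indent=1))

        stage = "report"
        write_report(run_dir)
    except Exception as exc:
        (run_dir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        raise
    return run_dir
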