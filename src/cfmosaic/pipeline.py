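"""End-to-end two-stage pipeline orchestration.

``run_pipeline`` drives simulate -> extract -> differential -> detection
training -> tissue-of-origin training -> report on one configuration.
Stage outputs are written under the output directory and stages are
skipped when their outputs already exist (idempotent, resumable).  Stage 2
only ever sees samples that stage 1 called cancer.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from cfmosaic import detect, differential, too
from cfmosaic.features import MultiFeatureSet, extract_cohort_features
from cfmosaic.io import load_cohort, read_labels
from cfmosaic.profiles import CANCER_CLASSES
from cfmosaic.simulate import CohortDesign, simulate_cohort

log = logging.getLogger("cfmosaic")


@dataclass
class PipelineConfig:
    """Schema-validated pipeline configuration."""

    out_dir: str
    seed: int = 0
    class_counts: dict = field(
        default_factory=lambda: {"healthy": 40, **{c: 8 for c in CANCER_CLASSES}}
    )
    fragments_per_sample: int = 20_000
    target_depth: int = 2_000
    bin_depth: int = 1_000
    min_specificity: float = 0.95
    delta: float = 0.8
    importance_cutoff: float = 0.9
    focal_gamma: float = 2.0
    grids: str = "default"  # "default" or "fast"
    oof_folds: int = 10
    gcnn_epochs: int = 200
    force: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)


def _stage(name: str, out: Path, force: bool):
    done = out / f".{name}.done"

    def fresh() -> bool:
        if force or not done.exists():
            log.info("stage %s: running", name)
            return True
        log.info("stage %s: outputs present, skipping", name)
        return False

    return fresh, done


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the metrics dictionary (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    log.info("pipeline seed=%d out=%s", config.seed, out)

    cohort_dir = out / "cohort"
    fresh, done = _stage("simulate", out, config.force)
    if fresh():
        design = CohortDesign(
            class_counts=config.class_counts,
            fragments_per_sample=config.fragments_per_sample,
            target_depth=config.target_depth,
            bin_depth=config.bin_depth,
            master_seed=config.seed,
        )
        simulate_cohort(design, cohort_dir)
        done.touch()

    features_dir = out / "features"
    fresh, done = _stage("extract", out, config.force)
    if fresh():
        bundle = load_cohort(cohort_dir)
        feature_set = extract_cohort_features(bundle)
        feature_set.normalize().to_dir(features_dir)
        done.touch()

    feature_set = MultiFeatureSet.from_dir(features_dir)
    labels = read_labels(cohort_dir / "labels.tsv").set_index("sample_id")
    labels = labels.loc[feature_set.sample_ids]
    y = (labels["class_label"] != "healthy").astype(int).to_numpy()

    fresh, done = _stage("differential", out, config.force)
    if fresh():
        for group in ("TM", "GWM", "CNA", "EM"):
            result = differential.wilcoxon_bh(feature_set.matrices[group], y)
            result.table.to_csv(out / f"differential_{group}.tsv", sep="\t", index=False)
        done.touch()

    bundle_path = out / "detection_model.pkl"
    fresh, done = _stage("train_detect", out, config.force)
    if fresh():
        grids = detect.FAST_GRIDS if config.grids == "fast" else detect.DEFAULT_GRIDS
        model = detect.train_detection_model(
            feature_set, y, seed=config.seed, grids=grids,
            min_specificity=config.min_specificity, oof_folds=config.oof_folds,
        )
        model.save(bundle_path)
        done.touch()
    model = detect.DetectionModelBundle.load(bundle_path)

    scores = model.scores(feature_set)
    called = scores >= model.cutoff
    metrics = detect.evaluate_detection(
        scores.to_numpy(), y, model.cutoff,
        class_labels=labels["class_label"].to_numpy(), seed=config.seed,
    )

    fresh, done = _stage("train_too", out, config.force)
    too_report = None
    # stage 2 is trained on cancer samples only, and applied to stage-1 calls
    cancer_ids = labels.index[(labels["class_label"] != "healthy")].tolist()
    if fresh():
        graph = too.build_sample_graph(
            feature_set.subset(cancer_ids),
            labels.loc[cancer_ids, "class_label"],
            delta=config.delta,
            class_names=CANCER_CLASSES,
        )
        cfg = too.GCNNConfig(
            gamma=config.focal_gamma, epochs=config.gcnn_epochs, seed=config.seed
        )
        gcnn, too_report = too.train_gcnn(graph, cfg)
        called_cancer = [s for s in cancer_ids if called.get(s, False)]
        if called_cancer:
            probs, pred = too.predict_too(gcnn, graph, called_cancer)
        else:  # nothing passed stage 1: no tissue-of-origin calls
            pred = pd.Series(dtype=object, name="predicted_class")
        pred.rename("predicted_class").to_frame().assign(
            reference=labels.loc[pred.index, "class_label"]
        ).to_csv(out / "too_predictions.tsv", sep="\t", index_label="sample_id")
        agree = too.agreement_matrix(
            pred, labels.loc[pred.index, "class_label"], CANCER_CLASSES
        )
        agree.to_csv(out / "too_agreement.tsv", sep="\t")
        done.touch()

    report = {
        "seed": config.seed,
        "n_samples": int(len(y)),
        "detection": {
            "auc": metrics.auc,
            "auc_ci": list(metrics.auc_ci),
            "sensitivity": metrics.sensitivity,
            "specificity": metrics.specificity,
            "cutoff": metrics.cutoff,
            "per_class_sensitivity": metrics.per_class_sensitivity,
            "stack_subset": list(model.stack.subset),
            "stack_cv_auc": model.stack.cv_auc,
        },
        "too": {
            "fold_accuracies": too_report.fold_accuracies if too_report else None,
        },
    }
    (out / "metrics.json").write_text(json.dumps(report, indent=2))
    log.info("pipeline complete: %s", out / "metrics.json")
    return report
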