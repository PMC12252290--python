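"""Two-stage inference flow and the reproducible experiment driver.

Inference mirrors the mobile app's decision flow: preprocess the pupil ROI,
run the one-class gate, and only when the gate says CATARACT run the six-grade
classifier. ``run_experiment`` is the desk-scale reproducibility surface: one
pinned-seed YAML/JSON config in, one artifact directory out (split manifests,
trained models, metric reports, CV report, export parity report, event log).
"""

from __future__ import annotations

import csv
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml
from PIL import Image, UnidentifiedImageError
from pydantic import BaseModel, Field, ValidationError, field_validator

from . import export as export_mod
from . import gate as gate_mod
from . import grading, phantoms, preprocess

logger = logging.getLogger("nucat")


class InputError(ValueError):
    """User-input problem (bad path, bad config, empty ROI): CLI exit code 1."""


@dataclass
class InferenceResult:
    """Outcome of the two-stage flow; ``stage2`` present iff stage1 = CATARACT."""

    stage1: gate_mod.GateDecision
    stage2: dict | None
    input_id: str
    gate_model_id: str
    grade_model_id: str | None
    timings_ms: dict

    def __post_init__(self):
        has2 = self.stage2 is not None
        if has2 != (self.stage1.label == gate_mod.CATARACT):
            raise AssertionError(
                "invariant violated: stage2 must be present iff stage1=CATARACT")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.stage2 is not None:
            d["stage2"]["probabilities"] = [float(p) for p in
                                            self.stage2["probabilities"]]
        return d


def _load_roi_tensor(image_path, circle: preprocess.CircleSpec | None) -> np.ndarray:
    try:
        with Image.open(image_path) as pil:
            if circle is not None:
                rgb = np.asarray(pil.convert("RGB"))
                rgba = preprocess.apply_circular_roi(rgb, circle)
            elif pil.mode == "RGBA":
                rgba = np.asarray(pil)
            else:
                rgb = np.asarray(pil.convert("RGB"))
                if rgb.shape[:2] != (224, 224):
                    rgb = np.asarray(Image.fromarray(rgb).resize(
                        (224, 224), Image.BOX))
                return preprocess.normalize_for_model(rgb)
    except FileNotFoundError as exc:
        raise InputError(f"cannot read image: {image_path}") from exc
    except UnidentifiedImageError as exc:
        raise InputError(f"not a decodable image: {image_path}") from exc
    try:
        rgb = preprocess.extract_visible_roi(rgba)
    except preprocess.EmptyRoiError as exc:
        raise InputError(str(exc)) from exc
    return preprocess.normalize_for_model(rgb)


def run_inference(image_path, gate_model: gate_mod.GateModel,
                  grade_model: grading.GradeModel | None = None,
                  circle: preprocess.CircleSpec | None = None) -> InferenceResult:
    """Full two-stage flow on one image file (optionally with a circle ROI)."""
    t0 = time.perf_counter()
    tensor = _load_roi_tensor(image_path, circle)
    t1 = time.perf_counter()
    decision = gate_mod.classify_binary(gate_model, tensor)
    t2 = time.perf_counter()
    stage2 = None
    if decision.label == gate_mod.CATARACT:
        if grade_model is None:
            raise InputError("gate said CATARACT but no grading model was given")
        grade, probs = grading.predict_grade(grade_model, tensor)
        stage2 = {"grade": grade, "probabilities": probs.tolist()}
    t3 = time.perf_counter()
    return InferenceResult(
        stage1=decision, stage2=stage2, input_id=str(image_path),
        gate_model_id=f"cae-p{gate_model.percentile:g}",
        grade_model_id=grade_model.arch if grade_model is not None else None,
        timings_ms={"preprocess": (t1 - t0) * 1e3, "gate": (t2 - t1) * 1e3,
                    "grading": (t3 - t2) * 1e3})


def run_inference_on_batch(items: list[phantoms.LabeledImage],
                           gate_model: gate_mod.GateModel,
                           grade_model: grading.GradeModel) -> list[InferenceResult]:
    """Two-stage flow on in-memory labeled images (no file round-trip)."""
    results = []
    for item in items:
        tensor = preprocess.normalize_for_model(item.image)
        decision = gate_mod.classify_binary(gate_model, tensor)
        stage2 = None
        if decision.label == gate_mod.CATARACT:
            grade, probs = grading.predict_grade(grade_model, tensor)
            stage2 = {"grade": grade, "probabilities": probs.tolist()}
        results.append(InferenceResult(
            stage1=decision, stage2=stage2, input_id=item.source_id,
            gate_model_id=f"cae-p{gate_model.percentile:g}",
            grade_model_id=grade_model.arch, timings_ms={}))
    return results


# ---------------------------------------------------------------------------
# experiment config (pydantic: schema violations reported with field paths)
# ---------------------------------------------------------------------------

class DatasetConfig(BaseModel):
    source: str = "phantoms"
    n_per_class: int = Field(default=40, ge=1)
    labels: list[str] = list(phantoms.GRADE_LABELS)
    noise_sd: float = Field(default=8.0, ge=0)
    manifest: str | None = None

    @field_validator("source")
    @classmethod
    def _source_known(cls, v):
        if v not in ("phantoms", "manifest"):
            raise ValueError("source must be 'phantoms' or 'manifest'")
        return v


class GateSection(BaseModel):
    enabled: bool = True
    epochs: int = Field(default=8, ge=1)
    percentile: float = Field(default=99.0, ge=0, le=100)
    direction: str = "low_error_is_cataract"
    n_iol_eval: int = Field(default=20, ge=1)

    @field_validator("direction")
    @classmethod
    def _direction_known(cls, v):
        if v not in gate_mod.DIRECTIONS:
            raise ValueError(f"direction must be one of {gate_mod.DIRECTIONS}")
        return v


class GradingSection(BaseModel):
    architectures: list[str] = ["resnet18"]
    epochs: int = Field(default=10, ge=1)
    learning_rate: float = Field(default=1e-3, gt=0)
    batch_size: int = Field(default=16, ge=1)
    augment_multiplier: int = Field(default=1, ge=1)
    cv_folds: int | None = None

    @field_validator("architectures")
    @classmethod
    def _archs_known(cls, v):
        for arch in v:
            if arch not in grading.ARCHITECTURES:
                raise ValueError(f"unknown architecture {arch!r}; "
                                 f"choose from {grading.ARCHITECTURES}")
        return v


class ExportSection(BaseModel):
    enabled: bool = True
    formats: list[str] = ["float32"]
    n_probes: int = Field(default=60, ge=1)

    @field_validator("formats")
    @classmethod
    def _formats_known(cls, v):
        for f in v:
            if f not in ("float32", "float16"):
                raise ValueError(f"unknown export format {f!r}")
        return v


class ExperimentConfig(BaseModel):
    seed: int = 0
    out_dir: str = "nucat-run"
    dataset: DatasetConfig = DatasetConfig()
    gate: GateSection = GateSection()
    grading: GradingSection = GradingSection()
    export: ExportSection = ExportSection()


def load_experiment_config(path) -> ExperimentConfig:
    path = Path(path)
    if not path.exists():
        raise InputError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    try:
        return ExperimentConfig.model_validate(raw or {})
    except ValidationError as exc:
        lines = [f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}"
                 for e in exc.errors()]
        raise InputError("invalid experiment config:\n  " + "\n  ".join(lines)) from exc


def _write_manifest(items: list[phantoms.LabeledImage], path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source_id", "label"])
        for item in items:
            writer.writerow([item.source_id, item.label])


class _JsonlLog:
    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def event(self, kind: str, **payload) -> None:
        record = {"t": time.strftime("%Y-%m-%dT%H:%M:%S"), "event": kind,
                  **payload}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(record) + "\n")
        logger.info("%s %s", kind, payload)


def run_experiment(config_path, out_dir=None) -> Path:
    """Run the full pipeline experiment described by a YAML/JSON config.

    Returns the artifact directory. Rerunning with the same config reproduces
    identical split manifests, phantom content and gate threshold.
    """
    cfg = load_experiment_config(config_path)
    out = Path(out_dir) if out_dir is not None else Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _JsonlLog(out / "log.jsonl")
    (out / "config.json").write_text(cfg.model_dump_json(indent=2))
    log.event("start", config=str(config_path))

    if cfg.dataset.source == "manifest":
        if not cfg.dataset.manifest:
            raise InputError("dataset.manifest: path required when source=manifest")
        data = phantoms.load_manifest(cfg.dataset.manifest)
        data = [d for d in data if d.label in phantoms.GRADE_LABELS]
        iol = [d for d in phantoms.load_manifest(cfg.dataset.manifest)
               if d.label == phantoms.IOL_LABEL]
    else:
        data = phantoms.generate_dataset(cfg.dataset.n_per_class,
                                         labels=cfg.dataset.labels,
                                         seed=cfg.seed,
                                         noise_sd=cfg.dataset.noise_sd)
        iol = phantoms.generate_dataset(cfg.gate.n_iol_eval,
                                        labels=[phantoms.IOL_LABEL],
                                        seed=cfg.seed + 1,
                                        noise_sd=cfg.dataset.noise_sd)
    log.event("dataset", n=len(data), n_iol=len(iol))

    split = grading.stratified_split(data, grading.SplitSpec(seed=cfg.seed))
    train, val, test = split
    for name, subset in zip(("train", "val", "test"), split):
        _write_manifest(subset, out / f"split_{name}.csv")
    log.event("split", train=len(train), val=len(val), test=len(test))

    gate_model = None
    if cfg.gate.enabled:
        tensors = [preprocess.normalize_for_model(d.image) for d in train]
        cae_cfg = gate_mod.CaeConfig(epochs=cfg.gate.epochs, seed=cfg.seed)
        gate_model = gate_mod.train_gate(tensors, cae_cfg,
                                         percentile=cfg.gate.percentile,
                                         direction=cfg.gate.direction)
        gate_mod.save_gate(gate_model, out / "gate")
        eval_imgs = ([preprocess.normalize_for_model(d.image) for d in test]
                     + [preprocess.normalize_for_model(d.image) for d in iol])
        eval_labels = ([gate_mod.CATARACT] * len(test)
                       + [gate_mod.NON_CATARACT] * len(iol))
        report = gate_mod.evaluate_gate(gate_model, eval_imgs, eval_labels)
        (out / "gate_eval.json").write_text(json.dumps(asdict(report), indent=2))
        log.event("gate", threshold=gate_model.threshold,
                  accuracy=report.accuracy)

    train_cfg = grading.TrainConfig(epochs=cfg.grading.epochs,
                                    learning_rate=cfg.grading.learning_rate,
                                    batch_size=cfg.grading.batch_size,
                                    seed=cfg.seed)
    if cfg.grading.augment_multiplier > 1:
        aug = preprocess.AugmentationSpec(seed=cfg.seed)
        train_exp = grading.expand_with_augmentation(
            train, aug, cfg.grading.augment_multiplier)
    else:
        train_exp = train

    grade_models: dict[str, grading.GradeModel] = {}
    for arch in cfg.grading.architectures:
        model = grading.build_classifier(arch, seed=cfg.seed)
        grading.train_classifier(model, train_exp, val, train_cfg)
        grading.save_grader(model, out / arch)
        metrics = grading.evaluate(model, test)
        (out / f"{arch}_metrics.json").write_text(
            json.dumps(metrics.to_dict(), indent=2))
        with open(out / f"{arch}_confusion.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["true\\pred"] + list(metrics.classes))
            for cls, row in zip(metrics.classes, metrics.confusion):
                writer.writerow([cls] + row)
        grade_models[arch] = model
        log.event("grader", arch=arch, test_accuracy=metrics.accuracy)

    if cfg.grading.cv_folds:
        cv = grading.cross_validate(data, cfg.grading.architectures[0],
                                    train_cfg, k=cfg.grading.cv_folds)
        (out / "cv.json").write_text(json.dumps(cv.to_dict(), indent=2))
        log.event("cv", gap=cv.gap, gap_sd=cv.gap_sd)

    if cfg.export.enabled and grade_models:
        arch, model = next(iter(grade_models.items()))
        probes = phantoms.generate_dataset(
            max(1, cfg.export.n_probes // len(phantoms.GRADE_LABELS)),
            labels=phantoms.GRADE_LABELS, seed=cfg.seed + 2,
            noise_sd=cfg.dataset.noise_sd)
        handles = {}
        for fmt in cfg.export.formats:
            stem = out / f"{arch}_{fmt}"
            export_mod.export_model(model, stem, precision=fmt)
            handles[fmt] = export_mod.load_exported(stem)
        parity = export_mod.parity_report(model, handles, probes)
        (out / "parity.json").write_text(json.dumps(parity.to_dict(), indent=2))
        parity.to_csv(out / "parity.csv")
        log.event("parity", max_abs_logit_dev=parity.max_abs_logit_dev)

    log.event("done")
    return out
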