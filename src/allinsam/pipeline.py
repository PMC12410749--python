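"""End-to-end pipeline: simulate -> annotate -> train -> evaluate.

Mirrors the three-step weak-annotation workflow: (1) generate registered
structure+marker patches with ground truth and derive weak (box or noisy
mask) annotations, (2) convert weak annotations to pixel masks, (3) train the
adapter backbone with the plain or corrective loss, then score the held-out
test split with the full metric suite.  A run is fully reproducible from
(config, seed): all randomness flows through counter-based per-stage seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import io as _io
from .annotate import FallbackSegmenter, convert_boxes
from .backbone import AdapterModel, predict, save_checkpoint, train
from .config import RunConfig, stage_seed
from .metrics import MetricsReport, evaluate_image
from .synthdata import corrupt_labels, derive_boxes, render_patch
from .types import ClassAnnotationSet, InstanceMask, MultiplexImage

logger = logging.getLogger(__name__)

__all__ = ["simulate_dataset", "make_training_annotations", "run_pipeline", "average_reports"]

Sample = Tuple[MultiplexImage, InstanceMask, ClassAnnotationSet]


def _truth_annotations(inst: InstanceMask, n_classes: int) -> ClassAnnotationSet:
    masks = {c: inst.class_mask(c).astype(np.uint8) for c in range(1, n_classes + 1)}
    return ClassAnnotationSet(masks=masks, provenance="truth")


def simulate_dataset(cfg: RunConfig, split: str, n: int) -> List[Sample]:
    """Generate ``n`` patches for one split with split-disjoint seeds."""
    offsets = {"train": 0, "val": 10_000, "test": 20_000}
    s = cfg.synth
    out: List[Sample] = []
    for i in range(n):
        seed = stage_seed(cfg.seed, "simulate", offsets[split] + i)
        image, inst = render_patch(
            s.height, s.width, s.n_per_class, s.noise_sd, seed, s.min_gap
        )
        out.append((image, inst, _truth_annotations(inst, len(s.n_per_class))))
    return out


def make_training_annotations(
    cfg: RunConfig, samples: Sequence[Sample]
) -> List[ClassAnnotationSet]:
    """Produce the training labels the annotate stage is configured for."""
    mode = cfg.annotate.source
    out = []
    for i, (image, inst, truth) in enumerate(samples):
        seed = stage_seed(cfg.seed, "annotate", i)
        if mode == "truth":
            out.append(truth)
        elif mode == "lay":
            out.append(corrupt_labels(truth, inst, cfg.synth.noise, seed, image=image))
        else:  # boxes -> promptable conversion
            boxes = derive_boxes(inst, cfg.annotate.box_mode, cfg.annotate.jitter_px, seed)
            out.append(convert_boxes(image, boxes, FallbackSegmenter()))
    return out


def average_reports(reports: Sequence[MetricsReport]) -> MetricsReport:
    """NaN-aware mean of per-image reports (per-class breakdown averaged too)."""

    def mean(vals):
        vals = [v for v in vals if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    classes = sorted({c for r in reports for c in r.per_class})
    per_class = {
        c: {
            key: mean([r.per_class[c][key] for r in reports if c in r.per_class])
            for key in next(iter(reports)).per_class[classes[0]]
        }
        for c in classes
    } if classes else {}
    return MetricsReport(
        dice=mean([r.dice for r in reports]),
        iou=mean([r.iou for r in reports]),
        aji=mean([r.aji for r in reports]),
        auc=mean([r.auc for r in reports]),
        recall=mean([r.recall for r in reports]),
        precision=mean([r.precision for r in reports]),
        best_f1=mean([r.best_f1 for r in reports]),
        instance_f1=mean([r.instance_f1 for r in reports]),
        per_class=per_class,
        n_images=sum(r.n_images for r in reports),
    )


def evaluate_model(
    model: AdapterModel,
    samples: Sequence[Sample],
    sigma: float = 2.0,
) -> MetricsReport:
    reports = []
    for image, inst, truth in samples:
        probs = predict(model, image, sigma)
        reports.append(
            evaluate_image(probs, {c: truth.masks[c] for c in truth.classes}, inst)
        )
    return average_reports(reports)


def _write_samples(directory: Path, samples: Sequence[Sample]) -> None:
    for i, (image, inst, truth) in enumerate(samples):
        d = directory / f"img_{i:03d}"
        d.mkdir(parents=True, exist_ok=True)
        _io.write_image(d / "image.tiff", image)
        _io.write_instance_mask(d / "instances.tiff", inst)
        _io.write_class_masks(d, truth, prefix="truth")


def run_pipeline(cfg: RunConfig, write_artifacts: bool = True) -> MetricsReport:
    """Execute the full simulate/annotate/train/eval chain for one config.

    Artifacts (resolved config, dataset, annotations, checkpoint, history,
    metrics) land under ``cfg.out_dir``; a stage failure propagates with the
    stage name after partial outputs are persisted.
    """
    out = Path(cfg.out_dir)
    if write_artifacts:
        out.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(out / "config.yaml")

    stage = "simulate"
    try:
        train_samples = simulate_dataset(cfg, "train", cfg.synth.n_train)
        val_samples = simulate_dataset(cfg, "val", cfg.synth.n_val)
        test_samples = simulate_dataset(cfg, "test", cfg.synth.n_test)
        if write_artifacts:
            _write_samples(out / "data" / "train", train_samples)
            _write_samples(out / "data" / "val", val_samples)
            _write_samples(out / "data" / "test", test_samples)

        stage = "annotate"
        train_annotations = make_training_annotations(cfg, train_samples)
        if write_artifacts:
            for i, ann in enumerate(train_annotations):
                _io.write_class_masks(out / "data" / "train" / f"img_{i:03d}", ann, prefix="ann")

        stage = "train"
        model = AdapterModel(
            n_classes=len(cfg.synth.n_per_class),
            base_width=cfg.base_width,
            seed=stage_seed(cfg.seed, "train"),
        )
        train_pairs = [
            (img, ann) for (img, _, _), ann in zip(train_samples, train_annotations)
        ]
        val_pairs = [(img, truth) for img, _, truth in val_samples]
        model, history = train(
            model,
            train_pairs,
            dataclasses.replace(cfg.train, seed=stage_seed(cfg.seed, "train", 1)),
            val_dataset=val_pairs,
        )
        if write_artifacts:
            save_checkpoint(model, out / "checkpoint.npz")
            (out / "history.jsonl").write_text(
                "\n".join(json.dumps(h) for h in history) + "\n"
            )

        stage = "eval"
        report = evaluate_model(model, test_samples, cfg.train.texture_sigma)
        if write_artifacts:
            (out / "metrics.json").write_text(report.to_json())
            (out / "metrics.csv").write_text(
                report.csv_header() + "\n" + report.to_csv_row() + "\n"
            )
        return report
    except Exception:
        logger.exception("pipeline failed during stage %r", stage)
        raise
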