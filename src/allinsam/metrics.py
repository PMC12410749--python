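"""Segmentation evaluation suite.

Pixel-level: Dice, IoU, ROC AUC, precision/recall at 0.5, best F1 over
thresholds.  Instance-level: detection F1 after one-to-one IoU matching, and
the aggregated Jaccard index (AJI) standard in nuclei-segmentation
benchmarks.  Conventions: metrics are in [0, 1]; the degenerate both-empty
case scores 1.0 (logged) so per-image averages never propagate NaN;
threshold-free metrics on single-class truth return NaN with a warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn import metrics as _skm

from .types import InstanceMask, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "dice_coefficient",
    "iou_score",
    "instance_f1",
    "aggregated_jaccard",
    "pixel_auc",
    "best_f1_and_pr",
    "MetricsReport",
    "evaluate_image",
]


def _binarize(a: np.ndarray) -> np.ndarray:
    return np.asarray(a) > 0


def dice_coefficient(pred: np.ndarray, truth: np.ndarray) -> float:
    """2|A∩B| / (|A|+|B|); both-empty -> 1.0 by convention."""
    a, b = _binarize(pred), _binarize(truth)
    if a.shape != b.shape:
        raise ValidationError("pred/truth shape mismatch")
    sa, sb = int(a.sum()), int(b.sum())
    if sa == 0 and sb == 0:
        logger.info("dice_coefficient: both masks empty, returning 1.0")
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def iou_score(pred: np.ndarray, truth: np.ndarray) -> float:
    """|A∩B| / |A∪B|; both-empty -> 1.0 by convention."""
    a, b = _binarize(pred), _binarize(truth)
    if a.shape != b.shape:
        raise ValidationError("pred/truth shape mismatch")
    union = int((a | b).sum())
    if union == 0:
        logger.info("iou_score: both masks empty, returning 1.0")
        return 1.0
    return int((a & b).sum()) / union


def _pairwise_iou(pred: InstanceMask, truth: InstanceMask):
    """IoU matrix between predicted and true instances (sparse, via overlap)."""
    p_ids = pred.instance_ids
    t_ids = truth.instance_ids
    p_index = {pid: i for i, pid in enumerate(p_ids)}
    t_index = {tid: j for j, tid in enumerate(t_ids)}
    p_area = {pid: int((pred.labels == pid).sum()) for pid in p_ids}
    t_area = {tid: int((truth.labels == tid).sum()) for tid in t_ids}
    iou = np.zeros((len(p_ids), len(t_ids)))
    both = (pred.labels > 0) & (truth.labels > 0)
    pairs, counts = np.unique(
        np.stack([pred.labels[both], truth.labels[both]]), axis=1, return_counts=True
    )
    for (pid, tid), inter in zip(pairs.T, counts):
        i, j = p_index[int(pid)], t_index[int(tid)]
        union = p_area[int(pid)] + t_area[int(tid)] - int(inter)
        iou[i, j] = inter / union
    return p_ids, t_ids, iou


def instance_f1(
    pred: InstanceMask,
    truth: InstanceMask,
    iou_thresh: float = 0.5,
    matching: str = "greedy",
) -> float:
    """Detection F1 after one-to-one instance matching at an IoU threshold.

    Pairs are matched greedily in descending IoU (each instance used once);
    matches with IoU >= ``iou_thresh`` are true positives and
    F1 = 2TP / (2TP + FP + FN).  Both-empty maps score 1.0.
    """
    if matching != "greedy":
        raise ValidationError("only greedy matching is implemented")
    p_ids, t_ids, iou = _pairwise_iou(pred, truth)
    if not p_ids and not t_ids:
        logger.info("instance_f1: both maps empty, returning 1.0")
        return 1.0
    tp = 0
    if p_ids and t_ids:
        order = np.argsort(-iou, axis=None, kind="stable")
        used_p, used_t = set(), set()
        for flat in order:
            i, j = divmod(int(flat), iou.shape[1])
            if iou[i, j] < iou_thresh:
                break
            if i in used_p or j in used_t:
                continue
            used_p.add(i)
            used_t.add(j)
            tp += 1
    fp = len(p_ids) - tp
    fn = len(t_ids) - tp
    return 2.0 * tp / (2.0 * tp + fp + fn) if (tp + fp + fn) else 1.0


def aggregated_jaccard(pred: InstanceMask, truth: InstanceMask) -> float:
    """Aggregated Jaccard index (AJI).

    Each ground-truth instance is matched to the predicted instance that
    maximizes IoU (a predicted instance is usable once); the matched
    intersections and unions accumulate, unmatched ground truth adds its area
    to the union, and every unused predicted instance is added to the union.
    The pred-vs-truth direction is fixed by the API (AJI is not symmetric).
    """
    p_ids, t_ids, iou = _pairwise_iou(pred, truth)
    if not p_ids and not t_ids:
        logger.info("aggregated_jaccard: both maps empty, returning 1.0")
        return 1.0
    p_area = {pid: int((pred.labels == pid).sum()) for pid in p_ids}
    t_area = {tid: int((truth.labels == tid).sum()) for tid in t_ids}

    used_pred = set()
    inter_acc = 0
    union_acc = 0
    for j, tid in enumerate(t_ids):
        best_i = -1
        best = 0.0
        for i in range(len(p_ids)):
            if i in used_pred:
                continue
            if iou[i, j] > best:
                best = iou[i, j]
                best_i = i
        if best_i >= 0 and best > 0:
            pid = p_ids[best_i]
            inter = int(((pred.labels == pid) & (truth.labels == tid)).sum())
            union_acc += p_area[pid] + t_area[tid] - inter
            inter_acc += inter
            used_pred.add(best_i)
        else:
            union_acc += t_area[tid]
    for i, pid in enumerate(p_ids):
        if i not in used_pred:
            union_acc += p_area[pid]
    return inter_acc / union_acc if union_acc else 1.0


def pixel_auc(prob: np.ndarray, truth: np.ndarray) -> float:
    """ROC AUC over pixel scores; NaN (with warning) if truth has one class."""
    y = _binarize(truth).ravel().astype(int)
    s = np.asarray(prob, dtype=np.float64).ravel()
    if s.min() < 0 or s.max() > 1:
        raise ValidationError("probability map must be in [0, 1]")
    if y.min() == y.max():
        logger.warning("pixel_auc: single-class truth, AUC undefined (NaN)")
        return float("nan")
    return float(_skm.roc_auc_score(y, s))


def best_f1_and_pr(
    prob: np.ndarray, truth: np.ndarray, threshold: float = 0.5
) -> Tuple[float, float, float]:
    """(best F1 over all thresholds, recall@threshold, precision@threshold).

    Empty truth: recall is NaN (warned); precision is still defined from the
    thresholded prediction (1.0 if it predicts nothing).
    """
    y = _binarize(truth).ravel().astype(int)
    s = np.asarray(prob, dtype=np.float64).ravel()
    hard = s >= threshold
    tp = int((hard & (y == 1)).sum())
    fp = int((hard & (y == 0)).sum())
    fn = int((~hard & (y == 1)).sum())
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    if y.sum() == 0:
        logger.warning("best_f1_and_pr: empty truth, recall undefined (NaN)")
        recall = float("nan")
        best = 1.0 if fp == 0 else 0.0
        return best, recall, precision
    recall = tp / (tp + fn)
    prec_curve, rec_curve, _ = _skm.precision_recall_curve(y, s)
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = 2 * prec_curve * rec_curve / (prec_curve + rec_curve)
    best = float(np.nanmax(f1)) if f1.size else 0.0
    return best, float(recall), float(precision)


@dataclass
class MetricsReport:
    """Aggregated evaluation over one or more images, with per-class breakdown."""

    dice: float
    iou: float
    aji: float
    auc: float
    recall: float
    precision: float
    best_f1: float
    instance_f1: float
    per_class: Dict[int, Dict[str, float]] = field(default_factory=dict)
    n_images: int = 1

    def to_json(self) -> str:
        d = asdict(self)
        d["per_class"] = {str(k): v for k, v in self.per_class.items()}
        return json.dumps(d, indent=2, sort_keys=True)

    def csv_header(self) -> str:
        return "Dice,AUC,Recall,Precision,bestF1,IoU,ADJ,instanceF1,n_images"

    def to_csv_row(self) -> str:
        vals = [
            self.dice, self.auc, self.recall, self.precision,
            self.best_f1, self.iou, self.aji, self.instance_f1,
        ]
        return ",".join(f"{v:.6f}" for v in vals) + f",{self.n_images}"


def _relabel(mask: np.ndarray) -> InstanceMask:
    from scipy import ndimage as ndi

    labels, n = ndi.label(_binarize(mask))
    return InstanceMask(labels, {i: 1 for i in range(1, n + 1)})


def evaluate_image(
    prob_per_class: Dict[int, np.ndarray],
    truth_per_class: Dict[int, np.ndarray],
    truth_instances: Optional[InstanceMask] = None,
    threshold: float = 0.5,
) -> MetricsReport:
    """Full metric suite for one image, averaged over the class channels.

    ``prob_per_class`` maps each cell class to its probability map; hard masks
    are obtained at ``threshold``.  Instance metrics compare connected
    components of the thresholded prediction against ``truth_instances``
    restricted to the class (or components of the truth mask if not given).
    """
    per_class: Dict[int, Dict[str, float]] = {}
    for cls, prob in sorted(prob_per_class.items()):
        truth = truth_per_class[cls]
        hard = prob >= threshold
        pred_inst = _relabel(hard)
        if truth_instances is not None:
            cls_labels = np.where(
                np.isin(
                    truth_instances.labels,
                    [i for i, c in truth_instances.class_of.items() if c == cls],
                ),
                truth_instances.labels,
                0,
            )
            true_inst = InstanceMask(
                cls_labels,
                {
                    i: c
                    for i, c in truth_instances.class_of.items()
                    if c == cls and (cls_labels == i).any()
                },
            )
        else:
            true_inst = _relabel(truth)
        bf1, rec, prec = best_f1_and_pr(prob, truth, threshold)
        per_class[cls] = {
            "dice": dice_coefficient(hard, truth),
            "iou": iou_score(hard, truth),
            "aji": aggregated_jaccard(pred_inst, true_inst),
            "auc": pixel_auc(prob, truth),
            "recall": rec,
            "precision": prec,
            "best_f1": bf1,
            "instance_f1": instance_f1(pred_inst, true_inst),
        }

    def _mean(key: str) -> float:
        vals = [per_class[c][key] for c in per_class]
        vals = [v for v in vals if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    return MetricsReport(
        dice=_mean("dice"),
        iou=_mean("iou"),
        aji=_mean("aji"),
        auc=_mean("auc"),
        recall=_mean("recall"),
        precision=_mean("precision"),
        best_f1=_mean("best_f1"),
        instance_f1=_mean("instance_f1"),
        per_class=per_class,
        n_images=1,
    )
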