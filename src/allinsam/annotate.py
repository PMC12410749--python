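"""Weak box annotations to pixel-level class masks.

Lay annotators draw one bounding box per nucleus (guided by the molecular
channels, which make the class a colour judgement).  A promptable segmenter
turns each box into a pixel mask; per-box masks are then merged into per-class
binary annotation masks.

The :class:`PromptableSegmenter` protocol is the attachment point for any
promptable foundation model.  :class:`FallbackSegmenter` is a deterministic
classical implementation (invert-Otsu-close-pick-component) that needs no
pre-trained weights, so the whole pipeline runs offline.
"""

from __future__ import annotations

import logging
from typing import Protocol, Sequence, Tuple, runtime_checkable

import numpy as np
from skimage import filters, morphology
from scipy import ndimage as ndi

from .types import (
    BoxAnnotationSet,
    ClassAnnotationSet,
    MultiplexImage,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PromptableSegmenter",
    "FallbackSegmenter",
    "fallback_box_segment",
    "convert_boxes",
    "conversion_instance_iou",
]

Box = Tuple[int, int, int, int]  # (rmin, cmin, rmax, cmax), half-open


@runtime_checkable
class PromptableSegmenter(Protocol):
    """Anything that maps (image, box prompt) -> binary mask.

    Contract: the returned H x W mask is nonzero only inside a small (<= 5 px)
    dilation of the box, and nonempty whenever the box contains above-background
    signal.  A real promptable foundation model can implement this directly.
    """

    name: str

    def segment(self, image: MultiplexImage, box: Box) -> np.ndarray: ...


def _inscribed_ellipse(shape: Tuple[int, int], box: Box) -> np.ndarray:
    rmin, cmin, rmax, cmax = box
    cr = (rmin + rmax - 1) / 2.0
    cc = (cmin + cmax - 1) / 2.0
    a = max((rmax - rmin) / 2.0, 1.0)
    b = max((cmax - cmin) / 2.0, 1.0)
    rr, ccg = np.mgrid[rmin:rmax, cmin:cmax]
    inside = ((rr - cr) / a) ** 2 + ((ccg - cc) / b) ** 2 <= 1.0
    out = np.zeros(shape, dtype=np.uint8)
    out[rmin:rmax, cmin:cmax] = inside
    return out


def fallback_box_segment(image: MultiplexImage, box: Box) -> np.ndarray:
    """Classical box-to-mask conversion on the structure channel.

    Within the box crop: invert (nuclei are dark), Otsu-threshold, close with
    a radius-1 disk, and keep the connected component nearest the box centre.
    A uniform-intensity box, or an empty thresholding result, falls back to
    the inscribed ellipse of the box.  The mask never leaves the box.
    """
    h, w = image.shape
    rmin, cmin, rmax, cmax = (int(v) for v in box)
    if not (0 <= rmin < rmax <= h and 0 <= cmin < cmax <= w):
        raise ValidationError(f"box {box} outside {h}x{w} image")
    if rmax - rmin < 2 or cmax - cmin < 2:
        raise ValidationError(f"box {box} smaller than 2x2")

    crop = image.structure[rmin:rmax, cmin:cmax]
    inverted = crop.max() - crop
    if np.ptp(inverted) < 1e-6:
        logger.info("fallback_box_segment: uniform box, inscribed-ellipse fallback")
        return _inscribed_ellipse((h, w), (rmin, cmin, rmax, cmax))

    fg = inverted > filters.threshold_otsu(inverted)
    fg = morphology.closing(fg, morphology.disk(1))
    labels, n = ndi.label(fg)
    if n == 0:
        logger.info("fallback_box_segment: empty threshold, inscribed-ellipse fallback")
        return _inscribed_ellipse((h, w), (rmin, cmin, rmax, cmax))

    center = np.array([(rmax - rmin - 1) / 2.0, (cmax - cmin - 1) / 2.0])
    centroids = ndi.center_of_mass(fg, labels, range(1, n + 1))
    nearest = 1 + int(np.argmin([np.hypot(*(np.array(c) - center)) for c in centroids]))
    out = np.zeros((h, w), dtype=np.uint8)
    out[rmin:rmax, cmin:cmax] = labels == nearest
    return out


class FallbackSegmenter:
    """Deterministic classical :class:`PromptableSegmenter` implementation."""

    name = "fallback"

    def segment(self, image: MultiplexImage, box: Box) -> np.ndarray:
        return fallback_box_segment(image, box)


def convert_boxes(
    image: MultiplexImage,
    boxes: BoxAnnotationSet,
    segmenter: PromptableSegmenter | None = None,
    n_classes: int | None = None,
) -> ClassAnnotationSet:
    """Run the segmenter on every box and merge masks into per-class masks.

    Same-class overlaps are unioned.  Cross-class overlaps go to the smaller
    per-box mask (a nucleus inside a larger spurious box should keep its own
    label), ties to the lower class index.  A segmenter failure on one box
    skips that box with a warning and continues.
    """
    if segmenter is None:
        segmenter = FallbackSegmenter()
    if n_classes is None:
        n_classes = max((b[0] for b in boxes.boxes), default=0)
        n_classes = max(n_classes, len(image.channel_roles) - 1)
    h, w = image.shape

    per_box = []
    for i, (cls, rmin, cmin, rmax, cmax) in enumerate(boxes.boxes):
        try:
            mask = np.asarray(segmenter.segment(image, (rmin, cmin, rmax, cmax)))
        except Exception:
            logger.warning("segmenter %s failed on box %d, skipped", segmenter.name, i)
            continue
        if mask.shape != (h, w):
            logger.warning("segmenter returned wrong-shape mask for box %d, skipped", i)
            continue
        if mask.any():
            per_box.append((cls, mask.astype(bool)))

    # paint larger masks first so smaller masks win contested pixels;
    # among equal areas paint higher class first so lower class wins ties
    order = sorted(
        range(len(per_box)),
        key=lambda i: (-int(per_box[i][1].sum()), -per_box[i][0]),
    )
    owner = np.zeros((h, w), dtype=np.int32)
    for i in order:
        cls, mask = per_box[i]
        owner[mask] = cls

    masks = {c: (owner == c).astype(np.uint8) for c in range(1, n_classes + 1)}
    if not masks:
        masks = {1: np.zeros((h, w), dtype=np.uint8)}
    return ClassAnnotationSet(masks=masks, provenance="converted")


def conversion_instance_iou(image, inst, boxes: BoxAnnotationSet, segmenter=None):
    """Per-instance IoU of box-converted masks against the true instances.

    Boxes are produced by ``derive_boxes`` in instance-id order, so box ``j``
    prompts for instance ``j``; each converted mask is scored against its own
    instance's pixels.  Returns one IoU per successfully converted box.
    """
    if segmenter is None:
        segmenter = FallbackSegmenter()
    ious = []
    for (cls, rmin, cmin, rmax, cmax), inst_id in zip(boxes.boxes, inst.instance_ids):
        try:
            mask = segmenter.segment(image, (rmin, cmin, rmax, cmax)).astype(bool)
        except Exception:
            logger.warning("conversion failed on instance %d, skipped", inst_id)
            continue
        truth = inst.labels == inst_id
        union = (mask | truth).sum()
        ious.append(float((mask & truth).sum() / union) if union else 1.0)
    return ious
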