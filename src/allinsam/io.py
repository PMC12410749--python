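"""File formats: multi-channel TIFF images, PNG class masks, JSON boxes, YAML config.

Images are stored as 16-bit multi-channel TIFF (channel-first planes) with
the channel roles embedded in the TIFF description as JSON; float values in
[0, 1] map to the uint16 grid on write and back on read, so data that
originated on that grid round-trips bitwise.  Instance masks are 16-bit
single-channel labelled TIFF; class masks are 8-bit 0/255 PNG.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Tuple

import imageio.v3 as iio
import numpy as np
import tifffile

from .types import BoxAnnotationSet, ClassAnnotationSet, InstanceMask, MultiplexImage, ValidationError

__all__ = [
    "read_image",
    "write_image",
    "read_instance_mask",
    "write_instance_mask",
    "read_class_masks",
    "write_class_masks",
    "read_boxes",
    "write_boxes",
]

_U16 = 65535.0


def write_image(path, image: MultiplexImage) -> None:
    path = Path(path)
    planes = np.rint(image.pixels * _U16).astype(np.uint16).transpose(2, 0, 1)
    tifffile.imwrite(
        path,
        planes,
        photometric="minisblack",
        description=json.dumps({"channel_roles": image.channel_roles}),
    )


def read_image(path) -> MultiplexImage:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description or ""
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = _U16
    else:
        raise ValidationError(f"unsupported bit depth {arr.dtype} in {path}")
    if arr.ndim == 2:
        arr = arr[None]
    pixels = arr.astype(np.float64).transpose(1, 2, 0) / scale
    try:
        roles = json.loads(desc)["channel_roles"]
    except (json.JSONDecodeError, KeyError, TypeError):
        roles = ["structure"] + [f"marker:{c}" for c in range(1, pixels.shape[2])]
    return MultiplexImage(pixels=pixels, channel_roles=roles)


def write_instance_mask(path, mask: InstanceMask) -> None:
    labels = mask.labels
    if labels.max() > 65535:
        raise ValidationError("more than 65535 instances cannot be stored as 16-bit")
    tifffile.imwrite(
        Path(path),
        labels.astype(np.uint16),
        description=json.dumps({"class_of": {str(k): v for k, v in mask.class_of.items()}}),
    )


def read_instance_mask(path) -> InstanceMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"instance mask not found: {path}")
    with tifffile.TiffFile(path) as tf:
        labels = tf.asarray().astype(np.int32)
        desc = tf.pages[0].description or ""
    try:
        class_of = {int(k): int(v) for k, v in json.loads(desc)["class_of"].items()}
    except (json.JSONDecodeError, KeyError, TypeError):
        class_of = {int(i): 1 for i in np.unique(labels) if i > 0}
    present = set(int(i) for i in np.unique(labels) if i > 0)
    return InstanceMask(labels, {i: c for i, c in class_of.items() if i in present})


def write_class_masks(directory, ann: ClassAnnotationSet, prefix: str = "class") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for cls, mask in ann.masks.items():
        iio.imwrite(directory / f"{prefix}_{cls}.png", (mask * 255).astype(np.uint8))
    (directory / f"{prefix}_provenance.json").write_text(
        json.dumps({"provenance": ann.provenance, "classes": sorted(ann.masks)})
    )


def read_class_masks(directory, prefix: str = "class") -> ClassAnnotationSet:
    directory = Path(directory)
    meta_path = directory / f"{prefix}_provenance.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"annotation metadata not found: {meta_path}")
    meta = json.loads(meta_path.read_text())
    masks: Dict[int, np.ndarray] = {}
    for cls in meta["classes"]:
        arr = iio.imread(directory / f"{prefix}_{cls}.png")
        masks[int(cls)] = (np.asarray(arr) > 127).astype(np.uint8)
    return ClassAnnotationSet(masks=masks, provenance=meta["provenance"])


def write_boxes(path, boxes: BoxAnnotationSet) -> None:
    payload = {
        "mode": boxes.mode,
        "boxes": [
            {"class": cls, "bbox": [rmin, cmin, rmax, cmax]}
            for cls, rmin, cmin, rmax, cmax in boxes.boxes
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_boxes(path) -> BoxAnnotationSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"box file not found: {path}")
    payload = json.loads(path.read_text())
    boxes = []
    for i, entry in enumerate(payload.get("boxes", [])):
        bbox = entry["bbox"]
        if not (bbox[0] < bbox[2] and bbox[1] < bbox[3]):
            raise ValidationError(f"box {i}: degenerate bbox {bbox}")
        boxes.append((int(entry["class"]), *(int(v) for v in bbox)))
    return BoxAnnotationSet(boxes=boxes, mode=payload.get("mode", "tight"))
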