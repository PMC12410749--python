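"""Core container types shared across the pipeline.

Conventions used everywhere in this package:

* pixel coordinates are 0-based ``(row, col)``,
* bounding boxes are half-open ``(row_min, col_min, row_max, col_max)``,
* images are ``H x W x C`` float arrays with values in ``[0, 1]``,
* channel 0 of a multiplex image is the structure stain (the only channel a
  trained model sees at inference); channels ``1..C-1`` are molecular markers,
  one per cell class.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

__all__ = [
    "NucleusSpec",
    "MultiplexImage",
    "InstanceMask",
    "ClassAnnotationSet",
    "BoxAnnotationSet",
    "NoiseConfig",
    "PrototypeSet",
    "MOCLConfig",
    "ValidationError",
    "CapacityError",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


class CapacityError(ValidationError):
    """Raised when a requested nucleus layout cannot fit in the image."""


@dataclass(frozen=True)
class NucleusSpec:
    """Geometry and appearance of one synthetic nucleus.

    ``cell_class`` is 1-based; ``intensity`` is the structure-channel darkness
    scale in ``(0, 1]`` (1 = darkest nucleus the renderer draws).
    """

    center: Tuple[float, float]
    radii: Tuple[float, float]
    orientation: float
    cell_class: int
    intensity: float

    def __post_init__(self) -> None:
        if self.radii[0] <= 0 or self.radii[1] <= 0:
            raise ValidationError(f"nucleus radii must be positive, got {self.radii}")
        if self.cell_class < 1:
            raise ValidationError(f"cell_class must be >= 1, got {self.cell_class}")
        if not (0 < self.intensity <= 1):
            raise ValidationError(f"intensity must be in (0, 1], got {self.intensity}")


@dataclass
class MultiplexImage:
    """A registered multi-channel patch: structure stain + molecular markers.

    ``channel_roles[0]`` must be ``"structure"``; marker channels are labelled
    ``"marker:<class>"`` and are bright inside nuclei of that class only.
    """

    pixels: np.ndarray  # H x W x C float in [0, 1]
    channel_roles: List[str]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3:
            raise ValidationError("pixels must be H x W x C")
        if self.pixels.shape[2] < 2:
            raise ValidationError("a multiplex image needs >= 2 channels")
        if len(self.channel_roles) != self.pixels.shape[2]:
            raise ValidationError("channel_roles length must match channel count")
        if sum(r == "structure" for r in self.channel_roles) != 1:
            raise ValidationError("exactly one channel must have role 'structure'")
        if self.channel_roles[0] != "structure":
            raise ValidationError("channel 0 must be the structure channel")
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("pixel values must be finite")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValidationError("pixel values must lie in [0, 1]")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    @property
    def structure(self) -> np.ndarray:
        return self.pixels[:, :, 0]

    def marker(self, cell_class: int) -> np.ndarray:
        role = f"marker:{cell_class}"
        try:
            idx = self.channel_roles.index(role)
        except ValueError as exc:
            raise ValidationError(f"no channel with role {role!r}") from exc
        return self.pixels[:, :, idx]


@dataclass
class InstanceMask:
    """Labelled instance map: 0 = background, i > 0 = instance id."""

    labels: np.ndarray  # H x W int
    class_of: Dict[int, int]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValidationError("instance labels must be H x W")
        if self.labels.min() < 0:
            raise ValidationError("instance labels must be non-negative")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.class_of)
        if missing:
            raise ValidationError(f"instances missing from class_of: {sorted(missing)}")

    @property
    def instance_ids(self) -> List[int]:
        return sorted(int(i) for i in set(np.unique(self.labels)) - {0})

    def class_mask(self, cell_class: int) -> np.ndarray:
        """Binary union of all instances of one class."""
        ids = [i for i in self.instance_ids if self.class_of[i] == cell_class]
        out = np.zeros(self.labels.shape, dtype=bool)
        for i in ids:
            out |= self.labels == i
        return out


_PROVENANCES = ("truth", "expert", "lay", "converted")


@dataclass
class ClassAnnotationSet:
    """Per-class binary masks (the annotation Y) with a provenance tag."""

    masks: Dict[int, np.ndarray]  # class -> H x W binary
    provenance: str

    def __post_init__(self) -> None:
        if self.provenance not in _PROVENANCES:
            raise ValidationError(
                f"provenance must be one of {_PROVENANCES}, got {self.provenance!r}"
            )
        clean: Dict[int, np.ndarray] = {}
        shape = None
        for cls, mask in self.masks.items():
            arr = np.asarray(mask)
            if not np.isin(arr, (0, 1)).all():
                raise ValidationError(f"class {cls} mask is not binary")
            arr = arr.astype(np.uint8)
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValidationError("all class masks must share one shape")
            clean[int(cls)] = arr
        self.masks = clean

    @property
    def classes(self) -> List[int]:
        return sorted(self.masks)

    def copy(self) -> "ClassAnnotationSet":
        return ClassAnnotationSet(
            {c: m.copy() for c, m in self.masks.items()}, self.provenance
        )


@dataclass
class BoxAnnotationSet:
    """Weak box annotations: one ``(class, rmin, cmin, rmax, cmax)`` per nucleus."""

    boxes: List[Tuple[int, int, int, int, int]]
    mode: str  # "tight" | "random"

    def __post_init__(self) -> None:
        if self.mode not in ("tight", "random"):
            raise ValidationError(f"mode must be 'tight' or 'random', got {self.mode!r}")
        for i, box in enumerate(self.boxes):
            cls, rmin, cmin, rmax, cmax = box
            if cls < 1:
                raise ValidationError(f"box {i}: cell class must be >= 1")
            if not (rmin < rmax and cmin < cmax):
                raise ValidationError(
                    f"box {i}: degenerate bbox {[rmin, cmin, rmax, cmax]}"
                )
        self.boxes = [tuple(int(v) for v in b) for b in self.boxes]  # type: ignore[misc]


@dataclass(frozen=True)
class NoiseConfig:
    """Lay-annotator noise model applied to clean class masks.

    fp_rate
        fraction of background pixels turned foreground per class, injected as
        small object-shaped blobs (3-6 px radius), not salt-and-pepper.
    fn_rate
        per-instance probability that an annotator misses the nucleus entirely.
    class_swap_rate
        per-instance probability that a kept nucleus lands in the wrong class mask.
    boundary_jitter
        max radius (px) of per-instance erosion or dilation of the drawn contour.
    """

    fp_rate: float = 0.0
    fn_rate: float = 0.0
    class_swap_rate: float = 0.0
    boundary_jitter: int = 0

    def __post_init__(self) -> None:
        for name in ("fp_rate", "fn_rate", "class_swap_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.boundary_jitter < 0:
            raise ValidationError("boundary_jitter must be >= 0")


@dataclass
class PrototypeSet:
    """The k highest-confidence annotated-pixel embeddings (prototypes)."""

    embeddings: np.ndarray  # k x M
    confidences: np.ndarray  # k, sorted non-increasing

    def __post_init__(self) -> None:
        self.embeddings = np.asarray(self.embeddings, dtype=np.float64)
        self.confidences = np.asarray(self.confidences, dtype=np.float64)
        if self.embeddings.ndim != 2:
            raise ValidationError("prototype embeddings must be k x M")
        if self.confidences.shape != (self.embeddings.shape[0],):
            raise ValidationError("confidences must have one entry per prototype")
        if self.k < 1:
            raise ValidationError("a prototype set needs k >= 1")
        if np.any(np.diff(self.confidences) > 1e-12):
            raise ValidationError("confidences must be sorted non-increasing")

    @property
    def k(self) -> int:
        return self.embeddings.shape[0]


@dataclass(frozen=True)
class MOCLConfig:
    """Knobs of the corrective-learning loss.

    k
        number of prototype pixels: an int, or a fraction of the annotated
        pixels (default 5%, never below 1).
    aggregation
        how the k per-prototype cosine scores collapse to one score per pixel.
    background_weight
        loss weight on pixels outside the annotation; 0 reproduces the literal
        "multiply by Y" weighting that silences background supervision.
    """

    k: float | int = 0.05
    aggregation: str = "mean"
    dice_smooth: float = 1e-6
    background_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.aggregation not in ("mean", "max"):
            raise ValidationError("aggregation must be 'mean' or 'max'")
        if self.dice_smooth <= 0:
            raise ValidationError("dice_smooth must be > 0")
        if isinstance(self.k, float) and not (0 < self.k <= 1):
            raise ValidationError("fractional k must be in (0, 1]")
        if isinstance(self.k, int) and self.k < 1:
            raise ValidationError("integer k must be >= 1")

    def resolve_k(self, n_annotated: int) -> int:
        if n_annotated < 1:
            raise ValidationError("cannot resolve k against an empty annotation")
        if isinstance(self.k, int):
            return min(self.k, n_annotated)
        return max(1, min(n_annotated, int(np.ceil(self.k * n_annotated))))
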