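"""Synthetic paired stain/molecular patches with ground truth and weak labels.

The generator emulates the data regime of molecular-empowered annotation:
a structure-stain channel (PAS-like, nuclei as dark ellipses on a textured
bright background) registered by construction with one immunofluorescence-like
marker channel per cell class that is bright only inside nuclei of that class.
Two-class layouts mimic the podocyte/mesangial setting: the classes differ in
size and chromatin darkness on the structure channel, so a structure-only model
can in principle classify them, while the marker channels make the classes
trivially separable for an annotator.

Every operation is a pure function of its inputs and an integer seed.
"""

from __future__ import annotations

import logging
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi

from .types import (
    BoxAnnotationSet,
    CapacityError,
    ClassAnnotationSet,
    InstanceMask,
    MultiplexImage,
    NoiseConfig,
    NucleusSpec,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "sample_layout",
    "render_multiplex",
    "derive_boxes",
    "corrupt_labels",
    "render_patch",
    "class_appearance",
]

# Per-class appearance ranges (radii in px, intensity = darkness scale).
# Class 1 emulates the larger, darker nucleus type; class 2 the smaller,
# paler one; further classes interpolate.  Morphological separation between
# classes is deliberate: markers exist only at annotation time, so the
# structure channel must carry the class signal a trained model uses.
_CLASS_RADII = {1: (6.0, 9.0), 2: (4.0, 6.5)}
_CLASS_INTENSITY = {1: (0.75, 0.95), 2: (0.45, 0.65)}


def class_appearance(cell_class: int) -> Tuple[Tuple[float, float], Tuple[float, float]]:
    """(radius range, darkness range) for a class; classes > 2 reuse class 2."""
    key = 1 if cell_class == 1 else 2
    return _CLASS_RADII[key], _CLASS_INTENSITY[key]


def sample_layout(
    height: int,
    width: int,
    n_per_class: Sequence[int],
    min_gap: float,
    seed: int,
) -> List[NucleusSpec]:
    """Rejection-sample nucleus specs with a minimum centre-to-centre gap.

    Returns ``sum(n_per_class)`` specs, or fewer (with a warning) if rejection
    sampling exhausts ``10 * n`` attempts.  Raises :class:`CapacityError` when
    the requested packing cannot possibly fit.
    """
    if height < 64 or width < 64:
        raise ValidationError("image must be at least 64 x 64")
    if not len(n_per_class):
        raise ValidationError("n_per_class must be nonempty")
    if min_gap < 0:
        raise ValidationError("min_gap must be >= 0")
    n_total = int(sum(n_per_class))
    if min_gap > 0:
        # disc-packing bound: each centre excludes a disc of radius min_gap/2
        if n_total * np.pi * (min_gap / 2.0) ** 2 > height * width:
            raise CapacityError(
                f"cannot place {n_total} nuclei with min_gap={min_gap} "
                f"in a {height}x{width} image"
            )

    rng = np.random.default_rng(seed)
    margin = 10.0  # keep ellipses inside bounds
    specs: List[NucleusSpec] = []
    centers: List[Tuple[float, float]] = []
    max_attempts = 10 * n_total
    attempts = 0
    for cls_idx, count in enumerate(n_per_class):
        cell_class = cls_idx + 1
        (r_lo, r_hi), (i_lo, i_hi) = class_appearance(cell_class)
        placed = 0
        while placed < count and attempts < max_attempts:
            attempts += 1
            r = rng.uniform(margin, height - margin)
            c = rng.uniform(margin, width - margin)
            if any((r - cr) ** 2 + (c - cc) ** 2 < min_gap**2 for cr, cc in centers):
                continue
            r_major = rng.uniform(r_lo, r_hi)
            r_minor = r_major * rng.uniform(0.6, 0.95)
            specs.append(
                NucleusSpec(
                    center=(r, c),
                    radii=(r_major, r_minor),
                    orientation=rng.uniform(0, np.pi),
                    cell_class=cell_class,
                    intensity=rng.uniform(i_lo, i_hi),
                )
            )
            centers.append((r, c))
            placed += 1
    if len(specs) < n_total:
        logger.warning(
            "placed only %d of %d nuclei after %d attempts", len(specs), n_total, attempts
        )
    return specs


def _ellipse_mask(shape: Tuple[int, int], spec: NucleusSpec) -> np.ndarray:
    h, w = shape
    (cr, cc), (a, b), th = spec.center, spec.radii, spec.orientation
    r0 = max(int(np.floor(cr - a - 1)), 0)
    r1 = min(int(np.ceil(cr + a + 1)) + 1, h)
    c0 = max(int(np.floor(cc - a - 1)), 0)
    c1 = min(int(np.ceil(cc + a + 1)) + 1, w)
    rr, cci = np.mgrid[r0:r1, c0:c1]
    dr = rr - cr
    dc = cci - cc
    u = dr * np.cos(th) + dc * np.sin(th)
    v = -dr * np.sin(th) + dc * np.cos(th)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    out = np.zeros(shape, dtype=bool)
    out[r0:r1, c0:c1] = inside
    return out


def _smooth_field(shape: Tuple[int, int], rng: np.random.Generator, sigma: float) -> np.ndarray:
    """Low-frequency multiplicative texture field in roughly [0.85, 1.15]."""
    field = ndi.gaussian_filter(rng.standard_normal(shape), sigma)
    span = field.max() - field.min()
    if span > 0:
        field = (field - field.min()) / span - 0.5
    return 1.0 + 0.3 * field


def render_multiplex(
    layout: Sequence[NucleusSpec],
    n_classes: int,
    noise_sd: float,
    seed: int,
    shape: Tuple[int, int] | None = None,
    n_distractors: int | None = None,
) -> Tuple[MultiplexImage, InstanceMask]:
    """Rasterize a layout into a registered (structure, markers) image pair.

    The structure channel is a bright textured background with dark ellipses;
    marker channel ``c`` equals the nucleus intensity inside class-``c`` nuclei
    and 0 outside, plus clipped Gaussian noise of sd ``noise_sd`` (exactly zero
    noise when ``noise_sd == 0``).  Overlaps resolve by z-order: later specs in
    ``layout`` win, and the instance mask records the visible (top) pixels.
    ``shape`` defaults to the layout's extent.

    ``n_distractors`` small dark non-nucleus objects (pyknotic debris /
    injured-tissue artifacts, default half the nucleus count) are drawn on the
    structure channel only: they carry no marker signal and are absent from
    the instance mask.  They emulate the injured-vs-normal morphology
    variation of real tissue and give annotator false positives something
    nucleus-like to latch onto.
    """
    if not len(layout):
        raise ValidationError("layout must be nonempty")
    if not (0 <= noise_sd < 0.5):
        raise ValidationError("noise_sd must be in [0, 0.5)")
    for spec in layout:
        if spec.cell_class > n_classes:
            raise ValidationError(
                f"spec class {spec.cell_class} exceeds n_classes={n_classes}"
            )

    if shape is None:
        h = int(max(np.ceil(s.center[0] + s.radii[0]) for s in layout)) + 12
        w = int(max(np.ceil(s.center[1] + s.radii[0]) for s in layout)) + 12
        h = max(h, 64)
        w = max(w, 64)
    else:
        h, w = int(shape[0]), int(shape[1])

    rng = np.random.default_rng(seed)
    labels = np.zeros((h, w), dtype=np.int32)
    class_of = {}
    intensity_of = {}
    for i, spec in enumerate(layout, start=1):
        mask = _ellipse_mask((h, w), spec)
        labels[mask] = i  # z-order: later spec overwrites
        class_of[i] = spec.cell_class
        intensity_of[i] = spec.intensity

    # drop instances fully occluded by later ones
    survivors = set(np.unique(labels)) - {0}
    class_of = {i: c for i, c in class_of.items() if i in survivors}

    texture = _smooth_field((h, w), rng, sigma=12.0)
    structure = 0.85 * np.ones((h, w))
    distractor_mask = np.zeros((h, w), dtype=bool)
    if n_distractors is None:
        n_distractors = max(2, len(layout) // 2)
    for _ in range(n_distractors):
        spec = NucleusSpec(
            center=(rng.uniform(4, h - 4), rng.uniform(4, w - 4)),
            radii=(rng.uniform(2.0, 3.5), rng.uniform(1.2, 2.2)),
            orientation=rng.uniform(0, np.pi),
            cell_class=1,  # placeholder; distractors carry no class
            intensity=rng.uniform(0.4, 0.6),
        )
        m = _ellipse_mask((h, w), spec) & (labels == 0)
        structure[m] = 0.85 * (1.0 - spec.intensity)
        distractor_mask |= m
    for i in sorted(class_of):
        m = labels == i
        structure[m] = 0.85 * (1.0 - intensity_of[i])
    structure = np.clip(structure * texture, 0.0, 1.0)

    channels = [structure]
    for cls in range(1, n_classes + 1):
        marker = np.zeros((h, w))
        for i in sorted(class_of):
            if class_of[i] == cls:
                marker[labels == i] = intensity_of[i]
        if noise_sd > 0:
            marker = np.clip(marker + rng.normal(0.0, noise_sd, (h, w)), 0.0, 1.0)
        channels.append(marker)
    if noise_sd > 0:
        channels[0] = np.clip(channels[0] + rng.normal(0.0, noise_sd, (h, w)), 0.0, 1.0)

    image = MultiplexImage(
        pixels=np.stack(channels, axis=-1),
        channel_roles=["structure"] + [f"marker:{c}" for c in range(1, n_classes + 1)],
    )
    return image, InstanceMask(labels=labels, class_of=class_of)


def render_patch(
    height: int,
    width: int,
    n_per_class: Sequence[int],
    noise_sd: float,
    seed: int,
    min_gap: float = 14.0,
) -> Tuple[MultiplexImage, InstanceMask]:
    """Convenience wrapper: sample a layout and render it at a fixed size."""
    rng = np.random.default_rng(seed)
    layout_seed, render_seed = (int(s) for s in rng.integers(0, 2**31 - 1, 2))
    layout = sample_layout(height, width, n_per_class, min_gap, layout_seed)
    return render_multiplex(
        layout, len(n_per_class), noise_sd, render_seed, shape=(height, width)
    )


def derive_boxes(
    mask: InstanceMask, mode: str, jitter_px: int = 0, seed: int = 0
) -> BoxAnnotationSet:
    """One bounding box per instance, tight or with independent edge jitter.

    ``random`` mode shifts each edge by a uniform integer in
    ``[-jitter_px, +jitter_px]``, clips to the image, and enforces a minimum
    2x2 box.  ``tight`` mode ignores ``jitter_px``.
    """
    ids = mask.instance_ids
    if not ids:
        raise ValidationError("instance mask has no instances")
    if jitter_px < 0:
        raise ValidationError("jitter_px must be >= 0")
    if mode == "tight":
        jitter_px = 0
    elif mode != "random":
        raise ValidationError(f"unknown box mode {mode!r}")

    h, w = mask.labels.shape
    rng = np.random.default_rng(seed)
    boxes = []
    for i in ids:
        rows, cols = np.nonzero(mask.labels == i)
        rmin, rmax = int(rows.min()), int(rows.max()) + 1
        cmin, cmax = int(cols.min()), int(cols.max()) + 1
        if jitter_px:
            d = rng.integers(-jitter_px, jitter_px + 1, size=4)
            rmin, cmin, rmax, cmax = rmin + d[0], cmin + d[1], rmax + d[2], cmax + d[3]
        rmin = int(np.clip(rmin, 0, h - 2))
        cmin = int(np.clip(cmin, 0, w - 2))
        rmax = int(np.clip(rmax, rmin + 2, h))
        cmax = int(np.clip(cmax, cmin + 2, w))
        boxes.append((mask.class_of[i], rmin, cmin, rmax, cmax))
    return BoxAnnotationSet(boxes=boxes, mode=mode)


def _place_blob(
    mask: np.ndarray,
    background: np.ndarray,
    rng: np.random.Generator,
    salience: np.ndarray | None = None,
) -> int:
    """Add one 3-6 px-radius blob on background; returns pixels added.

    With ``salience`` given, blob centres are drawn proportionally to it
    (annotator false positives cluster on nucleus-like dark spots, they are
    not uniform over empty background).
    """
    h, w = mask.shape
    radius = int(rng.integers(3, 7))
    free = np.flatnonzero(background.ravel())
    if free.size == 0:
        return 0
    if salience is not None:
        weights = salience.ravel()[free]
        total = weights.sum()
        if total > 0:
            pos = int(rng.choice(free, p=weights / total))
        else:
            pos = int(free[rng.integers(0, free.size)])
    else:
        pos = int(free[rng.integers(0, free.size)])
    r0, c0 = divmod(pos, w)
    rr, cc = np.mgrid[
        max(r0 - radius, 0) : min(r0 + radius + 1, h),
        max(c0 - radius, 0) : min(c0 + radius + 1, w),
    ]
    blob = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    region = (slice(rr.min(), rr.max() + 1), slice(cc.min(), cc.max() + 1))
    addable = blob & background[region] & ~mask[region].astype(bool)
    mask[region][addable] = 1
    return int(addable.sum())


def corrupt_labels(
    truth: ClassAnnotationSet,
    inst: InstanceMask,
    cfg: NoiseConfig,
    seed: int,
    image: MultiplexImage | None = None,
) -> ClassAnnotationSet:
    """Simulate lay-annotator noise on clean class masks.

    Per instance: dropped with probability ``fn_rate``; surviving instances are
    reassigned to a uniformly chosen wrong class with probability
    ``class_swap_rate``; boundaries are eroded or dilated by a uniform radius
    up to ``boundary_jitter``.  Finally, ``fp_rate`` of the background pixels
    per class are set as 3-6 px blobs (annotators invent object-shaped marks,
    not salt-and-pepper).  When ``image`` is supplied, false-positive blobs
    land preferentially on dark background structures (distractors/debris),
    matching how annotators actually err; without it they are uniform.
    """
    if truth.provenance not in ("truth", "expert"):
        raise ValidationError(
            f"can only corrupt truth/expert annotations, got {truth.provenance!r}"
        )
    classes = truth.classes
    if all(truth.masks[c].sum() == 0 for c in classes):
        logger.warning("corrupt_labels: all-zero truth, returned unchanged")
        out = truth.copy()
        out.provenance = "lay"
        return out

    rng = np.random.default_rng(seed)
    shape = truth.masks[classes[0]].shape
    out = {c: np.zeros(shape, dtype=np.uint8) for c in classes}

    for i in inst.instance_ids:
        if rng.random() < cfg.fn_rate:
            continue  # annotator missed this nucleus
        true_cls = inst.class_of[i]
        cls = true_cls
        if len(classes) > 1 and rng.random() < cfg.class_swap_rate:
            others = [c for c in classes if c != true_cls]
            cls = others[int(rng.integers(0, len(others)))]
        blob = (inst.labels == i) & (truth.masks[true_cls] > 0)
        if cfg.boundary_jitter > 0:
            radius = int(rng.integers(0, cfg.boundary_jitter + 1))
            if radius:
                op = ndi.binary_dilation if rng.random() < 0.5 else ndi.binary_erosion
                jittered = op(blob, ndi.generate_binary_structure(2, 1), iterations=radius)
                blob = jittered if jittered.any() else blob  # never erase entirely
        out[cls][blob] = 1

    if cfg.fp_rate > 0:
        salience = None
        if image is not None:
            # darkness to the 4th power concentrates mass on nucleus-like spots
            salience = np.clip(image.structure.max() - image.structure, 0.0, None) ** 4
        for cls in classes:
            background = ~np.any([truth.masks[c] > 0 for c in classes], axis=0)
            target = int(round(cfg.fp_rate * background.sum()))
            added = 0
            for _ in range(10_000):
                if added >= target:
                    break
                added += _place_blob(out[cls], background, rng, salience)

    return ClassAnnotationSet(out, provenance="lay")
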