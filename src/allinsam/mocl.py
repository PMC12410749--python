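"""Molecular-oriented corrective learning (MOCL) loss components.

MOCL refines training under noisy (lay-annotator) labels.  For one target
class with annotation Y, prediction probability map W = f(X; theta)[:, 1] and
decoder embedding map E:

1. the k annotated pixels with highest confidence W are selected as prototype
   embeddings {(e_1, w_1), ..., (e_k, w_k)};
2. every pixel's embedding is scored by cosine similarity S against the
   prototypes (aggregated over k by mean or max);
3. per-pixel corrective weights omega(W) = exp(W) * Y and omega(S) = S * Y
   emphasize pixels where prediction and annotation agree;
4. the combined weight exp(W) * S (clipped at 0) scales pixel-wise soft-Dice
   and binary-cross-entropy terms, so probably-wrong annotated pixels pull the
   model less.

All functions are pure numpy and framework-agnostic; weights are meant to be
treated as constants (detached) by any surrounding training loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .types import MOCLConfig, PrototypeSet, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "confidence_map",
    "select_topk",
    "similarity_map",
    "WeightMaps",
    "weight_maps",
    "soft_dice_loss",
    "weighted_bce_loss",
    "mocl_loss",
    "EmptyAnnotationError",
]

_BCE_EPS = 1e-7


class EmptyAnnotationError(ValidationError):
    """Raised when prototypes are requested from an empty annotation mask."""


def confidence_map(probabilities: np.ndarray, class_index: int) -> np.ndarray:
    """Per-pixel confidence W for one class: the softmax probability slice.

    ``probabilities`` is H x W x n_classes and must be normalized per pixel.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    if p.ndim != 3:
        raise ValidationError("probabilities must be H x W x n_classes")
    if not (0 <= class_index < p.shape[2]):
        raise ValidationError(f"class_index {class_index} out of range")
    sums = p.sum(axis=2)
    if np.any(np.abs(sums - 1.0) > 1e-5):
        raise ValidationError("probabilities must sum to 1 per pixel (+-1e-5)")
    return p[:, :, class_index]


def select_topk(
    E: np.ndarray, W: np.ndarray, Y: np.ndarray, k: int
) -> PrototypeSet:
    """Top-k highest-confidence annotated pixels as (embedding, confidence) pairs.

    Ties in W are broken by row-major pixel order.  ``k`` larger than the
    annotation support is clamped with a warning; an empty Y raises
    :class:`EmptyAnnotationError` (the caller should skip the class).
    """
    E = np.asarray(E, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    Y = np.asarray(Y)
    if E.ndim != 3 or W.shape != E.shape[:2] or Y.shape != W.shape:
        raise ValidationError("shapes must be E: HxWxM, W: HxW, Y: HxW")
    flat_idx = np.flatnonzero(Y.ravel() > 0)  # row-major order
    n = flat_idx.size
    if n == 0:
        raise EmptyAnnotationError("annotation mask Y has no foreground pixels")
    if k > n:
        logger.warning("select_topk: k=%d clamped to |Y|=%d", k, n)
        k = n
    if k < 1:
        raise ValidationError("k must be >= 1")
    w_vals = W.ravel()[flat_idx]
    # stable sort on -W keeps row-major order among ties
    order = np.argsort(-w_vals, kind="stable")[:k]
    chosen = flat_idx[order]
    emb = E.reshape(-1, E.shape[2])[chosen]
    return PrototypeSet(embeddings=emb, confidences=w_vals[order])


def similarity_map(
    E: np.ndarray, protos: PrototypeSet, aggregation: str = "mean"
) -> np.ndarray:
    """Cosine similarity of every pixel embedding against the prototypes.

    The k per-prototype scores collapse to one score per pixel by ``mean``
    (default) or ``max``.  Zero-norm embeddings (pixel or prototype) score 0.
    """
    E = np.asarray(E, dtype=np.float64)
    if aggregation not in ("mean", "max"):
        raise ValidationError("aggregation must be 'mean' or 'max'")
    h, w, m = E.shape
    flat = E.reshape(-1, m)
    pix_norm = np.linalg.norm(flat, axis=1)
    pro = protos.embeddings
    pro_norm = np.linalg.norm(pro, axis=1)
    if np.any(pix_norm == 0):
        logger.warning("similarity_map: zero-norm pixel embeddings score 0")
    denom = np.outer(pix_norm, pro_norm)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = (flat @ pro.T) / denom
    cos[denom == 0] = 0.0
    cos = np.clip(cos, -1.0, 1.0)  # guard rounding
    agg = cos.mean(axis=1) if aggregation == "mean" else cos.max(axis=1)
    return agg.reshape(h, w)


@dataclass
class WeightMaps:
    """Corrective weights: omega(W) = exp(W)*Y, omega(S) = S*Y, and their product.

    ``combined`` is exp(W)*S clipped below at 0 on annotated pixels and
    ``background_weight`` elsewhere (the literal annotation-masked weighting is
    recovered with background_weight = 0).
    """

    w_conf: np.ndarray
    w_sim: np.ndarray
    combined: np.ndarray


def weight_maps(
    W: np.ndarray,
    S: np.ndarray,
    Y: np.ndarray,
    background_weight: float = 1.0,
) -> WeightMaps:
    W = np.asarray(W, dtype=np.float64)
    S = np.asarray(S, dtype=np.float64)
    Yb = np.asarray(Y).astype(np.float64)
    if not (W.shape == S.shape == Yb.shape):
        raise ValidationError("W, S, Y must share one shape")
    w_conf = np.exp(W) * Yb
    w_sim = S * Yb
    combined = np.where(
        Yb > 0, np.clip(w_conf * w_sim, 0.0, None), float(background_weight)
    )
    return WeightMaps(w_conf=w_conf, w_sim=w_sim, combined=combined)


def soft_dice_loss(
    Y: np.ndarray, P: np.ndarray, weights: np.ndarray | None = None,
    smooth: float = 1e-6,
) -> float:
    """Pixel-weighted soft Dice loss 1 - (2*sum(wYP)+s)/(sum(wY)+sum(wP)+s)."""
    Yf = np.asarray(Y, dtype=np.float64)
    Pf = np.asarray(P, dtype=np.float64)
    w = np.ones_like(Yf) if weights is None else np.asarray(weights, dtype=np.float64)
    if np.any(w < 0):
        raise ValidationError("dice weights must be >= 0")
    num = 2.0 * np.sum(w * Yf * Pf) + smooth
    den = np.sum(w * Yf) + np.sum(w * Pf) + smooth
    return float(1.0 - num / den)


def weighted_bce_loss(
    Y: np.ndarray, P: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Mean over pixels of w * [-Y log P - (1-Y) log(1-P)], P clipped to [eps, 1-eps]."""
    Yf = np.asarray(Y, dtype=np.float64)
    Pc = np.clip(np.asarray(P, dtype=np.float64), _BCE_EPS, 1.0 - _BCE_EPS)
    w = np.ones_like(Yf) if weights is None else np.asarray(weights, dtype=np.float64)
    terms = w * (-Yf * np.log(Pc) - (1.0 - Yf) * np.log(1.0 - Pc))
    return float(terms.mean())


def mocl_loss(
    Y: np.ndarray,
    P: np.ndarray,
    E: np.ndarray,
    cfg: MOCLConfig = MOCLConfig(),
) -> Tuple[float, Dict]:
    """Corrective-learning loss for one binary class channel.

    ``P`` is the foreground probability map (which is also the confidence W),
    ``E`` the decoder embedding map.  Returns the scalar loss and a
    diagnostics record.  Multiclass problems call this once per class channel
    and average.  An empty annotation falls back to the unweighted
    Dice + BCE with the corrective path skipped.
    """
    Yb = (np.asarray(Y) > 0).astype(np.float64)
    P = np.asarray(P, dtype=np.float64)
    n_annot = int(Yb.sum())
    if n_annot == 0:
        logger.info("mocl_loss: empty annotation channel, corrective terms skipped")
        loss = soft_dice_loss(Yb, P, None, cfg.dice_smooth) + weighted_bce_loss(Yb, P)
        return loss, {"k": 0, "mean_weight_on_y": None, "corrective": False}

    k = cfg.resolve_k(n_annot)
    protos = select_topk(E, P, Yb, k)
    S = similarity_map(E, protos, cfg.aggregation)
    wm = weight_maps(P, S, Yb, cfg.background_weight)
    loss = soft_dice_loss(Yb, P, wm.combined, cfg.dice_smooth) + weighted_bce_loss(
        Yb, P, wm.combined
    )
    diagnostics = {
        "k": k,
        "mean_weight_on_y": float(wm.combined[Yb > 0].mean()),
        "similarity_mean": float(S.mean()),
        "similarity_min": float(S.min()),
        "similarity_max": float(S.max()),
        "corrective": True,
    }
    return loss, diagnostics
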