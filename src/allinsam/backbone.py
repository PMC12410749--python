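"""Desk-scale adapter backbone: frozen trunk + trainable adapters + MOCL training.

The network is a small 3-level encoder-decoder (a stand-in trunk behind the
same contract a real promptable foundation backbone would satisfy): it takes
the structure channel only, is prompt-free at inference, emits per-pixel class
probabilities (softmax over background + cell classes), and exports the
penultimate decoder activation as the embedding map E (L2-normalized per
pixel) that the corrective loss consumes.

Adapter fine-tuning inserts small residual bottleneck blocks after every
encoder stage; each block additively receives a handcrafted texture feature
(high-pass residual of the structure channel) through a learned 1x1
projection.  In ``adapter`` mode only the adapters and the classifier head
update; the trunk is frozen and its parameter hash is verifiable before and
after training.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi

from . import mocl as _mocl
from .nn import Adam, AvgPool2, Conv2D, Param, ReLU, Upsample2, params_hash, softmax, softmax_backward
from .types import ClassAnnotationSet, MOCLConfig, MultiplexImage, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "texture_features",
    "Adapter",
    "AdapterModel",
    "TrainConfig",
    "train",
    "predict",
    "validation_dice",
    "save_checkpoint",
    "load_checkpoint",
]

_BCE_EPS = 1e-7


def texture_features(image: MultiplexImage | np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Handcrafted texture prompt: standardized high-pass residual, H x W x 1.

    The structure channel minus its Gaussian blur isolates fine texture
    (chromatin granularity, membrane edges); standardization to zero mean /
    unit variance makes the prompt scale-free.  A constant image yields an
    all-zero map.
    """
    if sigma <= 0:
        raise ValidationError("sigma must be > 0")
    chan = image.structure if isinstance(image, MultiplexImage) else np.asarray(image)
    if chan.ndim != 2:
        raise ValidationError("texture_features expects a single H x W channel")
    resid = chan - ndi.gaussian_filter(chan.astype(np.float64), sigma)
    sd = resid.std()
    if sd < 1e-12:
        return np.zeros(chan.shape + (1,))
    return ((resid - resid.mean()) / sd)[..., None]


class Adapter:
    """Residual bottleneck adapter with additive texture injection.

    h -> h + Up(ReLU(Down(h) + Proj(texture))).  The up-projection is
    zero-initialized so an untrained adapter is the identity.
    """

    def __init__(self, channels: int, rng: np.random.Generator, name: str = "adapter"):
        bottleneck = max(channels // 2, 4)
        self.down = Conv2D(channels, bottleneck, 1, rng, f"{name}.down")
        self.tex = Conv2D(1, bottleneck, 1, rng, f"{name}.tex")
        self.up = Conv2D(bottleneck, channels, 1, rng, f"{name}.up")
        self.up.weight.value[...] = 0.0
        self.relu = ReLU()

    @property
    def params(self) -> List[Param]:
        return self.down.params + self.tex.params + self.up.params

    def forward(self, h: np.ndarray, texture: np.ndarray) -> np.ndarray:
        z = self.relu.forward(self.down.forward(h) + self.tex.forward(texture))
        return h + self.up.forward(z)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dz = self.relu.backward(self.up.backward(dout))
        dh = self.down.backward(dz)
        self.tex.backward(dz)  # gradient w.r.t. the texture input is discarded
        return dout + dh


class AdapterModel:
    """3-level encoder-decoder with per-stage adapters and an embedding tap."""

    DOWN_FACTOR = 4

    def __init__(self, n_classes: int = 2, base_width: int = 8, seed: int = 0):
        if n_classes < 1 or base_width < 4:
            raise ValidationError("need n_classes >= 1 and base_width >= 4")
        self.n_classes = n_classes
        self.base_width = base_width
        self.seed = seed
        rng = np.random.default_rng(seed)
        w1, w2, w3 = base_width, base_width * 2, base_width * 4

        self.enc1 = Conv2D(1, w1, 3, rng, "enc1")
        self.enc2 = Conv2D(w1, w2, 3, rng, "enc2")
        self.enc3 = Conv2D(w2, w3, 3, rng, "enc3")
        self.dec2a = Conv2D(w3 + w2, w2, 1, rng, "dec2a")
        self.dec2b = Conv2D(w2, w2, 3, rng, "dec2b")
        self.dec1a = Conv2D(w2 + w1, w1, 1, rng, "dec1a")
        self.dec1b = Conv2D(w1, w1, 3, rng, "dec1b")
        self.head = Conv2D(w1, n_classes + 1, 1, rng, "head")
        self.adapters = [
            Adapter(w1, rng, "ad1"),
            Adapter(w2, rng, "ad2"),
            Adapter(w3, rng, "ad3"),
        ]
        self._relus = [ReLU() for _ in range(7)]
        self._pools = [AvgPool2() for _ in range(2)]
        self._tex_pools = [AvgPool2() for _ in range(2)]
        self._ups = [Upsample2() for _ in range(2)]
        self._cache: Optional[Tuple] = None

    # parameter groups -------------------------------------------------
    @property
    def trunk_params(self) -> List[Param]:
        layers = [self.enc1, self.enc2, self.enc3, self.dec2a, self.dec2b, self.dec1a, self.dec1b]
        return [p for l in layers for p in l.params]

    @property
    def adapter_params(self) -> List[Param]:
        return [p for a in self.adapters for p in a.params] + self.head.params

    @property
    def all_params(self) -> List[Param]:
        return self.trunk_params + self.adapter_params

    def trunk_hash(self) -> str:
        return params_hash(self.trunk_params)

    @property
    def embedding_channels(self) -> int:
        return self.base_width

    # forward / backward ------------------------------------------------
    def _pad(self, x: np.ndarray) -> Tuple[np.ndarray, Tuple[int, int]]:
        h, w = x.shape[1:3]
        f = self.DOWN_FACTOR
        ph = (-h) % f
        pw = (-w) % f
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)), mode="reflect")
        return x, (h, w)

    def forward_batch(
        self, x: np.ndarray, texture: np.ndarray
    ) -> Tuple[np.ndarray, np.ndarray]:
        """(N,H,W,1) structure + texture -> (probs (N,H,W,K+1), emb (N,H,W,M)).

        The embedding map is the penultimate decoder activation, L2-normalized
        per pixel; it is exported detached (no gradient flows through it).
        """
        if x.ndim != 4 or x.shape[-1] != 1:
            raise ValidationError("expected an N x H x W x 1 structure batch")
        x, (h0, w0) = self._pad(x)
        texture, _ = self._pad(texture)
        R, P, U, TP = self._relus, self._pools, self._ups, self._tex_pools

        t1 = texture
        t2 = TP[0].forward(t1)
        t3 = TP[1].forward(t2)

        a1 = self.adapters[0].forward(R[0].forward(self.enc1.forward(x)), t1)
        a2 = self.adapters[1].forward(R[1].forward(self.enc2.forward(P[0].forward(a1))), t2)
        a3 = self.adapters[2].forward(R[2].forward(self.enc3.forward(P[1].forward(a2))), t3)

        u2 = np.concatenate([U[0].forward(a3), a2], axis=-1)
        d2 = R[4].forward(self.dec2b.forward(R[3].forward(self.dec2a.forward(u2))))
        u1 = np.concatenate([U[1].forward(d2), a1], axis=-1)
        d1 = R[6].forward(self.dec1b.forward(R[5].forward(self.dec1a.forward(u1))))
        logits = self.head.forward(d1)
        probs = softmax(logits)

        norms = np.linalg.norm(d1, axis=-1, keepdims=True)
        emb = np.where(norms > 0, d1 / np.maximum(norms, 1e-12), 0.0)

        self._cache = (probs, (h0, w0), a3.shape[-1], a2.shape[-1], a1.shape[-1])
        return probs[:, :h0, :w0], emb[:, :h0, :w0]

    def backward_batch(self, dprobs: np.ndarray) -> None:
        """Accumulate parameter gradients from dL/dprobs (cropped shape)."""
        probs, (h0, w0), c3, c2, c1 = self._cache
        dp = np.zeros_like(probs)
        dp[:, :h0, :w0] = dprobs
        dlogits = softmax_backward(probs, dp)

        R, P, U = self._relus, self._pools, self._ups
        dd1 = R[6].backward(self.head.backward(dlogits))
        du1 = self.dec1a.backward(R[5].backward(self.dec1b.backward(dd1)))
        dd2_up, da1 = du1[..., : du1.shape[-1] - c1], du1[..., -c1:]
        dd2 = R[4].backward(U[1].backward(dd2_up))
        du2 = self.dec2a.backward(R[3].backward(self.dec2b.backward(dd2)))
        da3_up, da2 = du2[..., : du2.shape[-1] - c2], du2[..., -c2:]
        da3 = U[0].backward(da3_up)

        da3 = self.adapters[2].backward(da3)
        da2 = da2 + P[1].backward(self.enc3.backward(R[2].backward(da3)))
        da2 = self.adapters[1].backward(da2)
        da1 = da1 + P[0].backward(self.enc2.backward(R[1].backward(da2)))
        da1 = self.adapters[0].backward(da1)
        self.enc1.backward(R[0].backward(da1))  # gradient w.r.t. input discarded

    def forward(
        self, image: MultiplexImage, sigma: float = 2.0
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Single-image inference: (H x W x n_classes+1 probs, H x W x M embedding)."""
        x = image.structure[None, :, :, None]
        t = texture_features(image, sigma)[None]
        probs, emb = self.forward_batch(x, t)
        return probs[0], emb[0]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters; ``loss`` picks plain Dice+BCE or MOCL.

    Corrective learning is a refinement stage: with ``loss='mocl'`` the first
    ``mocl_warmup`` fraction of the epochs trains with unit weights (the
    confidence map and embedding space have to mean something before they can
    rank prototypes), and the corrective weighting switches on for the rest.
    """

    epochs: int = 30
    batch_size: int = 4
    learning_rate: float = 5e-3
    seed: int = 0
    loss: str = "plain"  # "plain" | "mocl"
    mocl: MOCLConfig = field(default_factory=MOCLConfig)
    mocl_warmup: float = 0.5
    mocl_refine_lr_factor: float = 0.2
    adapter_mode: str = "full"  # "full" | "adapter"
    texture_sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValidationError("epochs, batch_size and learning_rate must be positive")
        if self.loss not in ("plain", "mocl"):
            raise ValidationError("loss must be 'plain' or 'mocl'")
        if self.adapter_mode not in ("full", "adapter"):
            raise ValidationError("adapter_mode must be 'full' or 'adapter'")
        if not (0 <= self.mocl_warmup < 1):
            raise ValidationError("mocl_warmup must be in [0, 1)")


def _class_loss_and_grad(
    Y: np.ndarray, P: np.ndarray, weights: np.ndarray, smooth: float
) -> Tuple[float, np.ndarray]:
    """Weighted soft-Dice + weighted BCE and its gradient w.r.t. P."""
    Yf = Y.astype(np.float64)
    w = weights
    num = 2.0 * np.sum(w * Yf * P) + smooth
    den = np.sum(w * Yf) + np.sum(w * P) + smooth
    dice = 1.0 - num / den
    ddice = -2.0 * w * Yf / den + num * w / den**2

    Pc = np.clip(P, _BCE_EPS, 1.0 - _BCE_EPS)
    n = P.size
    bce = float(np.sum(w * (-Yf * np.log(Pc) - (1.0 - Yf) * np.log(1.0 - Pc))) / n)
    inside = (P > _BCE_EPS) & (P < 1.0 - _BCE_EPS)
    dbce = np.where(inside, w * (-Yf / Pc + (1.0 - Yf) / (1.0 - Pc)) / n, 0.0)
    return float(dice + bce), ddice + dbce


def _corrective_weights(
    Y: np.ndarray, P: np.ndarray, E: np.ndarray, cfg: MOCLConfig
) -> np.ndarray:
    """MOCL combined weight map, detached from the computation graph."""
    n_annot = int((Y > 0).sum())
    if n_annot == 0:
        return np.ones_like(P)
    k = cfg.resolve_k(n_annot)
    protos = _mocl.select_topk(E, P, Y, k)
    S = _mocl.similarity_map(E, protos, cfg.aggregation)
    return _mocl.weight_maps(P, S, Y, cfg.background_weight).combined


def train(
    model: AdapterModel,
    dataset: Sequence[Tuple[MultiplexImage, ClassAnnotationSet]],
    cfg: TrainConfig,
    val_dataset: Optional[Sequence[Tuple[MultiplexImage, ClassAnnotationSet]]] = None,
) -> Tuple[AdapterModel, List[Dict]]:
    """Train in place; returns (model, per-epoch history records).

    Each epoch shuffles the dataset (seeded), runs Adam on mini-batches of the
    per-class loss averaged over classes, and (when ``val_dataset`` is given)
    records the validation Dice at threshold 0.5.  ``adapter_mode='adapter'``
    updates only adapters and head; the trunk hash is left untouched.
    A non-finite loss aborts with the offending batch indices.
    """
    if not len(dataset):
        raise ValidationError("empty training dataset")
    xs = np.stack([img.structure[:, :, None] for img, _ in dataset])
    ts = np.stack([texture_features(img, cfg.texture_sigma) for img, _ in dataset])
    anns = [ann for _, ann in dataset]
    classes = sorted({c for ann in anns for c in ann.classes})
    if max(classes, default=0) > model.n_classes:
        raise ValidationError("annotation classes exceed model n_classes")

    trainable = model.all_params if cfg.adapter_mode == "full" else model.adapter_params
    opt = Adam(trainable, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    n = len(dataset)
    history: List[Dict] = []

    warmup_epochs = int(np.ceil(cfg.mocl_warmup * cfg.epochs)) if cfg.loss == "mocl" else 0

    for epoch in range(cfg.epochs):
        corrective = cfg.loss == "mocl" and epoch >= warmup_epochs
        # refinement of a warm model uses smaller steps than initial fitting
        opt.lr = cfg.learning_rate * (cfg.mocl_refine_lr_factor if corrective else 1.0)
        # Corrective weights are recomputed once per epoch from a frozen
        # forward pass: within an epoch the objective stays fixed, so the
        # optimizer is not chasing weights that move with every update.
        weight_cache: Dict[Tuple[int, int], np.ndarray] = {}
        if corrective:
            for start in range(0, n, cfg.batch_size):
                idx = np.arange(start, min(start + cfg.batch_size, n))
                probs, emb = model.forward_batch(xs[idx], ts[idx])
                for bi, di in enumerate(idx):
                    for cls in classes:
                        Y = anns[di].masks.get(cls)
                        if Y is not None:
                            weight_cache[(int(di), cls)] = _corrective_weights(
                                Y, probs[bi, :, :, cls], emb[bi], cfg.mocl
                            )
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            probs, emb = model.forward_batch(xs[idx], ts[idx])
            b = len(idx)
            dprobs = np.zeros_like(probs)
            batch_loss = 0.0
            for bi, di in enumerate(idx):
                ann = anns[di]
                for cls in classes:
                    Y = ann.masks.get(cls)
                    if Y is None:
                        continue
                    P = probs[bi, :, :, cls]
                    if corrective:
                        w = weight_cache[(int(di), cls)]
                    else:
                        w = np.ones_like(P)
                    scale = 1.0 / (len(classes) * b)
                    loss_c, grad_c = _class_loss_and_grad(Y, P, w, cfg.mocl.dice_smooth)
                    batch_loss += loss_c * scale
                    dprobs[bi, :, :, cls] += grad_c * scale
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch images {idx.tolist()}"
                )
            opt.zero_grad()
            model.backward_batch(dprobs)
            opt.step()
            epoch_loss += batch_loss
            n_batches += 1

        record: Dict = {"epoch": epoch, "loss": epoch_loss / max(n_batches, 1)}
        if val_dataset is not None:
            record["val_dice"] = validation_dice(model, val_dataset, cfg.texture_sigma)
        history.append(record)
    return model, history


def predict(
    model: AdapterModel, image: MultiplexImage, sigma: float = 2.0
) -> Dict[int, np.ndarray]:
    """Per-class foreground probability maps for one image."""
    probs, _ = model.forward(image, sigma)
    return {c: probs[:, :, c] for c in range(1, model.n_classes + 1)}


def validation_dice(
    model: AdapterModel,
    dataset: Sequence[Tuple[MultiplexImage, ClassAnnotationSet]],
    sigma: float = 2.0,
    threshold: float = 0.5,
) -> float:
    """Mean Dice at a fixed threshold over images and class channels."""
    from .metrics import dice_coefficient

    scores = []
    for img, ann in dataset:
        probs = predict(model, img, sigma)
        for cls in ann.classes:
            scores.append(dice_coefficient(probs[cls] >= threshold, ann.masks[cls]))
    return float(np.mean(scores)) if scores else float("nan")


def save_checkpoint(model: AdapterModel, path) -> None:
    """Single-file checkpoint: npz with a JSON config entry plus parameters."""
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.all_params)}
    config = json.dumps(
        {"n_classes": model.n_classes, "base_width": model.base_width, "seed": model.seed}
    )
    np.savez(path, config=np.frombuffer(config.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> AdapterModel:
    data = np.load(path)
    config = json.loads(bytes(data["config"]).decode())
    model = AdapterModel(**config)
    for i, p in enumerate(model.all_params):
        p.value[...] = data[f"param_{i}"]
    return model
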