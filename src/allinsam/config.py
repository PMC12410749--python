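"""Run configuration: a YAML-round-trippable description of a full pipeline run.

Unknown keys are rejected so that a typo in a config file fails loudly instead
of silently falling back to a default.  Per-stage seeds are derived from the
master seed with a counter-based splitter, so a stage's randomness is stable
when unrelated parts of the config change.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Dict, Optional

import numpy as np
import yaml

from .types import MOCLConfig, NoiseConfig, ValidationError
from .backbone import TrainConfig

__all__ = ["SynthConfig", "AnnotateConfig", "RunConfig", "stage_seed"]

_STAGE_INDEX = {"simulate": 0, "annotate": 1, "train": 2, "eval": 3}


def stage_seed(master_seed: int, stage: str, offset: int = 0) -> int:
    """Deterministic per-stage child seed (counter-based, < 2**31)."""
    if stage not in _STAGE_INDEX:
        raise ValidationError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(_STAGE_INDEX[stage], offset))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _lay_noise() -> NoiseConfig:
    """Default lay-annotator noise regime: 20% missed nuclei, 20% class swaps,
    1% of background turned into object-shaped false-positive blobs."""
    return NoiseConfig(fp_rate=0.01, fn_rate=0.2, class_swap_rate=0.2)


@dataclass
class SynthConfig:
    """Synthetic-data stage: image geometry and noise of the study conditions."""

    height: int = 128
    width: int = 128
    n_per_class: tuple = (6, 6)
    min_gap: float = 16.0
    noise_sd: float = 0.05
    n_train: int = 20
    n_val: int = 10
    n_test: int = 10
    noise: NoiseConfig = field(default_factory=_lay_noise)


@dataclass
class AnnotateConfig:
    """Annotation stage: where the training labels come from.

    source: 'truth' (clean masks), 'lay' (corrupted masks), or 'boxes'
    (derive boxes, convert with the fallback segmenter, then corrupt if the
    noise config is nonzero is NOT applied here - box noise comes from the
    box mode/jitter).
    """

    source: str = "lay"
    box_mode: str = "tight"
    jitter_px: int = 0

    def __post_init__(self) -> None:
        if self.source not in ("truth", "lay", "boxes"):
            raise ValidationError("annotate source must be truth|lay|boxes")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "run"
    log_level: str = "INFO"
    synth: SynthConfig = field(default_factory=SynthConfig)
    annotate: AnnotateConfig = field(default_factory=AnnotateConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    base_width: int = 8

    # ---- YAML round trip -------------------------------------------------
    def to_dict(self) -> Dict[str, Any]:
        d = asdict(self)
        d["synth"]["n_per_class"] = list(self.synth.n_per_class)
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, data: Dict[str, Any]) -> "RunConfig":
        data = dict(data)

        def build(klass, payload):
            if payload is None:
                return klass()
            names = {f.name for f in dataclasses.fields(klass)}
            unknown = set(payload) - names
            if unknown:
                raise ValidationError(f"unknown {klass.__name__} keys: {sorted(unknown)}")
            return klass(**payload)

        synth_payload = data.pop("synth", None)
        if synth_payload:
            synth_payload = dict(synth_payload)
            if "n_per_class" in synth_payload:
                synth_payload["n_per_class"] = tuple(synth_payload["n_per_class"])
            if isinstance(synth_payload.get("noise"), dict):
                synth_payload["noise"] = build(NoiseConfig, synth_payload["noise"])
        train_payload = data.pop("train", None)
        if train_payload:
            train_payload = dict(train_payload)
            if isinstance(train_payload.get("mocl"), dict):
                train_payload["mocl"] = build(MOCLConfig, train_payload["mocl"])
        annotate_payload = data.pop("annotate", None)

        known = {f.name for f in dataclasses.fields(cls)} - {"synth", "annotate", "train"}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown RunConfig keys: {sorted(unknown)}")
        return cls(
            synth=build(SynthConfig, synth_payload),
            annotate=build(AnnotateConfig, annotate_payload),
            train=build(TrainConfig, train_payload),
            **data,
        )

    @classmethod
    def from_yaml(cls, path_or_text) -> "RunConfig":
        p = Path(str(path_or_text))
        text = p.read_text() if p.exists() else str(path_or_text)
        return cls.from_dict(yaml.safe_load(text) or {})
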