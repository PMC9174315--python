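"""Run configuration: a single JSON document with per-stage sections.

Every artifact a stage writes records the configuration hash, so a run is
reproducible from (config, seed) alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .scoring import DEFAULT_CUTOFF
from .synthetic import SyntheticConfig


@dataclass
class RunConfig:
    output_root: str = "runs/default"
    seed: int = 0
    magnifications: tuple = (5, 10, 20)
    cutoff: float = DEFAULT_CUTOFF
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    train_frac: float = 0.7
    finetune_frac: float = 0.2
    image_format: str = "tiles"        # cohort persistence: tiles | tiff
    segmenter: str = "oracle"          # oracle | trained
    epochs: int = 12
    learning_rate: float = 3e-3
    conv_channels: tuple = (8, 16)
    attention_hidden_dim: int = 8
    kwsi_iterations: int = 100
    biopsy_strip_length: int = 30
    biopsy_iterations: int = 100

    def validate(self, stage: str = "score") -> None:
        mags = tuple(self.magnifications)
        allowed = {5, 10, 20, 40} if stage in ("segment", "ablation") else \
            {5, 10, 20}
        bad = [m for m in mags if m not in allowed]
        if bad:
            if 40 in bad and stage not in ("segment", "ablation"):
                raise ValueError(
                    "magnifications: 40x is excluded from the prediction "
                    "model (poor predictive performance at 40x); it is "
                    "allowed only for segmentation/ablation stages"
                )
            raise ValueError(f"magnifications: unsupported values {bad}")
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must be in (0, 1)")
        if not 0.0 <= self.finetune_frac < 1.0:
            raise ValueError("finetune_frac must be in [0, 1)")
        if not 0.0 <= self.cutoff <= 1.0:
            raise ValueError("cutoff must be in [0, 1]")
        if self.image_format not in ("tiles", "tiff"):
            raise ValueError("image_format must be 'tiles' or 'tiff'")
        if self.epochs < 5:
            raise ValueError("epochs must be >= 5 (five checkpoints)")
        self.synthetic.validate()

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        syn = raw.pop("synthetic", {})
        if "slides_per_patient" in syn:
            syn["slides_per_patient"] = tuple(syn["slides_per_patient"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw, synthetic=SyntheticConfig(**syn))
        cfg.magnifications = tuple(cfg.magnifications)
        cfg.conv_channels = tuple(cfg.conv_channels)
        return cfg

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
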