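"""Run configuration: the training/detection hyper-parameters in one place.

Defaults mirror the published protocol: batch size 35, at most 10,000
iterations, learning rate decayed from 0.01 to 0.0001 by exponential
attenuation at the milestone iterations {1000, 1500, 2000, 2500, 2900},
weight decay 1e-4, momentum 0.9, residual offset ξ = 0.0001.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


def setup_logging(level: int = logging.INFO) -> logging.Logger:
    logger = logging.getLogger("tscnna")
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)
    return logger


@dataclass
class RunConfig:
    classes: tuple[str, ...] = (
        "corn_borer",
        "cabbage_night_moth",
        "moth_larvae",
        "cabbage_pest",
    )
    input_side: int = 32
    batch_size: int = 35
    max_iterations: int = 10_000
    initial_lr: float = 0.01
    final_lr: float = 0.0001
    milestones: tuple[int, ...] = (1000, 1500, 2000, 2500, 2900)
    weight_decay: float = 1e-4
    momentum: float = 0.9
    residual_offset: float = 0.0001
    attention_ratio: int = 8
    detection_scales: tuple[int, ...] = (8, 12, 18, 27)
    detection_stride: float = 0.25
    score_threshold: float = 0.8
    nms_iou: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if min(self.initial_lr, self.final_lr) <= 0:
            raise ValueError("learning rates must be positive")
        if any(b <= a for a, b in zip(self.milestones, self.milestones[1:])):
            raise ValueError("milestones must be strictly increasing")
        if self.residual_offset <= 0:
            raise ValueError("residual offset must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        for key in ("classes", "milestones", "detection_scales"):
            if key in doc and doc[key] is not None:
                doc[key] = tuple(doc[key])
        return cls(**doc)
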