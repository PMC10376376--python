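"""Central pipeline configuration with every stage's tunable in one place.

All defaults match the per-module defaults; a YAML file with any subset of
the keys overrides them.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

from .classify import TrainConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # preprocess
    d0: float | None = None          # None -> 5% of the image diagonal
    strength: float = 1.0
    bright_cutoff: int = 170
    # threshold
    max_iter: int = 64
    # segment
    max_lines: int = 5
    min_gap: int | None = None       # None -> width // 6
    shift_range: int | None = None   # None -> width // 10
    gap_sum_fraction: float = 0.35   # candidate kept iff its projection sum
    #                                  is below this fraction of the median
    # mask
    expansion_divisor: int = 30
    tile_pad: int = 0
    # dataset / classify
    split_ratio: float = 0.7
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.d0 is not None and self.d0 <= 0:
            raise ValueError("d0 must be > 0")
        if self.strength < 0:
            raise ValueError("strength must be >= 0")
        if not (0 < self.bright_cutoff < 255):
            raise ValueError("bright_cutoff must be in (0, 255)")
        if self.max_lines < 1 or self.max_iter < 1:
            raise ValueError("max_lines and max_iter must be >= 1")
        if not (0 < self.split_ratio < 1):
            raise ValueError("split_ratio must be in (0, 1)")
        if self.expansion_divisor < 1:
            raise ValueError("expansion_divisor must be >= 1")
        if not (0 < self.gap_sum_fraction <= 1):
            raise ValueError("gap_sum_fraction must be in (0, 1]")
        self.train.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        train = TrainConfig(**data.pop("train", {}))
        cfg = cls(train=train, **data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(asdict(self)))
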