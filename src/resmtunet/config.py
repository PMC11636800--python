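"""Configuration objects for the network and for training.

The default :class:`ModelConfig` describes the full-size network: a four-stage
hierarchical-transformer branch (channel widths 64/128/320/512, depths
3/4/6/3, sequence-reduction ratios 8/4/2/1, attention heads 1/2/5/8 — the
dimensioning of the SegFormer MiT-B2 family), a ResNet-50 residual branch, a
convolutional fusion module, a U-Net style decoder, and the two task heads.
``width_multiplier`` scales every channel count for desk-scale experiments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

PATCH_EMBED_SPECS = ((7, 4, 3), (3, 2, 1), (3, 2, 1), (3, 2, 1))  # (K, S, P) per stage


def _scale(value: int, mult: float) -> int:
    return max(int(round(value * mult)), 1)


@dataclass
class ModelConfig:
    """Architecture hyperparameters of ResMTUNet."""

    input_size: int = 512
    n_class: int = 4
    stage_channels: tuple[int, int, int, int] = (64, 128, 320, 512)
    stage_depths: tuple[int, int, int, int] = (3, 4, 6, 3)
    reduction_ratios: tuple[int, int, int, int] = (8, 4, 2, 1)
    head_counts: tuple[int, int, int, int] = (1, 2, 5, 8)
    mlp_ratio: int = 4
    residual_variant: str = "resnet50"
    residual_width: int = 64
    fused_channels: int = 2360
    decoder_channels: tuple[int, int, int] = (416, 208, 104)  # levels 3, 2, 1
    seg_head_hidden: int = 40
    width_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.input_size % 32 != 0:
            raise ValueError("input_size must be divisible by 32")
        if self.n_class < 2:
            raise ValueError("n_class must be >= 2")
        for c in (*self.stage_channels, *self.decoder_channels,
                  self.fused_channels, self.residual_width, self.seg_head_hidden):
            if c <= 0:
                raise ValueError("all channel counts must be positive")
        if any(r < 1 for r in self.reduction_ratios):
            raise ValueError("reduction ratios must be >= 1")
        for c, h in zip(self.stage_channels, self.head_counts):
            if _scale(c, self.width_multiplier) % h != 0:
                raise ValueError(
                    f"scaled channel count {_scale(c, self.width_multiplier)} "
                    f"not divisible by head count {h}")

    # effective (width-scaled) dimensions -------------------------------------
    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(_scale(c, self.width_multiplier) for c in self.stage_channels)

    @property
    def res_width(self) -> int:
        return _scale(self.residual_width, self.width_multiplier)

    @property
    def fused(self) -> int:
        return _scale(self.fused_channels, self.width_multiplier)

    @property
    def dec_channels(self) -> tuple[int, ...]:
        return tuple(_scale(c, self.width_multiplier) for c in self.decoder_channels)

    @property
    def seg_hidden(self) -> int:
        return _scale(self.seg_head_hidden, self.width_multiplier)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "ModelConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def tiny_config(input_size: int = 64, seed: int = 0, **overrides) -> ModelConfig:
    """A 1/8-width configuration small enough for CPU tests."""
    kwargs = dict(input_size=input_size, width_multiplier=0.125,
                  stage_depths=(1, 1, 2, 1), seed=seed)
    kwargs.update(overrides)
    return ModelConfig(**kwargs)


@dataclass
class TrainConfig:
    """Optimization settings for joint classification + segmentation training."""

    lr0: float = 1e-3               # initial SGD learning rate
    momentum: float = 0.9
    halving_period: int = 7         # epochs between learning-rate halvings
    epochs: int = 30
    batch_size: int = 16
    lambda_weight: float = 0.5      # weight of the classification loss
    augment_hflip: bool = True
    augment_vflip: bool = True
    augment_blur: bool = True
    augment_brightness: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if self.lambda_weight < 0:
            raise ValueError("lambda_weight must be >= 0")
        if self.halving_period < 1:
            raise ValueError("halving_period must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in names})

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "TrainConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
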