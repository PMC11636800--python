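"""U-Net style decoder and the two task heads."""

from __future__ import annotations

import numpy as np

from .. import nn
from ..config import ModelConfig
from ..nn.tensor import Tensor, concat, interpolate_bilinear, softmax
from .encoder import FeaturePyramid


class DecoderBlock(nn.Module):
    """x_i' = Conv(Concat(x_i, Upsample(x_{i+1}')));  Conv = 3x3 + BN + ReLU."""

    def __init__(self, skip_ch: int, up_ch: int, out_ch: int,
                 rng: np.random.Generator):
        super().__init__()
        self.skip_ch, self.up_ch = skip_ch, up_ch
        self.up = nn.Upsample2x()
        self.conv = nn.Conv2d(skip_ch + up_ch, out_ch, 3, 1, 1, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(out_ch)

    def forward(self, skip: Tensor, below: Tensor) -> Tensor:
        if skip.shape[1] != self.skip_ch or below.shape[1] != self.up_ch:
            raise ValueError("decoder received features with unexpected channels")
        up = self.up(below)
        if up.shape[2:] != skip.shape[2:]:
            raise ValueError(
                f"decoder skip {skip.shape} does not match upsampled {up.shape}")
        return self.bn(self.conv(concat([skip, up], axis=1))).relu()


class UNetDecoder(nn.Module):
    """Aggregates the pyramid top-down; returns the stride-4 feature map."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        chans = cfg.channels
        dec = cfg.dec_channels            # (level3, level2, level1)
        ups = (cfg.fused,) + dec[:2]
        self.blocks = nn.ModuleList([
            DecoderBlock(chans[2 - i], ups[i], dec[i], rng) for i in range(3)])
        self.out_channels = dec[2]

    def forward(self, pyramid: FeaturePyramid) -> Tensor:
        if pyramid.fused_top is None:
            raise ValueError("decoder requires the fused stride-32 feature")
        x = pyramid.fused_top
        for i, block in enumerate(self.blocks):
            x = block(pyramid.levels[2 - i], x)
        return x


class ClassificationHead(nn.Module):
    """Global average pooling over the fused top feature, then a linear map."""

    def __init__(self, in_ch: int, n_class: int, rng: np.random.Generator):
        super().__init__()
        self.fc = nn.Linear(in_ch, n_class, rng=rng)

    def logits(self, fused_top: Tensor) -> Tensor:
        pooled = fused_top.mean(axis=(2, 3))
        return self.fc(pooled)

    def forward(self, fused_top: Tensor) -> Tensor:
        return softmax(self.logits(fused_top), axis=-1)


class SegmentationHead(nn.Module):
    """Two convolutions on the stride-4 map, then bilinear x4 upsampling.

    The first convolution halves the channel count (C0 -> C0/2 for the
    default configuration), the second maps to n_class + 1 channels
    (lesion classes plus background); logits are returned at full
    resolution.
    """

    def __init__(self, in_ch: int, hidden: int, n_class: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, hidden, 3, 1, 1, rng=rng)
        self.conv2 = nn.Conv2d(hidden, n_class + 1, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv2(self.conv1(x).relu())
        return interpolate_bilinear(y, (4 * x.shape[2], 4 * x.shape[3]))
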