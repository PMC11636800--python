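"""The hybrid encoder: hierarchical transformer branch, residual CNN branch,
and the convolutional fusion module that joins their stride-32 outputs."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import nn
from ..config import PATCH_EMBED_SPECS, ModelConfig
from ..nn.tensor import Tensor, concat
from .attention import TransformerSubmodule


def patch_embed_output_size(size: int, k: int, s: int, p: int) -> int:
    out = (size + 2 * p - k) // s + 1
    if out <= 0:
        raise ValueError(f"patch embedding of size-{size} input with K={k}, "
                         f"S={s}, P={p} yields non-positive output")
    return out


class PatchEmbed(nn.Module):
    """Overlapping patch embedding: a strided convolution over the image/grid.

    Output spatial size is floor((H + 2P - K)/S) + 1 per axis.
    """

    def __init__(self, in_ch: int, out_ch: int, k: int, s: int, p: int,
                 rng: np.random.Generator):
        super().__init__()
        self.k, self.s, self.p = k, s, p
        self.proj = nn.Conv2d(in_ch, out_ch, k, s, p, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        patch_embed_output_size(x.shape[2], self.k, self.s, self.p)
        patch_embed_output_size(x.shape[3], self.k, self.s, self.p)
        return self.proj(x)


@dataclass
class FeaturePyramid:
    """Encoder outputs: four maps at strides 4/8/16/32 plus the fused top."""

    levels: list[Tensor]            # NCHW, strides 4, 8, 16, 32
    fused_top: Tensor | None = None

    def __post_init__(self):
        if len(self.levels) != 4:
            raise ValueError("a feature pyramid has exactly four levels")
        for lo, hi in zip(self.levels, self.levels[1:]):
            if lo.shape[2] != 2 * hi.shape[2] or lo.shape[3] != 2 * hi.shape[3]:
                raise ValueError("pyramid spatial sizes must halve level to level")
        if self.fused_top is not None and \
                self.fused_top.shape[2:] != self.levels[3].shape[2:]:
            raise ValueError("fused_top must match the stride-32 level spatially")


class TransformerStage(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, depth: int, heads: int,
                 reduction: int, mlp_ratio: int, kps: tuple[int, int, int],
                 rng: np.random.Generator):
        super().__init__()
        k, s, p = kps
        self.embed = PatchEmbed(in_ch, out_ch, k, s, p, rng)
        self.embed_norm = nn.LayerNorm(out_ch)
        self.blocks = nn.ModuleList([
            TransformerSubmodule(out_ch, heads, reduction, mlp_ratio, rng)
            for _ in range(depth)])
        self.norm = nn.LayerNorm(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        x = self.embed(x)
        B, C, H, W = x.shape
        t = x.reshape(B, C, H * W).transpose(0, 2, 1)
        t = self.embed_norm(t)
        for blk in self.blocks:
            t = blk(t, (H, W))
        t = self.norm(t)
        return t.transpose(0, 2, 1).reshape(B, C, H, W)


class TransformerBranch(nn.Module):
    """Four stages producing features at strides 4, 8, 16 and 32."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        chans = cfg.channels
        ins = (3,) + chans[:3]
        self.stages = nn.ModuleList([
            TransformerStage(ins[i], chans[i], cfg.stage_depths[i],
                             cfg.head_counts[i], cfg.reduction_ratios[i],
                             cfg.mlp_ratio, PATCH_EMBED_SPECS[i], rng)
            for i in range(4)])

    def forward(self, x: Tensor) -> list[Tensor]:
        levels = []
        for stage in self.stages:
            x = stage(x)
            levels.append(x)
        return levels


class Bottleneck(nn.Module):
    """ResNet bottleneck: 1x1 reduce, 3x3, 1x1 expand (x4), identity shortcut."""

    expansion = 4

    def __init__(self, in_ch: int, width: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        out_ch = width * self.expansion
        self.conv1 = nn.Conv2d(in_ch, width, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(width)
        self.conv2 = nn.Conv2d(width, width, 3, stride, 1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(width)
        self.conv3 = nn.Conv2d(width, out_ch, 1, bias=False, rng=rng)
        self.bn3 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.shortcut = nn.Sequential(
                nn.Conv2d(in_ch, out_ch, 1, stride, bias=False, rng=rng),
                nn.BatchNorm2d(out_ch))
        else:
            self.shortcut = nn.Identity()

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y)).relu()
        y = self.bn3(self.conv3(y))
        return (y + self.shortcut(x)).relu()


RESNET_LAYERS = {"resnet50": (3, 4, 6, 3)}


class ResidualBranch(nn.Module):
    """ResNet-style CNN branch; overall stride 32 to align with the
    transformer branch's deepest level."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        if cfg.residual_variant not in RESNET_LAYERS:
            raise ValueError(f"unknown residual_variant {cfg.residual_variant!r}")
        blocks = RESNET_LAYERS[cfg.residual_variant]
        w = cfg.res_width
        self.stem = nn.Sequential(
            nn.Conv2d(3, w, 7, 2, 3, bias=False, rng=rng),
            nn.BatchNorm2d(w), nn.ReLU())
        self.pool = nn.MaxPool2d(3, 2, 1)
        stages = []
        in_ch = w
        for i, n in enumerate(blocks):
            width = w * 2 ** i
            stride = 1 if i == 0 else 2
            layer = [Bottleneck(in_ch, width, stride, rng)]
            in_ch = width * Bottleneck.expansion
            for _ in range(n - 1):
                layer.append(Bottleneck(in_ch, width, 1, rng))
            stages.append(nn.Sequential(*layer))
        self.stages = nn.ModuleList(stages)
        self.out_channels = in_ch

    def forward(self, x: Tensor) -> Tensor:
        x = self.pool(self.stem(x))
        for stage in self.stages:
            x = stage(x)
        return x


class FusionModule(nn.Module):
    """Concatenate the two stride-32 features and fuse with a 3x3 convolution."""

    def __init__(self, t_ch: int, r_ch: int, out_ch: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(t_ch + r_ch, out_ch, 3, 1, 1, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(out_ch)

    def forward(self, t4: Tensor, r4: Tensor) -> Tensor:
        if t4.shape[2:] != r4.shape[2:]:
            raise ValueError(
                f"fusion inputs disagree spatially: {t4.shape} vs {r4.shape}")
        return self.bn(self.conv(concat([t4, r4], axis=1))).relu()
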