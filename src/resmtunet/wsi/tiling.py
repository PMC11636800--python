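"""Tile planning, three-scale context extraction, and multi-scale fusion.

The foreground is divided into non-overlapping 512x512 tiles on a grid
anchored at (0, 0) at 20x magnification.  For every tile two additional
center crops of 768x768 and 1024x1024 share the tile's center; both are
resized to 512x512 for the network.  The three outputs are mapped back to
the tile frame (resize to the window's native size, center-crop to 512) and
averaged, giving the tile's fused probability map.

All probability/image resizes use bilinear interpolation with the
align_corners=False pixel-center convention and no antialiasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..nn import Tensor, interpolate_bilinear, no_grad
from .foreground import ForegroundMask
from .slide import SlidePyramid

TILE_SIZE = 512
CONTEXT_SIZES = (512, 768, 1024)


@dataclass(frozen=True)
class PatchPlan:
    """A tile's level-0 position and its concentric context windows."""

    origin: tuple[int, int]                       # (x, y), 0-based level-0 px
    tile_size: int = TILE_SIZE
    context_sizes: tuple[int, ...] = CONTEXT_SIZES
    padding_mode: str = "reflect"

    @property
    def center(self) -> tuple[float, float]:
        x, y = self.origin
        return (x + self.tile_size / 2, y + self.tile_size / 2)

    def window_origin(self, size: int) -> tuple[int, int]:
        x, y = self.origin
        off = (size - self.tile_size) // 2
        return (x - off, y - off)


def resize_bilinear(arr: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of an (H, W, C) array (channels preserved)."""
    with no_grad():
        t = Tensor(np.moveaxis(np.asarray(arr, dtype=np.float64), -1, 0)[None])
        out = interpolate_bilinear(t, out_hw)
    return np.moveaxis(out.data[0], 0, -1)


def plan_tiles(fg: ForegroundMask, slide: SlidePyramid,
               tile_size: int = TILE_SIZE,
               min_coverage: float = 0.05) -> list[PatchPlan]:
    """Grid-aligned non-overlapping tiles whose foreground coverage exceeds
    ``min_coverage``."""
    h, w = slide.dimensions
    plans = []
    for y in range(0, h - tile_size + 1, tile_size):
        for x in range(0, w - tile_size + 1, tile_size):
            if fg.coverage(x, y, tile_size) > min_coverage:
                plans.append(PatchPlan(origin=(x, y), tile_size=tile_size))
    return plans


def extract_context(slide: SlidePyramid, plan: PatchPlan) -> list[np.ndarray]:
    """Three 512x512 float images in [0, 1]: the tile itself and the two
    context windows resized down to the tile size."""
    out = []
    for size in plan.context_sizes:
        x, y = plan.window_origin(size)
        img = slide.read_region(x, y, size, plan.padding_mode).astype(np.float64) / 255.0
        if size != plan.tile_size:
            img = resize_bilinear(img, (plan.tile_size, plan.tile_size))
        out.append(img)
    return out


def fuse_multiscale(outputs: list[np.ndarray], plan: PatchPlan) -> np.ndarray:
    """Average the three window outputs in the tile frame.

    ``outputs[k]`` is the (512, 512, L) probability map predicted on context
    window k; maps from the larger windows are resized back to their native
    window size, center-cropped to the tile, and the three are averaged and
    renormalized to the simplex.
    """
    if len(outputs) != len(plan.context_sizes):
        raise ValueError("one output per context window required")
    t = plan.tile_size
    acc = np.zeros_like(np.asarray(outputs[0], dtype=np.float64))
    for prob, size in zip(outputs, plan.context_sizes):
        prob = np.asarray(prob, dtype=np.float64)
        if prob.shape[:2] != (t, t):
            raise ValueError(f"window output must be {t}x{t}")
        if size != t:
            full = resize_bilinear(prob, (size, size))
            off = (size - t) // 2
            prob = full[off:off + t, off:off + t]
        acc += prob
    acc /= len(outputs)
    acc = np.clip(acc, 0.0, None)
    total = acc.sum(axis=-1, keepdims=True)
    total[total == 0] = 1.0
    return acc / total
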