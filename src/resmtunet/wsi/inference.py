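"""Slide-level inference: tiling, three-scale prediction, fusion, stitching.

Tiles are processed one at a time (the full patch set is never materialized),
fused per tile, and written into a slide-level probability canvas.  Pixels
outside the planned foreground tiles are assigned the background class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from ..model import ResMTUNet
from .foreground import ForegroundMask, otsu_foreground
from .slide import SlidePyramid
from .tiling import (CONTEXT_SIZES, TILE_SIZE, PatchPlan, extract_context,
                     fuse_multiscale, plan_tiles, resize_bilinear)

# A tile predictor maps a (512, 512, 3) image in [0, 1] plus its plan and
# context-window size to a (512, 512, L) probability map.
TilePredictor = Callable[[np.ndarray, PatchPlan, int], np.ndarray]


def network_predictor(model: ResMTUNet) -> TilePredictor:
    """Wrap a trained network as a tile predictor (ignores the plan)."""

    def predict(image: np.ndarray, plan: PatchPlan, size: int) -> np.ndarray:
        batch = (image.transpose(2, 0, 1)[None] * 2.0 - 1.0)
        probs = model.predict_proba(batch)[0]
        return probs.transpose(1, 2, 0)

    return predict


@dataclass
class SlideResult:
    prob_map: np.ndarray          # (H/stride, W/stride, L) simplex per pixel
    labels: np.ndarray            # (H/stride, W/stride) argmax labels
    plans: list[PatchPlan]
    foreground: ForegroundMask
    stride: int = 1


def infer_slide(slide: SlidePyramid, predictor: TilePredictor | ResMTUNet,
                n_labels: int, tile_size: int = TILE_SIZE,
                context_sizes: Sequence[int] = CONTEXT_SIZES,
                min_coverage: float = 0.05, stride: int = 1,
                plans: list[PatchPlan] | None = None) -> SlideResult:
    """Run the multi-scale pipeline over a whole slide.

    ``context_sizes=(512,)`` gives single-scale inference.  ``stride``
    controls the output resolution (level-0 pixels per output pixel).
    """
    if isinstance(predictor, ResMTUNet):
        predictor = network_predictor(predictor)
    h, w = slide.dimensions
    if h % stride or w % stride:
        raise ValueError("slide dimensions must be divisible by the stride")
    fg = otsu_foreground(slide)
    if plans is None:
        plans = plan_tiles(fg, slide, tile_size, min_coverage)
        plans = [PatchPlan(p.origin, p.tile_size, tuple(context_sizes),
                           p.padding_mode) for p in plans]
    canvas = np.zeros((h // stride, w // stride, n_labels))
    canvas[..., 0] = 1.0                       # background prior off-tissue
    for plan in plans:
        images = extract_context(slide, plan)
        outputs = [predictor(img, plan, size)
                   for img, size in zip(images, plan.context_sizes)]
        fused = fuse_multiscale(outputs, plan)
        if stride > 1:
            fused = resize_bilinear(fused, (plan.tile_size // stride,
                                            plan.tile_size // stride))
            s = fused.sum(axis=-1, keepdims=True)
            fused = fused / np.where(s == 0, 1.0, s)
        x, y = plan.origin
        canvas[y // stride:(y + plan.tile_size) // stride,
               x // stride:(x + plan.tile_size) // stride] = fused
    labels = canvas.argmax(axis=-1)
    return SlideResult(prob_map=canvas, labels=labels, plans=plans,
                       foreground=fg, stride=stride)
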