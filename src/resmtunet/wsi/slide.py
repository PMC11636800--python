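"""Pyramidal slide container with multi-page TIFF I/O.

A :class:`SlidePyramid` holds a list of RGB arrays, level 0 largest, with
monotonically increasing downsample factors and a nominal base magnification
(20x for the tiling convention used here).  Slides are stored as multi-page
TIFF files whose ImageDescription carries the magnification metadata as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class SlidePyramid:
    levels: list[np.ndarray]                 # RGB uint8, level 0 largest
    base_magnification: float = 20.0

    def __post_init__(self):
        if not self.levels:
            raise ValueError("a slide needs at least one level")
        areas = [lv.shape[0] * lv.shape[1] for lv in self.levels]
        if any(a <= b for a, b in zip(areas, areas[1:])):
            raise ValueError("levels must shrink monotonically")

    @property
    def dimensions(self) -> tuple[int, int]:
        """(height, width) of level 0."""
        return self.levels[0].shape[:2]

    @property
    def downsamples(self) -> list[float]:
        h0 = self.levels[0].shape[0]
        return [h0 / lv.shape[0] for lv in self.levels]

    def thumbnail(self) -> tuple[np.ndarray, float]:
        """Deepest stored level and its downsample factor relative to level 0."""
        return self.levels[-1], self.downsamples[-1]

    def read_region(self, x: int, y: int, size: int,
                    padding_mode: str = "reflect") -> np.ndarray:
        """``size`` x ``size`` RGB crop at level-0 coordinates (x, y) = top
        left, 0-based; windows reaching past the slide edge are padded."""
        h, w = self.dimensions
        x0, y0 = max(x, 0), max(y, 0)
        x1, y1 = min(x + size, w), min(y + size, h)
        if x0 >= x1 or y0 >= y1:
            raise ValueError(f"window ({x},{y})+{size} outside slide {w}x{h}")
        crop = self.levels[0][y0:y1, x0:x1]
        pads = ((y0 - y, y + size - y1), (x0 - x, x + size - x1), (0, 0))
        if any(p for pair in pads for p in pair):
            crop = np.pad(crop, pads, mode=padding_mode)
        return crop

    # ---- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        meta = {"base_magnification": self.base_magnification,
                "levels": len(self.levels)}
        with tifffile.TiffWriter(str(path)) as tif:
            for i, lv in enumerate(self.levels):
                tif.write(lv, description=json.dumps(meta) if i == 0 else None,
                          photometric="rgb")

    @classmethod
    def load(cls, path: str | Path,
             magnification: float | None = None) -> "SlidePyramid":
        with tifffile.TiffFile(str(path)) as tif:
            levels = [p.asarray() for p in tif.pages]
            mag = magnification
            if mag is None:
                desc = tif.pages[0].description
                try:
                    mag = float(json.loads(desc)["base_magnification"])
                except (TypeError, ValueError, KeyError, json.JSONDecodeError):
                    raise ValueError(
                        "slide has no magnification metadata; pass magnification=")
        levels.sort(key=lambda lv: -lv.shape[0])
        return cls(levels=levels, base_magnification=mag)
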