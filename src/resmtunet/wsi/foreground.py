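"""Tissue foreground detection on a slide thumbnail via Otsu thresholding.

The Otsu threshold maximizes between-class variance of the grayscale
histogram; stained tissue is darker than the near-white glass background, so
pixels *below* the threshold are foreground.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu

from .slide import SlidePyramid


@dataclass
class ForegroundMask:
    mask: np.ndarray          # bool, at thumbnail resolution
    threshold: float          # grayscale threshold in [0, 1]
    downsample: float         # thumbnail-to-level-0 factor

    def coverage(self, x: int, y: int, size: int) -> float:
        """Fraction of foreground inside a level-0 window [x, x+size)."""
        f = self.downsample
        ys, ye = int(np.floor(y / f)), int(np.ceil((y + size) / f))
        xs, xe = int(np.floor(x / f)), int(np.ceil((x + size) / f))
        win = self.mask[ys:ye, xs:xe]
        return float(win.mean()) if win.size else 0.0

    def level0(self, shape: tuple[int, int]) -> np.ndarray:
        """Nearest-neighbour upsampling of the mask to level-0 shape."""
        h, w = shape
        ys = np.minimum((np.arange(h) / self.downsample).astype(int),
                        self.mask.shape[0] - 1)
        xs = np.minimum((np.arange(w) / self.downsample).astype(int),
                        self.mask.shape[1] - 1)
        return self.mask[np.ix_(ys, xs)]


def otsu_foreground(slide: SlidePyramid) -> ForegroundMask:
    """Separate tissue from background on the slide thumbnail."""
    thumb, factor = slide.thumbnail()
    gray = rgb2gray(thumb)
    if np.ptp(gray) < 1e-9:
        warnings.warn("constant thumbnail: Otsu threshold undefined; "
                      "returning empty foreground")
        return ForegroundMask(np.zeros(gray.shape, dtype=bool), float("nan"),
                              factor)
    thr = float(threshold_otsu(gray))
    return ForegroundMask(gray < thr, thr, factor)
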