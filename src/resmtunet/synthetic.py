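"""Synthetic H&E-like fixtures: ROI datasets and pyramidal pseudo-slides.

The generator emulates the structure of a breast-lesion ROI dataset: tissue
(pink stroma) on a near-white glass background, with blob-shaped epithelial
regions each belonging to one of four lesion classes (normal epithelium,
benign/pre-cancerous, DCIS, invasive carcinoma).  Classes differ in mean
color and nuclei-dot density so that small networks can genuinely learn
them.  Region shapes come from thresholded smoothed noise, giving irregular
tissue-like contours.  Every sample carries an exact ground-truth mask
(label 0 = background/stroma, 1..4 = lesion classes) and a consistent
image-level class label.

All randomness flows through a single seeded generator, so outputs are
bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_opening, distance_transform_edt, gaussian_filter

from .training.data import TrainingSample
from .wsi.slide import SlidePyramid
from .wsi.tiling import PatchPlan, resize_bilinear

BACKGROUND_COLOR = (244, 242, 246)
STROMA_COLOR = (231, 176, 203)
CLASS_COLORS = (                    # lesion classes 1..4, H&E-like purples
    (202, 140, 188),                # normal epithelium
    (168, 112, 178),                # benign / pre-cancerous lesion
    (132, 84, 162),                 # ductal carcinoma in situ
    (94, 56, 132),                  # invasive carcinoma
)
NUCLEI_DENSITY = (0.004, 0.008, 0.014, 0.022)     # dots per pixel, class 1..4


@dataclass
class SynthSpec:
    """Parameters of the synthetic H&E generator."""

    seed: int = 0
    canvas: int = 96                      # ROI side length, pixels
    n_regions: int = 2                    # lesion blobs per class on a slide
    lesion_fraction: tuple[float, float] = (0.08, 0.45)  # of ROI area
    noise_amplitude: float = 6.0          # additive RGB noise, 8-bit units
    blob_sigma: float = 6.0               # smoothing of the blob noise field
    pyramid_levels: int = 3
    slide_size: int = 2048
    tissue_fraction: float = 0.55         # of slide area
    n_class: int = 4

    def __post_init__(self):
        colors = [BACKGROUND_COLOR, STROMA_COLOR, *CLASS_COLORS]
        for a in range(len(colors)):
            for b in range(a + 1, len(colors)):
                d = np.linalg.norm(np.subtract(colors[a], colors[b]))
                if d < 20:
                    raise ValueError("class palette colors are too close")


@dataclass
class SyntheticSlide:
    pyramid: SlidePyramid
    mask: np.ndarray                      # level-0 labels in {0..n_class}
    tissue: np.ndarray                    # bool, planted tissue (stroma+lesion)
    region_table: pd.DataFrame            # class, bbox, area per region

    @property
    def magnification(self) -> float:
        return self.pyramid.base_magnification


# ---------------------------------------------------------------------------
# drawing helpers
# ---------------------------------------------------------------------------

def _blob(rng: np.random.Generator, shape: tuple[int, int], sigma: float,
          fraction: float, opening: int = 2) -> np.ndarray:
    """Irregular blob mask covering about ``fraction`` of ``shape``."""
    noise = gaussian_filter(rng.standard_normal(shape), sigma)
    thr = np.quantile(noise, 1.0 - fraction)
    mask = noise > thr
    if opening:
        mask = binary_opening(mask, np.ones((opening, opening)))
    return mask


def _largest_component(mask: np.ndarray) -> np.ndarray:
    from scipy.ndimage import label
    lab, n = label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == sizes.argmax()


def _paint(canvas: np.ndarray, mask: np.ndarray, color) -> None:
    canvas[mask] = np.asarray(color, dtype=np.float64)


def _sprinkle_nuclei(canvas: np.ndarray, mask: np.ndarray, density: float,
                     rng: np.random.Generator) -> None:
    """Darker dots inside ``mask`` mimicking nuclei."""
    ys, xs = np.nonzero(mask)
    n = int(len(ys) * density)
    if n == 0:
        return
    pick = rng.choice(len(ys), size=n, replace=False)
    h, w = mask.shape
    for y, x in zip(ys[pick], xs[pick]):
        y0, y1 = max(y - 1, 0), min(y + 2, h)
        x0, x1 = max(x - 1, 0), min(x + 2, w)
        canvas[y0:y1, x0:x1] *= 0.62


def _render(mask: np.ndarray, tissue: np.ndarray, rng: np.random.Generator,
            spec: SynthSpec) -> np.ndarray:
    """RGB image in [0, 1] from a label mask and a tissue mask."""
    h, w = mask.shape
    img = np.empty((h, w, 3))
    img[...] = BACKGROUND_COLOR
    _paint(img, tissue, STROMA_COLOR)
    for c in range(1, spec.n_class + 1):
        region = mask == c
        _paint(img, region, CLASS_COLORS[c - 1])
        _sprinkle_nuclei(img, region, NUCLEI_DENSITY[c - 1], rng)
    img += rng.normal(0.0, spec.noise_amplitude, img.shape)
    return np.clip(img / 255.0, 0.0, 1.0)


# ---------------------------------------------------------------------------
# ROI dataset
# ---------------------------------------------------------------------------

def make_roi(spec: SynthSpec, lesion_class: int,
             rng: np.random.Generator) -> TrainingSample:
    """One ROI with blobs of exactly one lesion class over stroma."""
    c = spec.canvas
    sigma = spec.blob_sigma * c / 64.0
    tissue = _blob(rng, (c, c), sigma, 0.75)
    lo, hi = spec.lesion_fraction
    # quantile within the tissue keeps the realized fraction on target even
    # after morphological opening trims the blob edges
    for _ in range(20):                    # deterministic retry budget
        target = rng.uniform(lo * 1.15, hi * 0.9)
        noise = gaussian_filter(rng.standard_normal((c, c)), sigma)
        thr = np.quantile(noise[tissue], 1.0 - target / tissue.mean())
        lesion = binary_opening((noise > thr) & tissue, np.ones((2, 2)))
        if lo <= lesion.mean() <= hi:
            break
    mask = np.zeros((c, c), dtype=np.int64)
    mask[lesion] = lesion_class
    img = _render(mask, tissue, rng, spec)
    return TrainingSample(image=img, mask=mask, class_label=lesion_class - 1)


def make_roi_dataset(spec: SynthSpec, n: int) -> list[TrainingSample]:
    """``n`` ROIs cycling through the lesion classes; deterministic in seed."""
    rng = np.random.default_rng(spec.seed)
    return [make_roi(spec, i % spec.n_class + 1, rng) for i in range(n)]


# ---------------------------------------------------------------------------
# pseudo whole-slide images
# ---------------------------------------------------------------------------

def _downsample2x(img: np.ndarray) -> np.ndarray:
    h, w = img.shape[0] // 2 * 2, img.shape[1] // 2 * 2
    x = img[:h, :w].astype(np.float64)
    return ((x[0::2, 0::2] + x[1::2, 0::2] + x[0::2, 1::2] + x[1::2, 1::2])
            / 4.0)


def make_slide(spec: SynthSpec) -> SyntheticSlide:
    """A pyramidal pseudo-WSI with planted lesion regions and exact mask."""
    rng = np.random.default_rng(spec.seed)
    s = spec.slide_size
    sigma = spec.blob_sigma * s / 256.0
    tissue = _blob(rng, (s, s), sigma, spec.tissue_fraction, opening=4)
    # keep lesions away from the tissue border so contexts stay meaningful
    interior = distance_transform_edt(tissue) > s / 64.0
    mask = np.zeros((s, s), dtype=np.int64)
    rows = []
    for c in range(1, spec.n_class + 1):
        planted = 0
        for _ in range(spec.n_regions * 6):
            if planted >= spec.n_regions:
                break
            blob = _blob(rng, (s, s), sigma * 0.8, rng.uniform(0.01, 0.03),
                         opening=4)
            blob &= interior & (mask == 0)
            blob = _largest_component(blob)
            if blob.sum() < (s / 40.0) ** 2:
                continue
            mask[blob] = c
            ys, xs = np.nonzero(blob)
            rows.append({"region": len(rows), "lesion_class": c,
                         "y0": int(ys.min()), "y1": int(ys.max()) + 1,
                         "x0": int(xs.min()), "x1": int(xs.max()) + 1,
                         "area": int(blob.sum())})
            planted += 1
    img = _render(mask, tissue, rng, spec)
    level0 = (img * 255.0).round().astype(np.uint8)
    levels = [level0]
    for _ in range(spec.pyramid_levels - 1):
        levels.append(levels[-1].astype(np.float64))
        levels[-1] = _downsample2x(levels[-2]).round().astype(np.uint8)
    pyramid = SlidePyramid(levels=levels, base_magnification=20.0)
    return SyntheticSlide(pyramid=pyramid, mask=mask, tissue=tissue,
                          region_table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# oracle predictor
# ---------------------------------------------------------------------------

class OracleModel:
    """Tile predictor that reads probabilities off the planted ground truth.

    ``temperature=1`` emits one-hot probabilities; smaller values spread
    ``1 - temperature`` uniformly over the remaining classes.  Used to test
    the slide pipeline and the CRF independently of any trained network.
    """

    def __init__(self, slide: SyntheticSlide, temperature: float = 1.0,
                 noise: float = 0.0, seed: int = 0):
        self.slide = slide
        self.n_labels = int(slide.mask.max()) + 1 if slide.mask.max() >= 4 \
            else 5
        self.temperature = float(temperature)
        self.noise = float(noise)
        self._rng = np.random.default_rng(seed)

    def _window_mask(self, plan: PatchPlan, size: int) -> np.ndarray:
        x, y = plan.window_origin(size)
        h, w = self.slide.mask.shape
        x0, y0 = max(x, 0), max(y, 0)
        x1, y1 = min(x + size, w), min(y + size, h)
        crop = self.slide.mask[y0:y1, x0:x1]
        pads = ((y0 - y, y + size - y1), (x0 - x, x + size - x1))
        if any(p for pair in pads for p in pair):
            crop = np.pad(crop, pads, mode="reflect")
        return crop

    def __call__(self, image: np.ndarray, plan: PatchPlan,
                 size: int) -> np.ndarray:
        L = self.n_labels
        gt = self._window_mask(plan, size)
        onehot = np.eye(L)[gt]
        if size != plan.tile_size:
            onehot = resize_bilinear(onehot, (plan.tile_size, plan.tile_size))
            total = onehot.sum(axis=-1, keepdims=True)
            onehot = onehot / np.where(total == 0, 1.0, total)
        probs = onehot
        if self.temperature < 1.0:
            probs = self.temperature * probs + (1 - self.temperature) / L
        if self.noise > 0:
            probs = probs + self._rng.uniform(0, self.noise, probs.shape)
            probs /= probs.sum(axis=-1, keepdims=True)
        return probs
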