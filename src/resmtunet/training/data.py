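"""Training samples and dataset manifest I/O.

A dataset is a CSV manifest with columns ``image_path``, ``mask_path`` and
``class_label``; images are RGB PNG/TIFF, masks single-channel PNG with
palette indices 0..n_class (0 = background/stroma, 1..n_class = lesion
classes).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image


@dataclass
class TrainingSample:
    image: np.ndarray        # (H, W, 3) float64 in [0, 1]
    mask: np.ndarray         # (H, W) integer labels in {0..n_class}
    class_label: int         # image-level lesion class in {0..n_class-1}

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask must be spatially congruent")


def to_batch(samples: list[TrainingSample]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack samples into (images NCHW normalized to [-1, 1], masks, labels)."""
    imgs = np.stack([s.image for s in samples]).transpose(0, 3, 1, 2)
    imgs = imgs * 2.0 - 1.0
    masks = np.stack([s.mask for s in samples])
    labels = np.array([s.class_label for s in samples], dtype=int)
    return imgs, masks, labels


def save_dataset(samples: list[TrainingSample], out_dir: str | Path) -> Path:
    """Write images/masks plus a CSV manifest; returns the manifest path."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        ipath = out / "images" / f"roi_{i:04d}.png"
        mpath = out / "masks" / f"roi_{i:04d}.png"
        Image.fromarray((s.image * 255).round().astype(np.uint8)).save(ipath)
        Image.fromarray(s.mask.astype(np.uint8), mode="L").save(mpath)
        rows.append({"image_path": str(ipath), "mask_path": str(mpath),
                     "class_label": s.class_label})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(manifest: str | Path) -> list[TrainingSample]:
    df = pd.read_csv(manifest)
    samples = []
    for _, row in df.iterrows():
        img = np.asarray(Image.open(row["image_path"]).convert("RGB"),
                         dtype=np.float64) / 255.0
        mask = np.asarray(Image.open(row["mask_path"]), dtype=np.int64)
        samples.append(TrainingSample(img, mask, int(row["class_label"])))
    return samples
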