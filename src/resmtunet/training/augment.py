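"""Training-time augmentation: flips (image+mask), blur and brightness (image).

Geometric transforms are applied identically to image and mask so the pair
stays congruent; photometric transforms touch only the image.  Each transform
fires with probability 0.5; blur sigma is drawn from [0.1, 2.0] and
brightness scaling from +/-20%.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from ..config import TrainConfig
from .data import TrainingSample

BLUR_SIGMA_RANGE = (0.1, 2.0)
BRIGHTNESS_JITTER = 0.2
APPLY_PROB = 0.5


def hflip(sample: TrainingSample) -> TrainingSample:
    return TrainingSample(sample.image[:, ::-1].copy(),
                          sample.mask[:, ::-1].copy(), sample.class_label)


def vflip(sample: TrainingSample) -> TrainingSample:
    return TrainingSample(sample.image[::-1].copy(),
                          sample.mask[::-1].copy(), sample.class_label)


def augment(sample: TrainingSample, rng: np.random.Generator,
            cfg: TrainConfig | None = None) -> TrainingSample:
    cfg = cfg or TrainConfig()
    img, mask = sample.image, sample.mask
    if cfg.augment_hflip and rng.random() < APPLY_PROB:
        img, mask = img[:, ::-1], mask[:, ::-1]
    if cfg.augment_vflip and rng.random() < APPLY_PROB:
        img, mask = img[::-1], mask[::-1]
    img = np.ascontiguousarray(img)
    if cfg.augment_blur and rng.random() < APPLY_PROB:
        sigma = rng.uniform(*BLUR_SIGMA_RANGE)
        img = gaussian_filter(img, sigma=(sigma, sigma, 0))
    if cfg.augment_brightness and rng.random() < APPLY_PROB:
        img = np.clip(img * rng.uniform(1 - BRIGHTNESS_JITTER,
                                        1 + BRIGHTNESS_JITTER), 0.0, 1.0)
    return TrainingSample(img, np.ascontiguousarray(mask), sample.class_label)
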