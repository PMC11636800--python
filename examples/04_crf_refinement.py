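"""Dense-CRF refinement of a noisy probability map.

Takes a softened, noise-corrupted oracle probability map on a synthetic ROI
and applies fully connected CRF mean-field inference.  The bilateral kernel
pulls labels toward color-coherent regions, the smoothness kernel removes
isolated pixels; the refined mask should contain strictly fewer wrongly
labeled pixels.
"""

import numpy as np

from resmtunet import CRFParams, SynthSpec, make_roi_dataset, mean_field_refine

sample = make_roi_dataset(SynthSpec(seed=11, canvas=64), 1)[0]
rng = np.random.default_rng(0)

n_labels = 5
probs = 0.4 * np.eye(n_labels)[sample.mask] + 0.6 / n_labels
probs += rng.uniform(0, 0.55, probs.shape)
probs /= probs.sum(axis=-1, keepdims=True)

image = sample.image * 255.0
params = CRFParams(sigma_alpha=20.0, sigma_beta=13.0, sigma_gamma=3.0)
refined, labels = mean_field_refine(probs, image, params)

before = int((probs.argmax(-1) != sample.mask).sum())
after = int((labels != sample.mask).sum())
print(f"wrong pixels before CRF: {before}")
print(f"wrong pixels after CRF : {after}")
print(f"improvement            : {before - after} pixels")
# The CRF cannot invent information; it cleans label noise where the image
# itself supports a coherent region.
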