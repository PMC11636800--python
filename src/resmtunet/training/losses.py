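"""Multi-task loss: classification cross-entropy + segmentation soft Dice.

The total objective is ``L_total = lambda * L_class + L_seg`` with
``lambda = 0.5`` by default; the segmentation term is a soft Dice loss over
all channels (background included) and the classification term is standard
cross-entropy on the image-level label.
"""

from __future__ import annotations

import numpy as np

from ..nn.tensor import Tensor, log_softmax, softmax


def one_hot(mask: np.ndarray, n_labels: int) -> np.ndarray:
    """(B, H, W) integer labels -> (B, L, H, W) one-hot floats."""
    if mask.min() < 0 or mask.max() >= n_labels:
        raise ValueError(f"mask labels outside [0, {n_labels})")
    return np.moveaxis(np.eye(n_labels)[mask.astype(int)], -1, 1)


def dice_loss(seg_probs: Tensor, mask_onehot: np.ndarray, eps: float = 1.0) -> Tensor:
    """Soft Dice loss: 1 - mean_c (2 sum(p q) + eps) / (sum p + sum q + eps).

    ``seg_probs`` holds per-pixel probabilities (B, L, H, W); sums run over
    batch and space, the mean over channels.  Values lie in [0, 1].
    """
    if seg_probs.shape != mask_onehot.shape:
        raise ValueError(
            f"shape mismatch: probs {seg_probs.shape} vs target {mask_onehot.shape}")
    q = Tensor(mask_onehot)
    inter = (seg_probs * q).sum(axis=(0, 2, 3))
    denom = seg_probs.sum(axis=(0, 2, 3)) + q.sum(axis=(0, 2, 3))
    dice = (2.0 * inter + eps) / (denom + eps)
    return 1.0 - dice.mean()


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels under row logits."""
    logp = log_softmax(logits, axis=-1)
    picked = logp[(np.arange(len(labels)), np.asarray(labels, dtype=int))]
    return -picked.mean()


def multitask_loss(output, masks: np.ndarray, labels: np.ndarray,
                   lambda_weight: float = 0.5,
                   ) -> tuple[Tensor, Tensor, Tensor]:
    """Return (L_total, L_class, L_seg) with L_total = lambda*L_class + L_seg."""
    l_class = cross_entropy(output.class_logits, labels)
    n_labels = output.seg_logits.shape[1]
    probs = softmax(output.seg_logits, axis=1)
    l_seg = dice_loss(probs, one_hot(masks, n_labels))
    total = lambda_weight * l_class + l_seg
    return total, l_class, l_seg
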