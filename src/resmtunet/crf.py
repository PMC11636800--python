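"""Fully connected CRF refinement of probability maps by mean-field inference.

The CRF energy over a pixel labeling x given an image I is

    E(x | I) = sum_i theta_i(x_i) + sum_{i<j} theta_ij(x_i, x_j)

with unary potentials theta_i(x_i) = -log P(x_i) taken from the network's
probability map, and Potts-weighted pairwise potentials built from two
Gaussian kernels: an appearance ("bilateral") kernel over pixel position and
RGB color that encourages similarly colored nearby pixels to share a label,
and a smoothness kernel over position alone that suppresses isolated small
regions.  Only pixel pairs with different labels are penalized.

Mean-field inference updates all pixel distributions in parallel; message
passing is exact (dense N^2) below a size cap and otherwise approximated with
separable Gaussian filtering — a downsampled five-dimensional bilateral grid
for the appearance kernel and a spatial Gaussian filter for the smoothness
kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate1d, gaussian_filter

DENSE_CAP = 4096          # max pixel count for exact O(N^2) message passing


@dataclass
class CRFParams:
    """Pairwise-energy hyperparameters (empirically determined defaults from
    the dense-CRF literature; all exposed in config)."""

    omega1: float = 1.0           # appearance kernel weight
    omega2: float = 1.0           # smoothness kernel weight
    sigma_alpha: float = 80.0     # appearance spatial scale, pixels
    sigma_beta: float = 13.0      # appearance color scale, 8-bit intensity
    sigma_gamma: float = 3.0      # smoothness spatial scale, pixels
    iterations: int = 5

    def __post_init__(self):
        if min(self.sigma_alpha, self.sigma_beta, self.sigma_gamma) <= 0:
            raise ValueError("kernel scales must be positive")
        if self.omega1 < 0 or self.omega2 < 0:
            raise ValueError("kernel weights must be non-negative")
        if self.iterations < 1:
            raise ValueError("at least one mean-field iteration required")


def build_unary(probs: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """theta = -log(max(P, floor)); finite for any simplex input."""
    probs = np.asarray(probs, dtype=np.float64)
    return -np.log(np.maximum(probs, floor))


def pairwise_potential(pi, pj, ii, ij, label_i: int, label_j: int,
                       params: CRFParams) -> float:
    """Pairwise energy of a single pixel pair (positions p, colors I)."""
    if label_i == label_j:
        return 0.0
    dp2 = float(np.sum((np.asarray(pi, float) - np.asarray(pj, float)) ** 2))
    di2 = float(np.sum((np.asarray(ii, float) - np.asarray(ij, float)) ** 2))
    appearance = np.exp(-dp2 / (2 * params.sigma_alpha ** 2)
                        - di2 / (2 * params.sigma_beta ** 2))
    smoothness = np.exp(-dp2 / (2 * params.sigma_gamma ** 2))
    return float(params.omega1 * appearance + params.omega2 * smoothness)


def _features(shape: tuple[int, int]):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    return np.stack([xx.ravel(), yy.ravel()], axis=1).astype(np.float64)


def _dense_kernels(image: np.ndarray, params: CRFParams):
    h, w = image.shape[:2]
    pos = _features((h, w))
    col = image.reshape(-1, 3).astype(np.float64)
    dp2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    di2 = ((col[:, None, :] - col[None, :, :]) ** 2).sum(-1)
    k1 = np.exp(-dp2 / (2 * params.sigma_alpha ** 2)
                - di2 / (2 * params.sigma_beta ** 2))
    k2 = np.exp(-dp2 / (2 * params.sigma_gamma ** 2))
    np.fill_diagonal(k1, 0.0)          # a pixel sends no message to itself
    np.fill_diagonal(k2, 0.0)
    return k1, k2


def total_energy(labels: np.ndarray, unary: np.ndarray, image: np.ndarray,
                 params: CRFParams, size_cap: int = DENSE_CAP) -> float:
    """Exact CRF energy of a complete labeling (small images only)."""
    labels = np.asarray(labels, dtype=int)
    h, w = labels.shape
    n = h * w
    if n > size_cap:
        raise ValueError(f"exact energy is quadratic; image has {n} > "
                         f"{size_cap} pixels")
    flat = labels.ravel()
    e = float(unary.reshape(n, -1)[np.arange(n), flat].sum())
    k1, k2 = _dense_kernels(image, params)
    diff = flat[:, None] != flat[None, :]
    pair = (params.omega1 * k1 + params.omega2 * k2) * diff
    return e + float(np.triu(pair, 1).sum())


# ---------------------------------------------------------------------------
# message passing
# ---------------------------------------------------------------------------

def _dense_message(q: np.ndarray, kernels) -> np.ndarray:
    k1, k2, params = kernels
    n, L = q.shape
    return params.omega1 * (k1 @ q) + params.omega2 * (k2 @ q)


def _spatial_filter(q: np.ndarray, sigma: float) -> np.ndarray:
    """Unnormalized Gaussian convolution per channel: approximates
    sum_j exp(-|p_i-p_j|^2 / 2 sigma^2) q_j including the j=i term."""
    mass = 2.0 * np.pi * sigma ** 2
    out = np.empty_like(q)
    for c in range(q.shape[-1]):
        out[..., c] = gaussian_filter(q[..., c], sigma=sigma, mode="constant")
    return out * mass


def _bilateral_grid_filter(q: np.ndarray, image: np.ndarray,
                           sigma_alpha: float, sigma_beta: float) -> np.ndarray:
    """Approximate bilateral filtering via a downsampled 5-D grid
    (x, y, r, g, b), one cell per kernel standard deviation."""
    h, w, L = q.shape
    feats = np.concatenate([
        np.stack(np.mgrid[0:h, 0:w], axis=-1).astype(np.float64) / sigma_alpha,
        image.astype(np.float64) / sigma_beta], axis=-1).reshape(-1, 5)
    lo = feats.min(axis=0)
    g = feats - lo + 1.0                       # 1-cell padding on each side
    dims = np.ceil(g.max(axis=0)).astype(int) + 2
    i0 = np.floor(g).astype(int)
    frac = g - i0
    qf = q.reshape(-1, L)
    grid = np.zeros((*dims, L))
    # multilinear splat over the 32 corners
    for corner in range(32):
        bits = [(corner >> k) & 1 for k in range(5)]
        wgt = np.ones(len(g))
        idx = []
        for k, b in enumerate(bits):
            wgt = wgt * (frac[:, k] if b else 1.0 - frac[:, k])
            idx.append(i0[:, k] + b)
        np.add.at(grid, tuple(idx), qf * wgt[:, None])
    # blur each grid axis with a unit-sigma normalized Gaussian
    kernel = np.exp(-0.5 * np.arange(-2, 3) ** 2)
    kernel /= kernel.sum()
    for axis in range(5):
        grid = correlate1d(grid, kernel, axis=axis, mode="constant")
    # multilinear slice
    out = np.zeros_like(qf)
    for corner in range(32):
        bits = [(corner >> k) & 1 for k in range(5)]
        wgt = np.ones(len(g))
        idx = []
        for k, b in enumerate(bits):
            wgt = wgt * (frac[:, k] if b else 1.0 - frac[:, k])
            idx.append(i0[:, k] + b)
        out += grid[tuple(idx)] * wgt[:, None]
    return (out * (2.0 * np.pi) ** 2.5).reshape(h, w, L)


def mean_field_refine(probs: np.ndarray, image: np.ndarray,
                      params: CRFParams | None = None, method: str = "auto",
                      dense_cap: int = DENSE_CAP,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Mean-field CRF refinement of a probability map.

    Parameters
    ----------
    probs : (H, W, L) per-pixel class probabilities (simplex).
    image : (H, W, 3) reference RGB in 8-bit intensity units.
    method : "dense" (exact messages), "grid" (separable approximation), or
        "auto" (dense below ``dense_cap`` pixels).

    Returns (refined probability map, argmax label mask).
    """
    params = params or CRFParams()
    probs = np.asarray(probs, dtype=np.float64)
    image = np.asarray(image, dtype=np.float64)
    h, w, L = probs.shape
    if image.shape[:2] != (h, w):
        raise ValueError("image and probability map must be congruent")
    unary = build_unary(probs).reshape(-1, L)
    if method == "auto":
        method = "dense" if h * w <= dense_cap else "grid"

    if method == "dense":
        k1, k2 = _dense_kernels(image, params)
        kernels = (k1, k2, params)
    elif method != "grid":
        raise ValueError(f"unknown method {method!r}")

    q = _softmax_rows(-unary)
    for it in range(params.iterations):
        if method == "dense":
            msg = _dense_message(q, kernels)
        else:
            qmap = q.reshape(h, w, L)
            msg = np.zeros_like(qmap)
            if params.omega1 > 0:
                msg += params.omega1 * (
                    _bilateral_grid_filter(qmap, image, params.sigma_alpha,
                                           params.sigma_beta) - qmap)
            if params.omega2 > 0:
                msg += params.omega2 * (
                    _spatial_filter(qmap, params.sigma_gamma) - qmap)
            msg = msg.reshape(-1, L)
        # Potts model: labels disagreeing with the field are penalized, which
        # is equivalent (up to a label-independent constant) to rewarding
        # agreement; softmax restores the simplex each iteration.
        q = _softmax_rows(-unary + msg)
        if not np.isfinite(q).all():
            raise RuntimeError(f"non-finite mean-field state at iteration {it}")
    refined = q.reshape(h, w, L)
    return refined, refined.argmax(axis=-1)


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    z = np.exp(logits - logits.max(axis=-1, keepdims=True))
    return z / z.sum(axis=-1, keepdims=True)
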