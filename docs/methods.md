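# Methods

## Problem and model

The package segments invasive carcinoma (IC) in H&E-stained breast
histopathology. The clinically hard part is separating IC from lesions that
mimic it — ductal carcinoma in situ (DCIS), benign or pre-cancerous
epithelium — which requires both local texture (nuclear morphology at the
lesion boundary) and long-range context (the low-magnification architecture
of the region). The model therefore uses a dual-branch encoder:

- a **hierarchical transformer branch** of four stages producing features at
  strides 4/8/16/32 (channel widths 64/128/320/512, depths 3/4/6/3, the
  MiT-B2 dimensioning). Each stage embeds patches with an overlapping strided
  convolution (K=7,S=4,P=3 for stage 1; K=3,S=2,P=1 after), then applies
  submodules of *efficient self-attention* (ESA) and *Mix-FFN*;
- a **residual CNN branch** (ResNet-50 topology, stride 32) supplying the
  local inductive bias CNNs are good at;
- a **fusion module** (channel concatenation + 3×3 convolution + batch norm +
  ReLU) joining the two stride-32 features. The fused feature drives a
  classification head (global average pooling + linear + softmax over the 4
  lesion classes) and seeds a U-Net decoder
  `x_i' = Conv(Concat(x_i, Upsample2×(x_{i+1}')))` down to stride 4, whose
  output feeds a two-convolution segmentation head emitting `n_class + 1`
  channels (background/stroma + 4 lesion classes) upsampled ×4 to full
  resolution.

ESA is ordinary multi-head attention `softmax(QKᵀ/√d_head)V`, except that K
and V are computed from a length-reduced sequence: the (N, C) token matrix is
reshaped to (N/R, C·R) and projected back to C channels by a linear layer, so
attention cost drops by the reduction ratio R (8/4/2/1 per stage). At R = 1
the operator is exactly dense attention, which the test suite exploits as an
oracle. Mix-FFN is `x + MLP(GELU(DWConv3×3(MLP(LN(x)))))`; the 3×3 depthwise
convolution over the token grid leaks zero-padding into the features and acts
as the positional signal, so no position embeddings exist anywhere in the
network. Pre-norm placement is used throughout (a LayerNorm in front of each
attention and FFN sublayer, one after each stage); with every internal weight
zeroed both sublayers reduce to the identity.

Class encoding: segmentation channel 0 = background + stroma; channels 1..4 =
normal epithelium, benign/pre-cancerous, DCIS, invasive carcinoma.
Classification uses the same four lesion classes.

## Loss and training

`L_total = λ·L_class + L_seg` with λ = 0.5. `L_class` is cross-entropy on the
image-level label. `L_seg` is a soft Dice loss over all channels (background
included): `1 − mean_c (2Σpq + ε)/(Σp + Σq + ε)` with ε = 1; no
cross-entropy term is added to the segmentation loss and no label smoothing is
applied. Default optimization: SGD, momentum 0.9, initial learning rate 1e-3
halved every 7 epochs, 30 epochs, batch 16, with horizontal/vertical flips
(image and mask together), Gaussian blur (σ ∈ [0.1, 2.0]) and brightness
jitter (±20%) each applied with probability 0.5 to the image only. The
checkpoint with the best validation mean IoU is kept.

## Whole-slide inference (multi-scale) and CRF

Slides are processed at 20× magnification. Otsu's threshold on the grayscale
thumbnail separates tissue (darker side) from glass; the foreground is tiled
into non-overlapping 512×512 patches on a grid anchored at (0,0), keeping
tiles with > 5% foreground. For each tile, two additional center crops of
768² and 1024² (reflect-padded at slide edges) are resized to 512² and
predicted; the two context outputs are resized back to native window size,
center-cropped to the tile, and averaged with the tile's own output in
probability space, then renormalized. Fused tiles are written into a
slide-level probability canvas (configurable output stride); off-tile pixels
get the background class; argmax yields the label mask. All resizes are
bilinear with the align_corners=False pixel-center convention and no
antialiasing.

The stitched map can be refined by a fully connected CRF with energy
`E(x|I) = Σ θ_i(x_i) + Σ θ_ij(x_i, x_j)`, unary `θ_i = −log max(P_i, 10⁻⁸)`,
and a Potts pairwise term combining an appearance kernel
`ω₁ exp(−‖p‖²/2σ_α² − ‖I‖²/2σ_β²)` and a smoothness kernel
`ω₂ exp(−‖p‖²/2σ_γ²)`; only differing labels are penalized. Mean-field
inference updates all pixels in parallel, renormalizing each pixel's
distribution every iteration. Message passing is exact (dense N², self-term
excluded) up to 4096 pixels and otherwise approximated by separable Gaussian
filtering: the smoothness kernel via a spatial Gaussian filter scaled by its
continuous mass 2πσ_γ², the appearance kernel via a downsampled 5-D bilateral
grid (one cell per kernel standard deviation, multilinear splat/slice,
unit-σ blur, mass (2π)^{5/2}). Defaults σ_α = 80 px, σ_β = 13 (8-bit RGB),
σ_γ = 3 px, ω₁ = ω₂ = 1, 5 iterations follow the dense-CRF literature and are
config-exposed; `--no-crf` bypasses refinement.

## Width calibration of the unpublished dimensions

The fusion width, decoder widths and segmentation-head hidden width are not
published. They were pinned jointly against the model's stated size budget:
110.73M trainable parameters and 91.13 GFLOPs at 512² input. Under those two
constraints a decoder that halves from the fused width is impossible — any
such decoder meeting the parameter budget costs ≈125 GMACs — so the design
places capacity in the stride-32 fusion (2360 channels, where MACs are cheap)
and keeps the decoder thin at high resolution (416/208/104 channels, seg-head
hidden width 40). The defaults give 110,730,297 parameters (110.73M) and
90.70 GMACs (−0.5% of the budget). FLOPs are counted as one per
multiply-accumulate of convolution, linear and attention layers;
normalizations, activations, poolings and interpolations are excluded — the
convention of the common profilers.

## Numerical engine

The network runs on a small reverse-mode automatic-differentiation engine
over NumPy float64 arrays (`resmtunet.nn`): hand-written vector-Jacobian
products for convolution (im2col), depthwise convolution, attention
primitives, batch/layer norm, pooling and bilinear interpolation, plus SGD
with momentum. Every primitive is validated against central finite
differences in the test suite, and the end-to-end joint-loss gradient is
checked the same way. Weight initialization: truncated normal (std 0.02) for
linear layers, Kaiming-normal for convolutions, seeded from the model config.

## Synthetic data

The generator emulates the structure of a breast-lesion ROI dataset: pink
stroma on near-white glass, with blob-shaped lesion regions (thresholded
smoothed Gaussian noise, morphologically opened so features are several
pixels wide) of exactly one class per ROI. Classes differ in mean color
(H&E-like purples of increasing depth) and nuclei-dot density, so small
networks can genuinely learn them; additive RGB noise (σ = 6/255) keeps the
problem non-trivial. Default ROI size is 96 px; lesion fractions are drawn
from [0.08, 0.45] by quantile thresholding inside the tissue, so realized
fractions stay in range. Pseudo-WSIs (default 2048², three ×2 pyramid
levels, 20× nominal magnification) plant compact single-component lesion
regions away from the tissue border and carry exact masks and a region
table.

What the synthetic data does *not* emulate: stain variability, scanner
artifacts, nuclear morphology, and the genuinely ambiguous DCIS/IC boundary
cases that make the real task hard. Passing tests therefore demonstrate the
*mechanics* — shapes, gradients, tiling geometry, stitching exactness, CRF
energetics, metric identities and the network's capacity to fit small
labeled sets — not clinical accuracy on real slides.

## Problem sizes used by the checks

The architecture checks construct the full-size model but never train it.
Training-dependent checks use a 1/8-width configuration (stage depths
1/1/2/1): the capacity check overfits 8 ROIs at 96 px for 200 full-batch SGD
steps (learning rate 0.05, momentum 0.9, no augmentation) and reaches
training mean IoU ≈ 0.96 against the 0.8 bar. The slide pipeline is
exercised on a 2048² pseudo-WSI with a ground-truth oracle predictor, which
must reproduce the planted mask exactly on foreground tiles. CRF claims are
verified with exact dense message passing on small problems, including
exhaustive-enumeration MAP comparisons on 3×3 two-label toys.

## Known limitations

- No ImageNet pretraining: training from scratch at full size is not
  attempted (loading externally obtained weights through the checkpoint
  format is supported but never required).
- The NumPy engine is single-threaded beyond BLAS and meant for desk-scale
  experiments, not production training.
- The bilateral-grid CRF approximation degrades for very small σ (grid cells
  are σ-sized); the dense path covers that regime.
- Otsu foreground detection assumes a bright background; slides with
  coverslip artifacts or pen marks would need masking upstream.
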