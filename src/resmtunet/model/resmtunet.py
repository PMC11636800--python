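"""The full ResMTUNet model and its checkpoint I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .. import nn
from ..config import ModelConfig
from ..nn.tensor import Tensor, no_grad, softmax
from .decoder import ClassificationHead, SegmentationHead, UNetDecoder
from .encoder import (FeaturePyramid, FusionModule, ResidualBranch,
                      TransformerBranch)


@dataclass
class ModelOutput:
    class_probs: Tensor     # (B, n_class), rows on the simplex
    seg_logits: Tensor      # (B, n_class + 1, H, W)
    class_logits: Tensor    # (B, n_class), pre-softmax


class ResMTUNet(nn.Module):
    """Dual-branch encoder-decoder with classification and segmentation heads.

    The input image passes through a hierarchical transformer branch (four
    stages, strides 4/8/16/32) and, in parallel, a residual CNN branch
    (stride 32).  The two stride-32 features are fused by a convolution
    module; the fused feature drives the classification head and seeds the
    U-Net decoder, whose stride-4 output feeds the segmentation head.
    """

    def __init__(self, cfg: ModelConfig | None = None):
        super().__init__()
        self.cfg = cfg = cfg or ModelConfig()
        rng = np.random.default_rng(cfg.seed)
        self.transformer = TransformerBranch(cfg, rng)
        self.residual = ResidualBranch(cfg, rng)
        self.fusion = FusionModule(cfg.channels[3], self.residual.out_channels,
                                   cfg.fused, rng)
        self.decoder = UNetDecoder(cfg, rng)
        self.cls_head = ClassificationHead(cfg.fused, cfg.n_class, rng)
        self.seg_head = SegmentationHead(self.decoder.out_channels,
                                         cfg.seg_hidden, cfg.n_class, rng)

    # ---- forward -------------------------------------------------------------
    def encode(self, x: Tensor) -> FeaturePyramid:
        levels = self.transformer(x)
        r4 = self.residual(x)
        fused = self.fusion(levels[3], r4)
        return FeaturePyramid(levels=levels, fused_top=fused)

    def forward(self, x: Tensor) -> ModelOutput:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float64))
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected NCHW RGB input, got shape {x.shape}")
        pyramid = self.encode(x)
        dec = self.decoder(pyramid)
        seg_logits = self.seg_head(dec)
        class_logits = self.cls_head.logits(pyramid.fused_top)
        return ModelOutput(class_probs=softmax(class_logits, axis=-1),
                           seg_logits=seg_logits, class_logits=class_logits)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities for a batch of NCHW images."""
        self.eval()
        with no_grad():
            out = self.forward(Tensor(images))
            probs = softmax(out.seg_logits, axis=1)
        return probs.data

    # ---- checkpointing -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        state = self.state_dict()
        state["__config__"] = np.frombuffer(
            json.dumps(self.cfg.to_dict()).encode(), dtype=np.uint8)
        np.savez_compressed(path, **state)

    @classmethod
    def from_checkpoint(cls, path: str | Path) -> "ResMTUNet":
        with np.load(Path(path)) as data:
            cfg = ModelConfig.from_dict(
                json.loads(bytes(data["__config__"]).decode()))
            model = cls(cfg)
            model.load_state_dict(
                {k: data[k] for k in data.files if k != "__config__"})
        return model
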