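"""Static parameter and multiply-accumulate accounting.

``count_parameters`` sums trainable scalars analytically from the
configuration; the result is checked against a constructed model in the test
suite.  ``count_macs`` walks the same architecture symbolically at a given
input size and accumulates multiply-accumulate operations (MACs) of
convolution, linear and attention layers — the convention used by the common
complexity profilers: normalizations, activations, poolings and
interpolations are not counted, and one MAC is reported as one FLOP.
``estimate_flops`` scales MACs by ``flops_per_mac`` (default 1 under this
convention).
"""

from __future__ import annotations

from ..config import PATCH_EMBED_SPECS, ModelConfig
from .encoder import RESNET_LAYERS, patch_embed_output_size


def _conv_p(cin: int, cout: int, k: int, bias: bool = True, groups: int = 1) -> int:
    return cout * (cin // groups) * k * k + (cout if bias else 0)


def _lin_p(cin: int, cout: int, bias: bool = True) -> int:
    return cin * cout + (cout if bias else 0)


def _norm_p(c: int) -> int:
    return 2 * c


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def _transformer_params(cfg: ModelConfig) -> int:
    total = 0
    ins = (3,) + cfg.channels[:3]
    for i in range(4):
        c = cfg.channels[i]
        k, _, _ = PATCH_EMBED_SPECS[i]
        total += _conv_p(ins[i], c, k) + _norm_p(c)          # embed + its norm
        hidden = c * cfg.mlp_ratio
        r = cfg.reduction_ratios[i]
        per_block = (
            _norm_p(c)                                        # pre-attention norm
            + 3 * _lin_p(c, c)                                # q, k, v
            + (_lin_p(c * r, c) if r > 1 else 0)              # sequence reduction
            + _lin_p(c, c)                                    # output projection
            + _norm_p(c)                                      # Mix-FFN norm
            + _lin_p(c, hidden)
            + _conv_p(hidden, hidden, 3, groups=hidden)       # depthwise 3x3
            + _lin_p(hidden, c)
        )
        total += cfg.stage_depths[i] * per_block
        total += _norm_p(c)                                   # stage norm
    return total


def _bottleneck_params(in_ch: int, width: int, stride: int) -> int:
    out_ch = 4 * width
    p = (_conv_p(in_ch, width, 1, bias=False) + _norm_p(width)
         + _conv_p(width, width, 3, bias=False) + _norm_p(width)
         + _conv_p(width, out_ch, 1, bias=False) + _norm_p(out_ch))
    if stride != 1 or in_ch != out_ch:
        p += _conv_p(in_ch, out_ch, 1, bias=False) + _norm_p(out_ch)
    return p


def _residual_params(cfg: ModelConfig) -> int:
    blocks = RESNET_LAYERS[cfg.residual_variant]
    w = cfg.res_width
    total = _conv_p(3, w, 7, bias=False) + _norm_p(w)
    in_ch = w
    for i, n in enumerate(blocks):
        width = w * 2 ** i
        total += _bottleneck_params(in_ch, width, 1 if i == 0 else 2)
        in_ch = 4 * width
        total += (n - 1) * _bottleneck_params(in_ch, width, 1)
    return total


def count_parameters(cfg: ModelConfig | None = None) -> int:
    """Total trainable parameters of the model described by ``cfg``."""
    cfg = cfg or ModelConfig()
    chans = cfg.channels
    dec = cfg.dec_channels
    f = cfg.fused
    res_out = 4 * cfg.res_width * 8
    total = _transformer_params(cfg) + _residual_params(cfg)
    total += _conv_p(chans[3] + res_out, f, 3, bias=False) + _norm_p(f)   # fusion
    ups = (f,) + dec[:2]
    for i in range(3):                                                     # decoder
        total += _conv_p(chans[2 - i] + ups[i], dec[i], 3, bias=False) + _norm_p(dec[i])
    total += _lin_p(f, cfg.n_class)                                        # cls head
    total += _conv_p(dec[2], cfg.seg_hidden, 3)                            # seg head
    total += _conv_p(cfg.seg_hidden, cfg.n_class + 1, 1)
    return total


# ---------------------------------------------------------------------------
# multiply-accumulates
# ---------------------------------------------------------------------------

def _transformer_macs(cfg: ModelConfig, size: int) -> int:
    total = 0
    ins = (3,) + cfg.channels[:3]
    s = size
    for i in range(4):
        c = cfg.channels[i]
        k, st, p = PATCH_EMBED_SPECS[i]
        s = patch_embed_output_size(s, k, st, p)
        n = s * s
        total += ins[i] * c * k * k * n                       # patch embedding
        hidden = c * cfg.mlp_ratio
        r = cfg.reduction_ratios[i]
        m = n // r
        d = c // cfg.head_counts[i]
        per_block = (
            n * c * c                                         # queries
            + (m * (c * r) * c if r > 1 else 0)               # sequence reduction
            + 2 * m * c * c                                   # keys, values
            + cfg.head_counts[i] * (n * m * d)                # Q K^T
            + cfg.head_counts[i] * (n * m * d)                # attn V
            + n * c * c                                       # output projection
            + n * c * hidden                                  # fc1
            + hidden * 9 * n                                  # depthwise 3x3
            + n * hidden * c                                  # fc2
        )
        total += cfg.stage_depths[i] * per_block
    return total


def _residual_macs(cfg: ModelConfig, size: int) -> int:
    blocks = RESNET_LAYERS[cfg.residual_variant]
    w = cfg.res_width
    s = size // 2
    total = 3 * w * 49 * s * s                                # stem 7x7/2
    s //= 2                                                   # max pool
    in_ch = w

    def bottleneck(in_ch, width, stride, s):
        out_s = s // stride
        macs = (in_ch * width * s * s                          # 1x1 (pre-stride)
                + width * width * 9 * out_s * out_s            # 3x3 (strided)
                + width * 4 * width * out_s * out_s)           # 1x1 expand
        if stride != 1 or in_ch != 4 * width:
            macs += in_ch * 4 * width * out_s * out_s
        return macs, out_s

    for i, n in enumerate(blocks):
        width = w * 2 ** i
        m, s = bottleneck(in_ch, width, 1 if i == 0 else 2, s)
        total += m
        in_ch = 4 * width
        for _ in range(n - 1):
            m, s = bottleneck(in_ch, width, 1, s)
            total += m
    return total


def count_macs(cfg: ModelConfig | None = None, input_size: int | None = None) -> int:
    """Forward-pass multiply-accumulates at the given input size."""
    cfg = cfg or ModelConfig()
    size = input_size or cfg.input_size
    chans = cfg.channels
    dec = cfg.dec_channels
    f = cfg.fused
    res_out = 4 * cfg.res_width * 8
    s32 = size // 32
    total = _transformer_macs(cfg, size) + _residual_macs(cfg, size)
    total += (chans[3] + res_out) * f * 9 * s32 * s32          # fusion 3x3
    ups = (f,) + dec[:2]
    for i in range(3):                                         # decoder levels 3..1
        s = size // (2 ** (4 - i))                             # 32, 64, 128 for 512
        total += (chans[2 - i] + ups[i]) * dec[i] * 9 * s * s
    total += f * cfg.n_class                                   # cls head linear
    s4 = size // 4
    total += dec[2] * cfg.seg_hidden * 9 * s4 * s4             # seg head 3x3
    total += cfg.seg_hidden * (cfg.n_class + 1) * s4 * s4      # seg head 1x1
    return total


def estimate_flops(cfg: ModelConfig | None = None, input_size: int | None = None,
                   flops_per_mac: int = 1) -> float:
    """FLOP estimate under the documented counting convention."""
    return float(count_macs(cfg, input_size)) * flops_per_mac
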