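"""Efficient self-attention and Mix-FFN token modules.

Efficient self-attention (ESA) is ordinary scaled dot-product attention whose
keys and values are computed from a length-reduced token sequence: the input
``X`` of shape (N, C) is reshaped to (N/R, C*R) and projected back to C
channels by a linear map, so K and V have length N/R while the queries retain
all N tokens.  With R = 1 it degenerates to dense multi-head self-attention.

Mix-FFN is a feed-forward block whose hidden layer contains a 3x3 depthwise
convolution over the token grid; the convolution leaks zero-padded border
information into the tokens and thereby acts as an implicit positional
encoding, so no explicit position embeddings are needed.
"""

from __future__ import annotations

import numpy as np

from .. import nn
from ..nn.tensor import Tensor, softmax


class EfficientSelfAttention(nn.Module):
    """Multi-head attention with sequence reduction of K/V by factor R."""

    def __init__(self, dim: int, heads: int, reduction: int,
                 rng: np.random.Generator):
        super().__init__()
        if dim % heads != 0:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.dim, self.heads, self.reduction = dim, heads, reduction
        self.head_dim = dim // heads
        self.q = nn.Linear(dim, dim, rng=rng)
        self.k = nn.Linear(dim, dim, rng=rng)
        self.v = nn.Linear(dim, dim, rng=rng)
        if reduction > 1:
            self.reduce = nn.Linear(dim * reduction, dim, rng=rng)
        else:
            self.reduce = None
        self.proj = nn.Linear(dim, dim, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        B, N, C = x.shape
        R = self.reduction
        if N % R != 0:
            raise ValueError(f"token count {N} not divisible by reduction {R}")
        q = self.q(x)
        src = self.reduce(x.reshape(B, N // R, C * R)) if self.reduce is not None else x
        k = self.k(src)
        v = self.v(src)
        M = src.shape[1]
        h, d = self.heads, self.head_dim
        q = q.reshape(B, N, h, d).transpose(0, 2, 1, 3)     # B,h,N,d
        k = k.reshape(B, M, h, d).transpose(0, 2, 3, 1)     # B,h,d,M
        v = v.reshape(B, M, h, d).transpose(0, 2, 1, 3)     # B,h,M,d
        attn = softmax((q @ k) * (1.0 / np.sqrt(d)), axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, N, C)
        return self.proj(out)


class MixFFN(nn.Module):
    """Token MLP with a 3x3 depthwise convolution and a residual connection.

    The leading layer normalization plays the role of the usual pre-norm; with
    every internal weight zeroed the block is the identity.
    """

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.norm = nn.LayerNorm(dim)
        self.fc1 = nn.Linear(dim, hidden, rng=rng)
        self.dwconv = nn.Conv2d(hidden, hidden, 3, 1, 1, groups=hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, dim, rng=rng)

    def forward(self, x: Tensor, hw: tuple[int, int]) -> Tensor:
        B, N, C = x.shape
        H, W = hw
        if H * W != N:
            raise ValueError(f"token count {N} does not match grid {H}x{W}")
        y = self.fc1(self.norm(x))
        y = y.transpose(0, 2, 1).reshape(B, y.shape[-1], H, W)
        y = self.dwconv(y)
        y = y.reshape(B, y.shape[1], N).transpose(0, 2, 1)
        y = self.fc2(y.gelu())
        return y + x


class TransformerSubmodule(nn.Module):
    """One encoder submodule: pre-norm ESA with residual, then Mix-FFN."""

    def __init__(self, dim: int, heads: int, reduction: int, mlp_ratio: int,
                 rng: np.random.Generator):
        super().__init__()
        self.norm1 = nn.LayerNorm(dim)
        self.attn = EfficientSelfAttention(dim, heads, reduction, rng)
        self.ffn = MixFFN(dim, dim * mlp_ratio, rng)

    def forward(self, x: Tensor, hw: tuple[int, int]) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return self.ffn(x, hw)
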