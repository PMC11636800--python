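"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small engine: a :class:`Tensor` wraps an ``ndarray`` and records
the operations applied to it; calling :meth:`Tensor.backward` on a scalar loss
walks the recorded graph in reverse topological order and accumulates
gradients.  Only the operations the network needs are implemented, each with a
hand-written vector-Jacobian product.  Everything runs in float64.

Gradient correctness of every primitive is established against central finite
differences in the test suite.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple["Tensor", ...] = (),
                 _vjp: Callable[[np.ndarray], Iterable[np.ndarray | None]] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._vjp = _vjp

    # ---- construction helper -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...],
              vjp: Callable[[np.ndarray], Iterable[np.ndarray | None]]) -> "Tensor":
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            return Tensor(data, requires_grad=True, _parents=parents, _vjp=vjp)
        return Tensor(data)

    # ---- bookkeeping ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._vjp is None:
                continue
            grads = node._vjp(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g
            # free intermediate gradient storage
            if node is not self:
                node._vjp = None

    # ---- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = self.data + other.data
        return Tensor._make(out, (self, other), lambda g: (
            _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)))

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = self.data * other.data
        return Tensor._make(out, (self, other), lambda g: (
            _unbroadcast(g * other.data, self.shape),
            _unbroadcast(g * self.data, other.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = self.data / other.data
        return Tensor._make(out, (self, other), lambda g: (
            _unbroadcast(g / other.data, self.shape),
            _unbroadcast(-g * self.data / other.data ** 2, other.shape)))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = self.data ** exponent
        return Tensor._make(out, (self,),
                            lambda g: (g * exponent * self.data ** (exponent - 1),))

    def __matmul__(self, other):
        other = as_tensor(other)
        out = self.data @ other.data
        a, b = self.data, other.data

        def vjp(g):
            if b.ndim == 1:
                ga = np.outer(g, b) if a.ndim == 2 else g[..., None] * b
            else:
                ga = g @ np.swapaxes(b, -1, -2)
            if a.ndim == 1:
                gb = np.outer(a, g)
            else:
                gb = np.swapaxes(a, -1, -2) @ g
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return Tensor._make(out, (self, other), vjp)

    # ---- indexing / shape ----------------------------------------------------
    def __getitem__(self, idx):
        out = self.data[idx]

        def vjp(g):
            gx = np.zeros_like(self.data)
            np.add.at(gx, idx, g)
            return (gx,)

        return Tensor._make(out, (self,), vjp)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = self.data.reshape(shape)
        return Tensor._make(out, (self,), lambda g: (g.reshape(self.shape),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = self.data.transpose(axes)
        return Tensor._make(out, (self,), lambda g: (g.transpose(inv),))

    # ---- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.shape).copy(),)

        return Tensor._make(out, (self,), vjp)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ---- elementwise nonlinearities ------------------------------------------
    def exp(self):
        out = np.exp(self.data)
        return Tensor._make(out, (self,), lambda g: (g * out,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def gelu(self):
        """Exact (erf-based) GELU."""
        x = self.data
        phi = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        out = x * phi

        def vjp(g):
            pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
            return (g * (phi + x * pdf),)

        return Tensor._make(out, (self,), vjp)

    def clip_min(self, lo: float):
        mask = self.data > lo
        return Tensor._make(np.maximum(self.data, lo), (self,), lambda g: (g * mask,))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------------

def concat(tensors: list[Tensor], axis: int) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out, tuple(tensors), vjp)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def vjp(g):
        return (s * (g - (g * s).sum(axis=axis, keepdims=True)),)

    return Tensor._make(s, (x,), vjp)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = z - lse

    def vjp(g):
        return (g - np.exp(out) * g.sum(axis=axis, keepdims=True),)

    return Tensor._make(out, (x,), vjp)


# ---- convolution -----------------------------------------------------------

def _windows(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    """Strided view (B, C, Ho, Wo, kh, kw) of a padded NCHW array."""
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return win[:, :, ::sh, ::sw]


def _accumulate_windows(dwin: np.ndarray, pshape: tuple[int, ...],
                        sh: int, sw: int) -> np.ndarray:
    """Scatter window gradients back onto the padded input (col2im)."""
    b, c, ho, wo, kh, kw = dwin.shape
    dxp = np.zeros(pshape, dtype=np.float64)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + ho * sh:sh, j:j + wo * sw:sw] += dwin[:, :, :, :, i, j]
    return dxp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: int = 0, groups: int = 1) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout.

    ``groups`` must be 1 (dense) or equal to the channel count (depthwise).
    """
    B, C, H, W = x.shape
    Co, Cin_g, kh, kw = w.shape
    sh = sw = stride
    if H + 2 * padding < kh or W + 2 * padding < kw:
        raise ValueError(
            f"conv2d: input {H}x{W} with padding {padding} smaller than kernel {kh}x{kw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    win = _windows(xp, kh, kw, sh, sw)           # B,C,Ho,Wo,kh,kw
    Ho, Wo = win.shape[2], win.shape[3]

    if groups == 1:
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho, Wo, C * kh * kw)
        wmat = w.data.reshape(Co, C * kh * kw)
        out = cols @ wmat.T                       # B,Ho,Wo,Co
        out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
    elif groups == C and Cin_g == 1 and Co == C:
        out = np.einsum("bcxykl,ckl->bcxy", win, w.data[:, 0], optimize=True)
    else:
        raise NotImplementedError("conv2d supports dense or depthwise groups only")

    if b is not None:
        out = out + b.data[None, :, None, None]

    def vjp(g):
        if groups == 1:
            gmat = g.transpose(0, 2, 3, 1).reshape(-1, Co)           # BHW x Co
            colsf = cols.reshape(-1, C * kh * kw)
            gw = (gmat.T @ colsf).reshape(w.shape)
            dcols = (gmat @ wmat).reshape(B, Ho, Wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        else:
            gw = np.einsum("bcxykl,bcxy->ckl", win, g, optimize=True)[:, None]
            dcols = g[:, :, :, :, None, None] * w.data[:, 0][None, :, None, None]
        dxp = _accumulate_windows(dcols, xp.shape, sh, sw)
        dx = dxp[:, :, padding:padding + H, padding:padding + W] if padding else dxp
        gb = None if b is None else g.sum(axis=(0, 2, 3))
        return dx, gw, gb

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, vjp)


def max_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    B, C, H, W = x.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=-np.inf) if padding else x.data
    win = _windows(xp, kernel, kernel, stride, stride)
    B_, C_, Ho, Wo = win.shape[:4]
    flat = win.reshape(B, C, Ho, Wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def vjp(g):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, arg[..., None], g[..., None], axis=-1)
        dwin = dflat.reshape(B, C, Ho, Wo, kernel, kernel)
        dxp = _accumulate_windows(dwin, xp.shape, stride, stride)
        return (dxp[:, :, padding:padding + H, padding:padding + W] if padding else dxp,)

    return Tensor._make(out, (x,), vjp)


# ---- bilinear interpolation ------------------------------------------------

def _bilinear_coeffs(n_in: int, n_out: int):
    """Source indices/weights for 1-D bilinear resize, align_corners=False."""
    scale = n_in / n_out
    x = (np.arange(n_out) + 0.5) * scale - 0.5
    x = np.clip(x, 0.0, n_in - 1.0)
    i0 = np.floor(x).astype(np.int64)
    i1 = np.minimum(i0 + 1, n_in - 1)
    f = x - i0
    return i0, i1, f


def interpolate_bilinear(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Bilinear resize of an NCHW tensor (align_corners=False, no antialias)."""
    B, C, H, W = x.shape
    Ho, Wo = out_hw
    if (H, W) == (Ho, Wo):
        return x
    r0, r1, fr = _bilinear_coeffs(H, Ho)
    c0, c1, fc = _bilinear_coeffs(W, Wo)
    fr = fr[:, None]
    fc = fc[None, :]
    d = x.data
    top = d[:, :, r0][:, :, :, c0] * (1 - fc) + d[:, :, r0][:, :, :, c1] * fc
    bot = d[:, :, r1][:, :, :, c0] * (1 - fc) + d[:, :, r1][:, :, :, c1] * fc
    out = top * (1 - fr) + bot * fr

    def vjp(g):
        # flat must be a view of gx: allocate C-contiguous explicitly
        flat = np.zeros((B * C, H * W))
        rows = [(r0, (1 - fr)), (r1, fr)]
        cols = [(c0, (1 - fc)), (c1, fc)]
        for ri, rw in rows:
            for ci, cw in cols:
                wgt = np.ascontiguousarray(g * rw * cw).reshape(B * C, Ho * Wo)
                idx = (ri[:, None] * W + ci[None, :]).ravel()
                np.add.at(flat, (slice(None), idx), wgt)
        return (flat.reshape(B, C, H, W),)

    return Tensor._make(out, (x,), vjp)
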