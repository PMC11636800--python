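"""Layer abstractions over the autodiff engine (Module, Conv2d, norms, ...)."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import (Tensor, concat, conv2d, interpolate_bilinear, max_pool2d,
                     softmax)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Truncated normal in [-2 std, 2 std] via resampling."""
    out = rng.normal(0.0, std, size=shape)
    bad = np.abs(out) > 2 * std
    while bad.any():
        out[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(out) > 2 * std
    return out


def kaiming_normal(rng: np.random.Generator, shape, fan: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan), size=shape)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # ---- (de)serialization ---------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self._named_buffers():
            state[name] = m.copy()
        return state

    def _named_buffers(self, prefix: str = ""):
        for name, m in self._modules.items():
            yield from m._named_buffers(prefix + name + ".")
        if isinstance(self, BatchNorm2d):
            yield prefix + "running_mean", self.running_mean
            yield prefix + "running_var", self.running_var

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        buffers = dict(self._named_buffers())
        for name, arr in state.items():
            if name in own:
                if own[name].shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}")
                own[name].data = np.asarray(arr, dtype=np.float64).copy()
            elif name in buffers:
                buffers[name][...] = arr
            else:
                raise KeyError(f"unexpected key {name}")
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing keys: {sorted(missing)[:5]} ...")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"_{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class ModuleList(Module):
    def __init__(self, mods: list[Module] | None = None):
        super().__init__()
        self._items: list[Module] = []
        for m in (mods or []):
            self.append(m)

    def append(self, m: Module) -> None:
        setattr(self, f"_{len(self._items)}", m)
        self._items.append(m)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class GELU(Module):
    def forward(self, x):
        return x.gelu()


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(trunc_normal(rng, (out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight.transpose(1, 0)
        return y + self.bias if self.bias is not None else y


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, groups: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding, self.groups = kernel, stride, padding, groups
        fan_out = out_ch * kernel * kernel // groups
        self.weight = Parameter(kaiming_normal(
            rng, (out_ch, in_ch // groups, kernel, kernel), fan_out))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class BatchNorm2d(Module):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.ch, self.eps, self.momentum = ch, eps, momentum
        self.weight = Parameter(np.ones(ch))
        self.bias = Parameter(np.zeros(ch))
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mean) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            n = x.shape[0] * x.shape[2] * x.shape[3]
            self.running_mean *= (1 - self.momentum)
            self.running_mean += self.momentum * mean.data.ravel()
            self.running_var *= (1 - self.momentum)
            self.running_var += self.momentum * var.data.ravel() * n / max(n - 1, 1)
        else:
            mean = Tensor(self.running_mean[None, :, None, None])
            var = Tensor(self.running_var[None, :, None, None])
        xhat = (x - mean) / ((var + self.eps) ** 0.5)
        return xhat * self.weight.reshape(1, self.ch, 1, 1) \
            + self.bias.reshape(1, self.ch, 1, 1)


class LayerNorm(Module):
    """Normalization over the last axis."""

    def __init__(self, ch: int, eps: float = 1e-6):
        super().__init__()
        self.ch, self.eps = ch, eps
        self.weight = Parameter(np.ones(ch))
        self.bias = Parameter(np.zeros(ch))

    def forward(self, x: Tensor) -> Tensor:
        mean = x.mean(axis=-1, keepdims=True)
        var = ((x - mean) ** 2).mean(axis=-1, keepdims=True)
        xhat = (x - mean) / ((var + self.eps) ** 0.5)
        return xhat * self.weight + self.bias


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return max_pool2d(x, self.kernel, self.stride, self.padding)


class Upsample2x(Module):
    """Bilinear 2x upsampling (align_corners=False)."""

    def forward(self, x: Tensor) -> Tensor:
        _, _, h, w = x.shape
        return interpolate_bilinear(x, (2 * h, 2 * w))


__all__ = [
    "Parameter", "Module", "Sequential", "ModuleList", "Identity", "ReLU",
    "GELU", "Linear", "Conv2d", "BatchNorm2d", "LayerNorm", "MaxPool2d",
    "Upsample2x", "trunc_normal", "kaiming_normal", "concat", "softmax",
]
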