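"""Neural-network modules built on the autodiff :class:`~vadistill.nn.tensor.Tensor`.

The module system mirrors the familiar torch-style API surface (parameters,
train/eval modes, state dicts) at the scale this package needs.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .tensor import Tensor, batch_norm_train, conv2d, maxpool2x2

__all__ = [
    "Module",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "ReLU",
    "Dropout",
    "MaxPool2d",
    "GlobalAvgPool",
    "Flatten",
    "Identity",
    "SqueezeExcite",
    "BilinearResize",
]


class Module:
    """Base class: parameter traversal, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    # -- traversal ---------------------------------------------------------
    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # -- modes -------------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- persistence -------------------------------------------------------
    def _buffers(self) -> Iterator[tuple[str, np.ndarray]]:
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield name, value

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                state[prefix + name] = value.data.copy()
            elif isinstance(value, np.ndarray):
                state[prefix + name] = value.copy()
        for name, child in self._children():
            state.update(child.state_dict(prefix + name + "."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, value in vars(self).items():
            key = prefix + name
            if isinstance(value, Tensor) and value.requires_grad:
                if value.data.shape != state[key].shape:
                    raise ValueError(f"shape mismatch for {key}")
                value.data = state[key].astype(value.data.dtype).copy()
            elif isinstance(value, np.ndarray):
                setattr(self, name, state[key].astype(value.dtype).copy())
        for name, child in self._children():
            child.load_state_dict(state, prefix + name + ".")

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.layers = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x

    def __iter__(self):
        return iter(self.layers)

    def __len__(self):
        return len(self.layers)

    def __getitem__(self, i):
        return self.layers[i]


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        groups: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.groups = groups
        fan_out = out_channels * kernel_size * kernel_size // groups
        std = math.sqrt(2.0 / fan_out)  # He init, fan-out mode (ReLU nets)
        shape = (out_channels, in_channels // groups, kernel_size, kernel_size)
        self.weight = Tensor(rng.normal(0.0, std, shape).astype(np.float32), requires_grad=True)
        self.bias = (
            Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True) if bias else None
        )

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Tensor(np.ones(num_features, dtype=np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(num_features, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = batch_norm_train(x, self.weight, self.bias, self.eps)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
            return out
        shape = (1, -1, 1, 1) if x.ndim == 4 else (1, -1)
        # fold running stats and affine into a single scale/shift pair
        rstd = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = (self.weight.data * rstd).astype(x.dtype).reshape(shape)
        shift = (self.bias.data - self.running_mean * self.weight.data * rstd).astype(
            x.dtype
        ).reshape(shape)
        return x * Tensor(scale) + Tensor(shift)


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_features = in_features
        self.out_features = out_features
        bound = math.sqrt(1.0 / in_features)
        self.weight = Tensor(
            rng.uniform(-bound, bound, (out_features, in_features)).astype(np.float32),
            requires_grad=True,
        )
        self.bias = (
            Tensor(rng.uniform(-bound, bound, out_features).astype(np.float32), requires_grad=True)
            if bias
            else None
        )

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight.transpose(1, 0)
        if self.bias is not None:
            y = y + self.bias
        return y


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Dropout(Module):
    def __init__(self, p: float = 0.5, rng: np.random.Generator | None = None):
        super().__init__()
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask.astype(x.dtype))


class MaxPool2d(Module):
    """2x2, stride-2 max pooling (the only configuration the nets use)."""

    def forward(self, x: Tensor) -> Tensor:
        return maxpool2x2(x)


class GlobalAvgPool(Module):
    """Adaptive average pooling to 1x1."""

    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3), keepdims=True)


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.shape[0], -1)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class SqueezeExcite(Module):
    """Channel gating: global pool -> bottleneck MLP (as 1x1 convs) -> sigmoid scale."""

    def __init__(self, channels: int, reduction: int = 4, rng: np.random.Generator | None = None):
        super().__init__()
        squeezed = max(1, channels // reduction)
        self.fc1 = Conv2d(channels, squeezed, 1, rng=rng)
        self.fc2 = Conv2d(squeezed, channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        s = x.mean(axis=(2, 3), keepdims=True)
        s = self.fc1(s).relu()
        s = self.fc2(s).sigmoid()
        return x * s


class BilinearResize(Module):
    """Bilinear spatial resize expressed as two constant interpolation matmuls."""

    def __init__(self, out_hw: tuple[int, int]):
        super().__init__()
        self.out_hw = out_hw
        self._mats: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}

    @staticmethod
    def _interp_matrix(n_out: int, n_in: int, dtype) -> np.ndarray:
        mat = np.zeros((n_out, n_in), dtype=dtype)
        if n_in == 1:
            mat[:, 0] = 1.0
            return mat
        src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
        src = np.clip(src, 0, n_in - 1)
        lo = np.floor(src).astype(int)
        hi = np.minimum(lo + 1, n_in - 1)
        frac = src - lo
        mat[np.arange(n_out), lo] += 1 - frac
        mat[np.arange(n_out), hi] += frac
        return mat

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        oh, ow = self.out_hw
        if (h, w) == (oh, ow):
            return x
        key = (h, w)
        if key not in self._mats:
            self._mats[key] = (
                self._interp_matrix(oh, h, np.float32),
                self._interp_matrix(ow, w, np.float32),
            )
        ah, aw = self._mats[key]
        xr = x.reshape(n * c, h, w)
        y = Tensor(ah.astype(x.dtype)) @ xr @ Tensor(aw.T.astype(x.dtype))
        return y.reshape(n, c, oh, ow)
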