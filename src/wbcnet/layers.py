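"""Neural-network layers built on the autograd engine.

Conventions follow the usual deep-learning layer catalogue: NCHW feature
volumes, He-uniform convolution initialisation, unit-gamma/zero-beta
normalisation layers.  Group normalisation is the in-block normaliser (it is
batch-size independent); batch normalisation appears only once, after the
attention/feature fusion stage of the full network.
"""

from __future__ import annotations

import logging
import math
from math import gcd

import numpy as np

from .autograd import Tensor, conv2d, maxpool2d

logger = logging.getLogger(__name__)


class Module:
    """Base class: parameter traversal, train/eval mode, state dict."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    def register(self, name: str, value: np.ndarray, trainable: bool = True) -> Tensor:
        t = Tensor(np.asarray(value, dtype=np.float32), requires_grad=trainable)
        self._params[name] = t
        object.__setattr__(self, name, t)
        return t

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield (prefix + name if not prefix else f"{prefix}.{name}"), p
        for cname, child in self._children.items():
            yield from child.named_parameters(f"{prefix}.{cname}" if prefix else cname)

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def trainable_parameters(self):
        return [p for p in self.parameters() if p.requires_grad]

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        bufs = dict(self._buffer_refs())
        for name, arr in state.items():
            if name in own:
                if own[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}: "
                                     f"{own[name].data.shape} vs {arr.shape}")
                own[name].data = np.asarray(arr, dtype=np.float32).copy()
            elif name in bufs:
                holder, attr = bufs[name]
                setattr(holder, attr, np.asarray(arr, dtype=np.float32).copy())
            else:
                raise KeyError(f"unexpected entry in state dict: {name}")

    # buffers = non-trainable running statistics (batch norm)
    def named_buffers(self, prefix: str = ""):
        for name, (holder, attr) in self._buffer_refs(prefix):
            yield name, getattr(holder, attr)

    def _buffer_refs(self, prefix: str = ""):
        for attr in getattr(self, "_buffers", ()):  # type: ignore[attr-defined]
            name = f"{prefix}.{attr}" if prefix else attr
            yield name, (self, attr)
        for cname, child in self._children.items():
            cpre = f"{prefix}.{cname}" if prefix else cname
            yield from child._buffer_refs(cpre)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def count_parameters(module: Module) -> int:
    """Exact number of trainable scalars in ``module``."""
    return int(sum(p.data.size for p in module.trainable_parameters()))


class Conv2d(Module):
    """2-D convolution; ``padding='same'`` keeps spatial dims at stride 1."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, dilation: int = 1,
                 padding: int | str = "same", bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if dilation < 1:
            raise ValueError(f"dilation must be positive, got {dilation}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.dilation = dilation
        if padding == "same":
            padding = dilation * (kernel - 1) // 2
        self.padding = int(padding)
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel * kernel
        limit = math.sqrt(6.0 / fan_in)  # He-uniform
        w = rng.uniform(-limit, limit, (out_channels, in_channels, kernel, kernel))
        self.register("weight", w)
        if bias:
            self.register("bias", np.zeros(out_channels))
        else:
            self.bias = None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, "
                             f"received {x.shape[1]}")
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      dilation=self.dilation, padding=self.padding)


class GroupNorm(Module):
    """Normalise channel groups per sample: (x - mu_g) / sqrt(var_g + eps).

    When ``num_groups`` does not divide the channel count the group count
    falls back to gcd(num_groups, channels) with a logged warning, so narrow
    width-reduced models remain valid.
    """

    def __init__(self, num_channels: int, num_groups: int = 32,
                 eps: float = 1e-5):
        super().__init__()
        if eps <= 0:
            raise ValueError("eps must be positive")
        if num_channels % num_groups != 0:
            fallback = gcd(num_groups, num_channels)
            logger.warning(
                "GroupNorm: %d groups does not divide %d channels; using %d",
                num_groups, num_channels, fallback)
            num_groups = fallback
        self.num_channels = num_channels
        self.num_groups = num_groups
        self.eps = eps
        self.register("gamma", np.ones(num_channels))
        self.register("beta", np.zeros(num_channels))

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != self.num_channels:
            raise ValueError(f"GroupNorm built for {self.num_channels} channels, "
                             f"received {c}")
        g = self.num_groups
        xg = x.reshape(n, g, (c // g) * h * w)
        mu = xg.mean(axis=2, keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=2, keepdims=True)
        xn = xc * (var + self.eps) ** -0.5
        xn = xn.reshape(n, c, h, w)
        return xn * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics for eval."""

    _buffers = ("running_mean", "running_var")

    def __init__(self, num_channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_channels = num_channels
        self.eps = eps
        self.momentum = momentum
        self.register("gamma", np.ones(num_channels))
        self.register("beta", np.zeros(num_channels))
        self.running_mean = np.zeros(num_channels, dtype=np.float32)
        self.running_var = np.ones(num_channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.data.reshape(c))
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data.reshape(c))
            xn = xc * (var + self.eps) ** -0.5
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
            xn = (x - mu) * (var + self.eps) ** -0.5
        return xn * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        limit = math.sqrt(6.0 / in_features)
        self.register("weight", rng.uniform(-limit, limit,
                                            (in_features, out_features)))
        self.register("bias", np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Mask drawn from ``self.rng``."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * Tensor(mask)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class MaxPool2d(Module):
    def __init__(self, k: int = 2):
        super().__init__()
        self.k = k

    def forward(self, x: Tensor) -> Tensor:
        return maxpool2d(x, self.k)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            self._children[str(i)] = m

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x
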