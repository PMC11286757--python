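"""Architectural building blocks of the classifier.

* :class:`ConvStem` — 3x3 convolution, 2x2 max pooling, group norm, ReLU.
* :class:`ResidualBranch` — conv-GN-ReLU-conv-GN with a skip connection;
  a dilation above 1 turns both convolutions into dilated convolutions.
* :class:`DRDB` — the six-branch dilated residual block: three plain
  residual branches interleaved with three dilated ones (dilations 1, 2, 4),
  channel-concatenated and reduced by a 1x1 convolution.
* :class:`GLFEB` — global/local feature enhancement: a three-convolution
  local path whose output is concatenated with a projection of the stem's
  global feature and squashed by tanh (so the output has twice the
  pre-concatenation channel count and lives in (-1, 1)).
* :class:`ChannelAttention` / :class:`SpatialAttention` / :class:`CSAB` —
  the channel gate (global average pool -> linear -> ReLU -> two FC layers
  -> sigmoid), the spatial gate (5x5 conv -> ReLU -> sum-normalisation so
  the map integrates to 1), and their elementwise combination
  ``out[c,i,j] = at[c,i,j] * Qc[c] * Qs[i,j]``.
"""

from __future__ import annotations

import logging

import numpy as np

from .autograd import Tensor, bilinear_resize, concat
from .layers import Conv2d, GroupNorm, Linear, MaxPool2d, Module

logger = logging.getLogger(__name__)


class ConvStem(Module):
    """Input stage: conv 3x3 -> max-pool 2x2 -> group norm -> ReLU."""

    def __init__(self, in_channels: int, out_channels: int, gn_groups: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, 3, rng=rng)
        self.pool = MaxPool2d(2)
        self.norm = GroupNorm(out_channels, gn_groups)

    def forward(self, x: Tensor) -> Tensor:
        return self.norm(self.pool(self.conv(x))).relu()


class ResidualBranch(Module):
    """x + T(x), with T = conv-GN-ReLU-conv-GN (convs optionally dilated)."""

    def __init__(self, width: int, gn_groups: int, rng: np.random.Generator,
                 dilation: int = 1):
        super().__init__()
        if dilation < 1:
            raise ValueError(f"dilation must be positive, got {dilation}")
        self.dilation = dilation
        self.conv1 = Conv2d(width, width, 3, dilation=dilation, rng=rng)
        self.norm1 = GroupNorm(width, gn_groups)
        self.conv2 = Conv2d(width, width, 3, dilation=dilation, rng=rng)
        self.norm2 = GroupNorm(width, gn_groups)

    def transform(self, x: Tensor) -> Tensor:
        h = self.norm1(self.conv1(x)).relu()
        return self.norm2(self.conv2(h))

    def forward(self, x: Tensor) -> Tensor:
        return x + self.transform(x)


class DRDB(Module):
    """Six-branch dilated residual block.

    Branches 1/3/5 are plain residual branches; branches 2/4/6 are dilated
    residual branches with the dilation sequence (1, 2, 4).  The six outputs
    are concatenated (6 x width channels) and reduced by a 1x1 convolution
    back to ``width``.  A 1x1 projection adapts the input when its channel
    count differs from the branch width.
    """

    def __init__(self, in_channels: int, width: int, gn_groups: int,
                 rng: np.random.Generator, dilations=(1, 2, 4)):
        super().__init__()
        self.width = width
        self.project = (Conv2d(in_channels, width, 1, rng=rng)
                        if in_channels != width else None)
        branches = []
        for d in dilations:
            branches.append(ResidualBranch(width, gn_groups, rng))          # plain
            branches.append(ResidualBranch(width, gn_groups, rng, dilation=d))
        self.branches = branches
        for i, b in enumerate(branches):
            self._children[f"branch{i + 1}"] = b
        self.reduce = Conv2d(6 * width, width, 1, rng=rng)
        self.norm = GroupNorm(width, gn_groups)

    def branch_outputs(self, x: Tensor) -> list[Tensor]:
        if self.project is not None:
            x = self.project(x)
        return [b(x) for b in self.branches]

    def forward(self, x: Tensor) -> Tensor:
        cat = concat(self.branch_outputs(x), axis=1)
        return self.norm(self.reduce(cat)).relu()


class GLFEB(Module):
    """Global/local feature enhancement with a tanh-fused concatenation."""

    def __init__(self, global_channels: int, local_channels: int,
                 widths: tuple, gn_groups: int, rng: np.random.Generator):
        super().__init__()
        w1, w2, c = widths
        self.out_channels = 2 * c
        self.conv1 = Conv2d(local_channels, w1, 3, rng=rng)
        self.norm1 = GroupNorm(w1, gn_groups)
        self.conv2 = Conv2d(w1, w2, 3, rng=rng)
        self.norm2 = GroupNorm(w2, gn_groups)
        self.conv3 = Conv2d(w2, c, 3, rng=rng)
        self.norm3 = GroupNorm(c, gn_groups)
        self.global_proj = Conv2d(global_channels, c, 1, rng=rng)

    def local_path(self, local_feature: Tensor) -> Tensor:
        h = self.norm1(self.conv1(local_feature)).relu()
        h = self.norm2(self.conv2(h)).relu()
        return self.norm3(self.conv3(h)).relu()

    def forward(self, global_feature: Tensor, local_feature: Tensor) -> Tensor:
        out, _ = self.forward_with_local(global_feature, local_feature)
        return out

    def forward_with_local(self, global_feature: Tensor,
                           local_feature: Tensor) -> tuple[Tensor, Tensor]:
        """Return (tanh-fused output, local conv feature used for fusion)."""
        local = self.local_path(local_feature)
        if global_feature.shape[2:] != local.shape[2:]:
            global_feature = bilinear_resize(global_feature,
                                             local.shape[2], local.shape[3])
        g = self.global_proj(global_feature)
        fused = concat([local, g], axis=1)
        return fused.tanh(), local


def global_average_pool(at) -> np.ndarray:
    """Per-channel spatial mean of a (C, H, W) or (N, C, H, W) volume."""
    arr = at.data if isinstance(at, Tensor) else np.asarray(at)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4:
        raise ValueError(f"expected a 3- or 4-axis volume, got shape {arr.shape}")
    if arr.shape[2] == 0 or arr.shape[3] == 0:
        raise ValueError("empty spatial extent")
    out = arr.mean(axis=(2, 3))
    return out[0] if out.shape[0] == 1 else out


class ChannelAttention(Module):
    """Per-channel gate in (0, 1).

    Pipeline: global average pool -> linear (W1) -> ReLU -> two fully
    connected layers (bottleneck of ``channels // reduction``) -> sigmoid.
    With ``dual_pool`` a global max-pool path shares the same weights and
    the two pre-sigmoid logits are summed.
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator,
                 dual_pool: bool = False):
        super().__init__()
        self.channels = channels
        self.dual_pool = dual_pool
        hidden = max(channels // reduction, 1)
        self.lin0 = Linear(channels, channels, rng=rng)   # W1
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.fc2 = Linear(hidden, channels, rng=rng)

    def _mlp(self, v: Tensor) -> Tensor:
        return self.fc2(self.fc1(self.lin0(v).relu()).relu())

    def forward(self, at: Tensor) -> Tensor:
        """(N, C, H, W) -> per-channel weights (N, C)."""
        if at.shape[1] != self.channels:
            raise ValueError(f"attention built for {self.channels} channels, "
                             f"received {at.shape[1]}")
        n, c, h, w = at.shape
        avg = at.mean(axis=(2, 3))
        logits = self._mlp(avg)
        if self.dual_pool:
            mx = at.reshape(n, c, h * w).max_along(axis=2)
            logits = logits + self._mlp(mx)
        return logits.sigmoid()


class SpatialAttention(Module):
    """Per-location gate: 5x5 conv -> ReLU -> normalise to unit sum.

    A map whose post-ReLU response is identically zero cannot be
    sum-normalised; such samples fall back to the uniform map 1/(H*W) and a
    warning is logged.
    """

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(channels, 1, kernel, rng=rng)
        self._warned_dead = False

    def forward(self, at: Tensor) -> Tensor:
        """(N, C, H, W) -> normalised map (N, 1, H, W) summing to 1."""
        n, _, h, w = at.shape
        s = self.conv(at).relu()
        totals = s.data.sum(axis=(1, 2, 3))
        dead = totals == 0.0
        if dead.any():
            # routine once the gate saturates during training: warn once,
            # then demote to debug
            log = logger.debug if self._warned_dead else logger.warning
            self._warned_dead = True
            log("spatial attention: %d all-zero map(s); "
                "falling back to uniform", int(dead.sum()))
            fill = np.where(dead, 1.0, 0.0).astype(np.float32)
            s = s + Tensor(fill.reshape(n, 1, 1, 1) *
                           np.ones((1, 1, h, w), dtype=np.float32))
        denom = s.sum(axis=(1, 2, 3), keepdims=True)
        return s / denom


class CSAB(Module):
    """Channel + spatial attention: at * Qc[c] * Qs[i, j], elementwise."""

    def __init__(self, channels: int, reduction: int, kernel: int,
                 rng: np.random.Generator, dual_pool: bool = False):
        super().__init__()
        self.channel_att = ChannelAttention(channels, reduction, rng,
                                            dual_pool=dual_pool)
        self.spatial_att = SpatialAttention(channels, kernel, rng)

    def forward(self, at: Tensor) -> Tensor:
        n, c, h, w = at.shape
        qc = self.channel_att(at).reshape(n, c, 1, 1)
        qs = self.spatial_att(at)       # (N, 1, H, W)
        return at * qc * qs
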