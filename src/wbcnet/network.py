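"""End-to-end classifier assembly, ablation variants and the residual
reference network used for the parameter-economy comparison.

The full network runs

    image -> stem -> DRDB -> GLFEB(global=stem, local=DRDB) -> CSAB
          -> CSAB + 1x1-projected GLFEB conv feature   (elementwise fusion)
          -> batch norm -> dropout -> 3x3 conv head -> GAP -> linear -> head

Ablation variants drop DRDB, GLFEB and/or CSAB while keeping the stem and
classification head, mirroring the seven-row ablation table.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .autograd import Tensor, log_softmax, no_grad
from .blocks import CSAB, DRDB, GLFEB, ConvStem
from .config import ModelConfig
from .layers import (BatchNorm2d, Conv2d, Dropout, GroupNorm, Linear, Module,
                     ReLU, Sequential, count_parameters)

VARIANTS = (
    "stem",
    "stem+DRDB",
    "stem+DRDB+CSAB",
    "stem+GLFEB",
    "stem+GLFEB+CSAB",
    "stem+DRDB+GLFEB",
    "full",
)


def prepare_images(images: np.ndarray) -> Tensor:
    """(N, H, W, 3) images in [0, 1] -> NCHW float32 tensor."""
    arr = np.asarray(images, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError(f"expected (N, H, W, 3) images, got shape {arr.shape}")
    return Tensor(np.ascontiguousarray(arr.transpose(0, 3, 1, 2)))


class DDRNet(Module):
    """Dilated-residual attention classifier (configurable block set)."""

    def __init__(self, cfg: ModelConfig | None = None, *,
                 use_drdb: bool = True, use_glfeb: bool = True,
                 use_csab: bool = True):
        super().__init__()
        cfg = cfg or ModelConfig()
        self.cfg = cfg
        self.use_drdb = use_drdb
        self.use_glfeb = use_glfeb
        self.use_csab = use_csab
        rng = np.random.default_rng(cfg.seed)
        g = cfg.gn_groups

        self.stem = ConvStem(cfg.input_size[2], cfg.stem_channels, g, rng)
        feat = cfg.stem_channels

        if use_drdb:
            self.drdbs = Sequential(*[
                DRDB(feat if i == 0 else cfg.drdb_branch_width,
                     cfg.drdb_branch_width, g, rng,
                     dilations=cfg.drdb_dilations)
                for i in range(cfg.drdb_depth)])
            feat = cfg.drdb_branch_width

        if use_glfeb:
            self.glfeb = GLFEB(cfg.stem_channels, feat, cfg.glfeb_widths, g, rng)
            skip_channels = cfg.glfeb_widths[2]          # local conv feature
            feat = self.glfeb.out_channels
        else:
            skip_channels = feat

        if use_csab:
            self.csab = CSAB(feat, cfg.attention_fc_reduction, cfg.csab_kernel,
                             rng, dual_pool=cfg.attention_dual_pool)
            self.skip_proj = (Conv2d(skip_channels, feat, 1, rng=rng)
                              if skip_channels != feat else None)

        self.post_norm = BatchNorm2d(feat)
        self.dropout = Dropout(cfg.dropout_rate,
                               rng=np.random.default_rng(cfg.seed + 1))
        self.head_conv = Conv2d(feat, cfg.head_channels, 3, rng=rng)
        self.head_norm = GroupNorm(cfg.head_channels, g)
        self.fc = Linear(cfg.head_channels, cfg.num_classes, rng=rng)

    # -- forward ----------------------------------------------------------
    def forward(self, x: Tensor, collect: dict | None = None) -> Tensor:
        """NCHW tensor -> raw class logits (N, num_classes).

        ``collect``, if given, is filled with named intermediate tensors
        ('stem', 'drdb', 'glfeb', 'csab', 'fusion', 'head_conv') for
        Grad-CAM and feature-map inspection.
        """
        h_in, w_in, c_in = self.cfg.input_size
        if x.shape[1] != c_in or x.shape[2:] != (h_in, w_in):
            raise ValueError(
                f"expected input of shape (N, {c_in}, {h_in}, {w_in}), "
                f"received {tuple(x.shape)}")
        acts = collect if collect is not None else {}

        f_stem = self.stem(x)
        acts["stem"] = f_stem
        feature = f_stem

        if self.use_drdb:
            feature = self.drdbs(feature)
            acts["drdb"] = feature

        skip = feature
        if self.use_glfeb:
            feature, skip = self.glfeb.forward_with_local(f_stem, feature)
            acts["glfeb"] = feature

        if self.use_csab:
            att = self.csab(feature)
            acts["csab"] = att
            s = self.skip_proj(skip) if self.skip_proj is not None else skip
            feature = att + s
        acts["fusion"] = feature

        h = self.dropout(self.post_norm(feature))
        h = self.head_norm(self.head_conv(h)).relu()
        acts["head_conv"] = h
        pooled = h.mean(axis=(2, 3))
        return self.fc(pooled)

    def layer_names(self) -> tuple:
        names = ["stem"]
        if self.use_drdb:
            names.append("drdb")
        if self.use_glfeb:
            names.append("glfeb")
        if self.use_csab:
            names.append("csab")
        names += ["fusion", "head_conv"]
        return tuple(names)

    def predict_logits(self, images: np.ndarray) -> np.ndarray:
        with no_grad():
            return self.forward(prepare_images(images)).data

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Class scores per image: softmax (sums to 1) or per-class sigmoid."""
        logits = self.predict_logits(images)
        if self.cfg.head == "sigmoid":
            from scipy.special import expit
            return expit(logits)
        return np.exp(log_softmax(Tensor(logits), axis=1).data)

    # -- persistence ------------------------------------------------------
    def save_checkpoint(self, path: str | Path) -> None:
        """Weights to ``.npz`` plus a JSON sidecar describing the config."""
        path = Path(path)
        np.savez(path, **self.state_dict())
        sidecar = {"model_config": self.cfg.to_dict(),
                   "blocks": {"use_drdb": self.use_drdb,
                              "use_glfeb": self.use_glfeb,
                              "use_csab": self.use_csab}}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2,
                                                        sort_keys=True))

    @classmethod
    def load_checkpoint(cls, path: str | Path) -> "DDRNet":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        sidecar = json.loads(path.with_suffix(".json").read_text())
        net = cls(ModelConfig.from_dict(sidecar["model_config"]),
                  **sidecar["blocks"])
        with np.load(path) as data:
            net.load_state_dict({k: data[k] for k in data.files})
        return net


def build_variant(name: str, cfg: ModelConfig | None = None) -> DDRNet:
    """Instantiate one of the named ablation variants."""
    if name not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}; valid names: {list(VARIANTS)}")
    parts = set(name.split("+"))
    return DDRNet(cfg,
                  use_drdb="DRDB" in parts or name == "full",
                  use_glfeb="GLFEB" in parts or name == "full",
                  use_csab="CSAB" in parts or name == "full")


# ---------------------------------------------------------------------------
# 18-layer residual reference (parameter-economy baseline)
# ---------------------------------------------------------------------------

class _BasicBlock(Module):
    def __init__(self, cin: int, cout: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(cin, cout, 3, stride=stride,
                            padding=1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, 3, padding=1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.down = Sequential(Conv2d(cin, cout, 1, stride=stride,
                                          padding=0, bias=False, rng=rng),
                                   BatchNorm2d(cout))
        else:
            self.down = None

    def forward(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h))
        s = self.down(x) if self.down is not None else x
        return (h + s).relu()


class ResNet18(Module):
    """Standard 18-layer residual network (2-2-2-2 basic blocks).

    Serves as the like-for-like baseline for the trainable-parameter
    comparison: same input size and class count as the attention model.
    """

    def __init__(self, num_classes: int = 4, in_channels: int = 3, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.conv1 = Conv2d(in_channels, 64, 7, stride=2, padding=3,
                            bias=False, rng=rng)
        self.bn1 = BatchNorm2d(64)
        blocks = []
        cin = 64
        for cout, stride in ((64, 1), (64, 1), (128, 2), (128, 1),
                             (256, 2), (256, 1), (512, 2), (512, 1)):
            blocks.append(_BasicBlock(cin, cout, stride, rng))
            cin = cout
        self.blocks = Sequential(*blocks)
        self.fc = Linear(512, num_classes, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        from .autograd import maxpool2d
        h = self.bn1(self.conv1(x)).relu()
        h = maxpool2d(h, 2)
        h = self.blocks(h)
        return self.fc(h.mean(axis=(2, 3)))


__all__ = ["DDRNet", "ResNet18", "VARIANTS", "build_variant",
           "count_parameters", "prepare_images"]
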