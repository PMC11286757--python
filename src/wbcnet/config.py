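"""Architectural configuration record with YAML round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

CLASS_NAMES = ("eosinophil", "lymphocyte", "monocyte", "neutrophil")


@dataclass
class ModelConfig:
    """Hyperparameters of the dilated-residual attention classifier.

    Defaults are the published recipe: 224x224x3 inputs, a 32-filter 3x3
    stem, a six-branch dilated residual block (dilations 1/2/4), the
    64/128/64 global-local enhancement convolutions, 32 normalisation
    groups, 20% dropout, a 5x5 spatial-attention kernel and a softmax head
    over the four leukocyte classes.
    """

    input_size: tuple = (224, 224, 3)
    stem_channels: int = 32
    drdb_branch_width: int = 64
    drdb_dilations: tuple = (1, 2, 4)
    drdb_depth: int = 1
    glfeb_widths: tuple = (64, 128, 64)
    gn_groups: int = 32
    dropout_rate: float = 0.20
    num_classes: int = 4
    head: str = "softmax"          # "softmax" | "sigmoid"
    head_channels: int = 64
    csab_kernel: int = 5
    attention_fc_reduction: int = 8
    attention_dual_pool: bool = False
    seed: int = 0

    def __post_init__(self):
        self.input_size = tuple(self.input_size)
        self.drdb_dilations = tuple(self.drdb_dilations)
        self.glfeb_widths = tuple(self.glfeb_widths)
        if len(self.drdb_dilations) != 3 or \
                list(self.drdb_dilations) != sorted(set(self.drdb_dilations)):
            raise ValueError("drdb_dilations must be 3 strictly increasing integers, "
                             f"got {self.drdb_dilations}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.num_classes < 2:
            raise ValueError(f"num_classes must be >= 2, got {self.num_classes}")
        if self.head not in ("softmax", "sigmoid"):
            raise ValueError(f"head must be 'softmax' or 'sigmoid', got {self.head!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("input_size", "drdb_dilations", "glfeb_widths"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown ModelConfig fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def reduced_config(canvas: int = 56, **overrides) -> ModelConfig:
    """A width-reduced configuration for desk-scale experiments.

    Same topology as the default model, an order of magnitude fewer
    parameters; suitable for CPU training on the synthetic generator.
    """
    base = dict(
        input_size=(canvas, canvas, 3),
        stem_channels=8,
        drdb_branch_width=8,
        glfeb_widths=(8, 16, 8),
        gn_groups=4,
        head_channels=8,
        attention_fc_reduction=4,
    )
    base.update(overrides)
    return ModelConfig(**base)
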