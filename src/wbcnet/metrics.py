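"""Confusion matrices and one-vs-rest classification metrics.

For class k the K-class confusion matrix is marginalised into binary counts
D (true positives), E (true negatives), F (false positives) and G (false
negatives), from which

    accuracy  = (D + E) / (D + E + F + G)
    precision = D / (D + F)
    recall    = D / (D + G)
    F1        = 2 * precision * recall / (precision + recall)
    MCC       = (D*E - F*G) / sqrt((D+F)(D+G)(E+F)(E+G))

Zero-denominator cases return 0.0 and are flagged rather than raised, so
degenerate splits (a class absent from truth or predictions) stay usable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import CLASS_NAMES


@dataclass
class ConfusionMatrix:
    """K x K count table; rows are true classes, columns predictions."""

    counts: np.ndarray
    class_names: tuple = CLASS_NAMES

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError(f"expected a {k}x{k} count table, "
                             f"got shape {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_predictions(cls, y_true, y_pred,
                         class_names: tuple = CLASS_NAMES) -> "ConfusionMatrix":
        k = len(class_names)
        counts = np.zeros((k, k), dtype=np.int64)
        for t, p in zip(np.asarray(y_true, int), np.asarray(y_pred, int)):
            counts[t, p] += 1
        return cls(counts, class_names)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, k: int) -> tuple[int, int, int, int]:
        """Binary marginals (D, E, F, G) for class ``k``."""
        d = int(self.counts[k, k])
        g = int(self.counts[k].sum() - d)        # false negatives
        f = int(self.counts[:, k].sum() - d)     # false positives
        e = self.total - d - f - g
        return d, e, f, g

    def to_csv(self, path: str | Path) -> None:
        lines = ["true\\pred," + ",".join(self.class_names)]
        for name, row in zip(self.class_names, self.counts):
            lines.append(name + "," + ",".join(str(int(v)) for v in row))
        Path(path).write_text("\n".join(lines) + "\n")


def classification_metrics(cm: ConfusionMatrix, class_k: int
                           ) -> dict[str, float]:
    """One-vs-rest accuracy/precision/recall/F1 for one class.

    Returns a dict with the four metrics plus a ``degenerate`` flag set when
    any denominator was zero (the affected metric is reported as 0.0).
    """
    d, e, f, g = cm.one_vs_rest(class_k)
    degenerate = False

    def _ratio(num, den):
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    accuracy = _ratio(d + e, d + e + f + g)
    precision = _ratio(d, d + f)
    recall = _ratio(d, d + g)
    f1 = _ratio(2 * precision * recall, precision + recall) \
        if (precision + recall) > 0 else 0.0
    if (precision + recall) == 0:
        degenerate = True
    return {"accuracy": accuracy, "precision": precision, "recall": recall,
            "f1": f1, "degenerate": degenerate}


def matthews_cc(cm: ConfusionMatrix, class_k: int) -> float:
    """One-vs-rest Matthews correlation coefficient; 0.0 when undefined."""
    d, e, f, g = cm.one_vs_rest(class_k)
    denom = (d + f) * (d + g) * (e + f) * (e + g)
    if denom == 0:
        return 0.0
    return (d * e - f * g) / math.sqrt(denom)


@dataclass
class MetricsReport:
    """Per-class metrics, macro averages and overall accuracy."""

    per_class: dict = field(default_factory=dict)
    overall_accuracy: float = 0.0
    macro: dict = field(default_factory=dict)

    @classmethod
    def from_confusion(cls, cm: ConfusionMatrix) -> "MetricsReport":
        per_class = {}
        for k, name in enumerate(cm.class_names):
            m = classification_metrics(cm, k)
            m["mcc"] = matthews_cc(cm, k)
            per_class[name] = m
        macro = {key: float(np.mean([per_class[n][key]
                                     for n in cm.class_names]))
                 for key in ("precision", "recall", "f1", "mcc")}
        overall = float(np.trace(cm.counts) / cm.total) if cm.total else 0.0
        return cls(per_class=per_class, overall_accuracy=overall, macro=macro)

    def to_dict(self) -> dict:
        return {"overall_accuracy": self.overall_accuracy,
                "macro": self.macro, "per_class": self.per_class}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2,
                                         sort_keys=True))
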