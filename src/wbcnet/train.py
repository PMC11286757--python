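"""Training loop (Adam, constant learning rate), evaluation and the
block-ablation harness.

The published recipe is the default: Adam with learning rate 0.01 held
constant, 30 epochs, 20% dropout (owned by the model config), minibatches
of 32.  Training is seeded end to end in deterministic mode — shuffling,
dropout masks and weight initialisation all derive from the config seed, so
two runs with the same seed produce bit-identical histories.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .autograd import Tensor, cross_entropy, no_grad
from .config import ModelConfig
from .data import LabeledImageSet
from .layers import Module
from .metrics import ConfusionMatrix, MetricsReport
from .network import DDRNet, VARIANTS, build_variant, count_parameters, \
    prepare_images

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 0.01
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0
    deterministic_mode: bool = True

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        d = yaml.safe_load(Path(path).read_text())
        unknown = set(d) - {f.name for f in fields(cls)}
        if unknown:
            raise ValueError(f"unknown TrainConfig fields: {sorted(unknown)}")
        return cls(**d)


@dataclass
class TrainHistory:
    """Per-epoch curves plus the global iteration counter."""

    train_loss: list = field(default_factory=list)
    train_acc: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_acc: list = field(default_factory=list)
    iterations: int = 0

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["epoch", "train_loss", "train_acc",
                         "val_loss", "val_acc"])
            for i in range(len(self.train_loss)):
                wr.writerow([i + 1, self.train_loss[i], self.train_acc[i],
                             self.val_loss[i], self.val_acc[i]])


class Adam:
    """Adam optimizer over a module's trainable parameters."""

    def __init__(self, params: list[Tensor], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _epoch_pass(net: Module, images: np.ndarray, labels: np.ndarray,
                batch_size: int, opt: Adam | None, epoch: int):
    """One pass over the data; returns (mean loss, accuracy, n_batches)."""
    n = len(labels)
    total_loss = 0.0
    correct = 0
    n_batches = 0
    for start in range(0, n, batch_size):
        idx = slice(start, min(start + batch_size, n))
        xb = prepare_images(images[idx])
        yb = labels[idx]
        if opt is None:
            with no_grad():
                logits = net.forward(xb)
                loss = cross_entropy(logits, yb)
        else:
            logits = net.forward(xb)
            loss = cross_entropy(logits, yb)
        lval = float(loss.data)
        if not np.isfinite(lval):
            raise RuntimeError(
                f"non-finite loss at epoch {epoch}, iteration {n_batches}: "
                f"{lval}")
        if opt is not None:
            net.zero_grad()
            loss.backward()
            opt.step()
        total_loss += lval * (idx.stop - idx.start)
        correct += int((logits.data.argmax(axis=1) == yb).sum())
        n_batches += 1
    return total_loss / n, correct / n, n_batches


def train_model(net: DDRNet, data: LabeledImageSet, cfg: TrainConfig
                ) -> tuple[dict, TrainHistory]:
    """Train on the set's train split; returns (best weights, history).

    The best checkpoint maximises validation accuracy (ties broken by lower
    validation loss).  Without a val split the train metrics drive both the
    val columns of the history and checkpoint selection.
    """
    if data.split is not None:
        train = data.subset("train")
        val = data.subset("val")
        if len(val) == 0:
            val = None
    else:
        train, val = data, None
    if len(train) == 0:
        raise ValueError("training split is empty")

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.trainable_parameters(), cfg.learning_rate)
    hist = TrainHistory()
    best = (-1.0, np.inf, None)                     # (acc, loss, state)
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(train))
        net.train()
        tl, ta, nb = _epoch_pass(net, train.images[order],
                                 train.labels[order], cfg.batch_size,
                                 opt, epoch)
        hist.iterations += nb
        net.eval()
        if val is not None:
            vl, va, _ = _epoch_pass(net, val.images, val.labels,
                                    cfg.batch_size, None, epoch)
        else:
            vl, va = tl, ta
        hist.train_loss.append(tl)
        hist.train_acc.append(ta)
        hist.val_loss.append(vl)
        hist.val_acc.append(va)
        if va > best[0] or (va == best[0] and vl < best[1]):
            best = (va, vl, net.state_dict())
        logger.info("epoch %d/%d loss=%.4f acc=%.3f val_loss=%.4f val_acc=%.3f",
                    epoch, cfg.epochs, tl, ta, vl, va)
    net.load_state_dict(best[2])
    return best[2], hist


def prediction_scores(net: DDRNet, images: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Class scores and argmax labels (ties break to the lowest index)."""
    net.eval()
    scores = []
    for start in range(0, len(images), 64):
        scores.append(net.predict_proba(images[start:start + 64]))
    scores = np.concatenate(scores)
    return scores, scores.argmax(axis=1)


def evaluate_model(net: DDRNet, data: LabeledImageSet, split: str | None = None
                   ) -> tuple[ConfusionMatrix, MetricsReport]:
    """Confusion matrix + metrics over a split (or the whole set)."""
    sub = data.subset(split) if split is not None else data
    if len(sub) == 0:
        raise ValueError(f"split {split!r} is empty")
    _, pred = prediction_scores(net, sub.images)
    cm = ConfusionMatrix.from_predictions(sub.labels, pred, sub.class_names)
    return cm, MetricsReport.from_confusion(cm)


def run_ablation(data: LabeledImageSet, variants: list[str], cfg: TrainConfig,
                 model_cfg: ModelConfig | None = None) -> list[dict]:
    """Train/evaluate each block variant on identical splits and seeds.

    Returns one row per variant: name, parameter count, final train
    accuracy and test accuracy.
    """
    for v in variants:
        if v not in VARIANTS:
            raise ValueError(f"unknown variant {v!r}; valid names: "
                             f"{list(VARIANTS)}")
    rows = []
    for v in variants:
        net = build_variant(v, model_cfg)
        _, hist = train_model(net, data, cfg)
        cm, report = evaluate_model(net, data, "test")
        rows.append({"variant": v,
                     "parameters": count_parameters(net),
                     "train_accuracy": hist.train_acc[-1],
                     "test_accuracy": report.overall_accuracy})
        logger.info("ablation %s: params=%d train=%.3f test=%.3f",
                    v, rows[-1]["parameters"], rows[-1]["train_accuracy"],
                    rows[-1]["test_accuracy"])
    return rows


def ablation_to_csv(rows: list[dict], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        wr = csv.DictWriter(fh, fieldnames=["variant", "parameters",
                                            "train_accuracy", "test_accuracy"])
        wr.writeheader()
        wr.writerows(rows)


def ablation_from_csv(path: str | Path) -> list[dict]:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    for r in rows:
        r["parameters"] = int(r["parameters"])
        r["train_accuracy"] = float(r["train_accuracy"])
        r["test_accuracy"] = float(r["test_accuracy"])
    return rows
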