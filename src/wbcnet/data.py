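"""Labeled image sets: loading from directory trees, resizing, stratified
train/val/test splitting, and manifest export.

Images are held as a single (N, H, W, 3) float32 array with values in
[0, 1]; labels are integer indices into ``class_names``.  The expected disk
layout is one subdirectory per class containing JPEG/PNG files.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .config import CLASS_NAMES

logger = logging.getLogger(__name__)

SPLITS = ("train", "val", "test")


def resize_bilinear(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resize with half-pixel centers; aspect is not preserved."""
    h, w = img.shape[:2]
    if (h, w) == (out_h, out_w):
        return img.astype(np.float32, copy=True)
    ry = np.clip((np.arange(out_h) + 0.5) * h / out_h - 0.5, 0, h - 1)
    rx = np.clip((np.arange(out_w) + 0.5) * w / out_w - 0.5, 0, w - 1)
    y0 = np.floor(ry).astype(int)
    x0 = np.floor(rx).astype(int)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    wy = (ry - y0)[:, None, None]
    wx = (rx - x0)[None, :, None]
    img = img.astype(np.float32)
    if img.ndim == 2:
        img = img[:, :, None]
    out = (img[y0[:, None], x0[None, :]] * (1 - wy) * (1 - wx)
           + img[y0[:, None], x1[None, :]] * (1 - wy) * wx
           + img[y1[:, None], x0[None, :]] * wy * (1 - wx)
           + img[y1[:, None], x1[None, :]] * wy * wx)
    return out.astype(np.float32)


@dataclass
class LabeledImageSet:
    """Images + labels (+ optional split tags, provenance and metadata)."""

    images: np.ndarray                        # (N, H, W, 3) float32, [0, 1]
    labels: np.ndarray                        # (N,) int
    class_names: tuple = CLASS_NAMES
    split: np.ndarray | None = None           # (N,) of {train, val, test}
    provenance: np.ndarray | None = None      # (N,) of {original, augmented}
    meta: list | None = None                  # per-image dicts (e.g. bbox)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels length mismatch: "
                             f"{len(self.images)} vs {len(self.labels)}")
        if self.labels.size and not np.isin(
                self.labels, np.arange(len(self.class_names))).all():
            raise ValueError("labels outside the declared class set")
        if self.provenance is None:
            self.provenance = np.array(["original"] * len(self.labels))
        if self.split is not None:
            self.split = np.asarray(self.split)

    def __len__(self) -> int:
        return len(self.labels)

    def class_counts(self) -> dict[str, int]:
        return {name: int((self.labels == k).sum())
                for k, name in enumerate(self.class_names)}

    def select(self, idx) -> "LabeledImageSet":
        idx = np.asarray(idx)
        return LabeledImageSet(
            self.images[idx], self.labels[idx], self.class_names,
            None if self.split is None else self.split[idx],
            self.provenance[idx],
            None if self.meta is None else [self.meta[i] for i in idx])

    def subset(self, split_tag: str) -> "LabeledImageSet":
        if self.split is None:
            raise ValueError("no split assigned; call split_train_test first")
        return self.select(np.where(self.split == split_tag)[0])

    # -- disk round trip --------------------------------------------------
    def to_directory(self, root: str | Path, fmt: str = "png") -> Path:
        """Write a directory-per-class tree plus a manifest.csv."""
        root = Path(root)
        rows = []
        for i in range(len(self)):
            cname = self.class_names[self.labels[i]]
            cdir = root / cname
            cdir.mkdir(parents=True, exist_ok=True)
            fname = f"{cname}_{i:05d}.{fmt}"
            arr = np.clip(self.images[i] * 255.0 + 0.5, 0, 255).astype(np.uint8)
            iio.imwrite(cdir / fname, arr)
            rows.append((f"{cname}/{fname}", cname,
                         "" if self.split is None else str(self.split[i]),
                         str(self.provenance[i])))
        with open(root / "manifest.csv", "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["path", "label", "split", "provenance"])
            wr.writerows(rows)
        return root


def load_image_dataset(root_dir: str | Path,
                       class_subdirs: dict[str, str] | None = None,
                       target_size: int = 224) -> LabeledImageSet:
    """Load a directory-per-class image tree.

    Every decodable JPEG/PNG is resized (bilinear, aspect ignored) to
    ``target_size`` square, scaled to [0, 1]; grayscale files are replicated
    to three channels, alpha channels dropped.  Undecodable files are
    skipped with a warning; a class directory without a single usable image
    is an error.
    """
    root = Path(root_dir)
    if class_subdirs is None:
        class_subdirs = {d.name: d.name for d in sorted(root.iterdir())
                         if d.is_dir()}
    class_names = tuple(sorted(class_subdirs))
    images, labels = [], []
    skipped = 0
    for k, cname in enumerate(class_names):
        cdir = root / class_subdirs[cname]
        n_before = len(images)
        for f in sorted(cdir.iterdir()):
            if f.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                continue
            try:
                arr = iio.imread(f)
            except Exception:  # undecodable file
                logger.warning("skipping undecodable image %s", f)
                skipped += 1
                continue
            arr = np.asarray(arr)
            if arr.ndim == 2:                      # grayscale -> 3 channels
                arr = np.repeat(arr[:, :, None], 3, axis=2)
            if arr.shape[2] == 4:                  # drop alpha
                arr = arr[:, :, :3]
            arr = arr.astype(np.float32) / 255.0
            images.append(resize_bilinear(arr, target_size, target_size))
            labels.append(k)
        n_loaded = len(images) - n_before
        if n_loaded == 0:
            raise ValueError(f"class {cname!r} has no decodable images in {cdir}")
        logger.info("class %s: %d images", cname, n_loaded)
    if skipped:
        logger.warning("skipped %d undecodable file(s)", skipped)
    return LabeledImageSet(np.stack(images), np.array(labels),
                           class_names=class_names)


def split_train_test(data: LabeledImageSet, train_frac: float = 0.8,
                     val_frac: float = 0.0, seed: int = 0) -> LabeledImageSet:
    """Stratified split into train/(val)/test, deterministic under ``seed``.

    Per class, round(train_frac * n) images go to the training split (an
    optional ``val_frac`` of the whole is carved from it) and the remainder
    to test.  Classes with fewer than 2 images are rejected.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError(f"train_frac must be in (0, 1), got {train_frac}")
    rng = np.random.default_rng(seed)
    split = np.empty(len(data), dtype=object)
    for k, name in enumerate(data.class_names):
        idx = np.where(data.labels == k)[0]
        if len(idx) < 2:
            raise ValueError(f"class {name!r} has {len(idx)} image(s); "
                             "need at least 2 to split")
        idx = rng.permutation(idx)
        n_train = int(round(train_frac * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)   # both splits non-empty
        n_val = int(round(val_frac * len(idx)))
        n_val = min(n_val, n_train - 1) if n_val >= n_train else n_val
        split[idx[:n_train - n_val]] = "train"
        split[idx[n_train - n_val:n_train]] = "val"
        split[idx[n_train:]] = "test"
    return LabeledImageSet(data.images, data.labels, data.class_names,
                           split.astype(str), data.provenance, data.meta)
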