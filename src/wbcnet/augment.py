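"""Augmentation transforms and class-balancing expansion.

The four transforms of the training recipe: horizontal flip, small-angle
rotation (10 degrees by default, clockwise), zoom (scale 2 by default) and
random mean-anchored contrast stretching.  ``balance_augment`` expands each
class to a common target count by composing these transforms on the
originals — never by cropping — and avoids emitting duplicate images until
the achievable transform set is exhausted.

All transforms act on (H, W, 3) float arrays with values in [0, 1];
coordinates are 0-based (row, col).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .data import LabeledImageSet

logger = logging.getLogger(__name__)


@dataclass
class AugmentationSpec:
    """Which transforms are enabled and with what parameters.

    A transform is disabled by its neutral value: ``rotation_deg=0``,
    ``zoom_scale=1`` or ``contrast_range=(1, 1)``.
    """

    flip_enabled: bool = True
    rotation_deg: float = 10.0
    zoom_scale: float = 2.0
    contrast_range: tuple = (0.7, 1.3)
    seed: int = 0

    def __post_init__(self):
        if not np.isfinite(self.rotation_deg):
            raise ValueError("rotation_deg must be finite")
        if self.zoom_scale <= 0:
            raise ValueError(f"zoom_scale must be positive, got {self.zoom_scale}")
        low, high = self.contrast_range
        if not (0 < low <= 1 <= high):
            raise ValueError("contrast_range must satisfy 0 < low <= 1 <= high, "
                             f"got {self.contrast_range}")


def flip_horizontal(img: np.ndarray) -> np.ndarray:
    """Mirror about the vertical axis: out[i, j] = in[i, W-1-j]."""
    if img.size == 0:
        raise ValueError("empty image")
    return np.ascontiguousarray(img[:, ::-1])


def rotate_image(img: np.ndarray, theta_deg: float,
                 anchor: str = "center") -> np.ndarray:
    """Rotate image content clockwise by ``theta_deg``.

    The canvas size is preserved, samples falling outside it are filled
    with 0, interpolation is bilinear.  ``anchor='center'`` (default)
    rotates about the image center; ``anchor='origin'`` about pixel (0, 0),
    matching the bare coordinate-rotation formula.
    """
    if theta_deg == 0.0:
        return img.astype(np.float32, copy=True)
    t = np.deg2rad(theta_deg)
    # content moves clockwise: offset (r, 0) from the anchor lands at
    # (r cos t, -r sin t); affine_transform needs the inverse map.
    minv = np.array([[np.cos(t), -np.sin(t)],
                     [np.sin(t), np.cos(t)]])
    if anchor == "center":
        c = (np.asarray(img.shape[:2]) - 1) / 2.0
        offset = c - minv @ c
    elif anchor == "origin":
        offset = np.zeros(2)
    else:
        raise ValueError(f"anchor must be 'center' or 'origin', got {anchor!r}")
    out = np.empty_like(img, dtype=np.float32)
    for ch in range(img.shape[2]):
        out[:, :, ch] = ndimage.affine_transform(
            img[:, :, ch].astype(np.float32), minv, offset=offset,
            order=1, mode="constant", cval=0.0)
    return out


def zoom_image(img: np.ndarray, scale: float,
               anchor: str = "center") -> np.ndarray:
    """Magnify by ``scale`` on a fixed canvas.

    ``anchor='origin'`` implements the printed index form
    out[m, n] = in[floor(m/scale), floor(n/scale)] (nearest neighbour,
    top-left anchored); ``anchor='center'`` magnifies about the image
    center with bilinear interpolation, keeping the cell framed.
    """
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    if scale == 1.0:
        return img.astype(np.float32, copy=True)
    h, w = img.shape[:2]
    if anchor == "origin":
        rows = np.minimum((np.arange(h) / scale).astype(int), h - 1)
        cols = np.minimum((np.arange(w) / scale).astype(int), w - 1)
        return img[rows[:, None], cols[None, :]].astype(np.float32)
    if anchor != "center":
        raise ValueError(f"anchor must be 'center' or 'origin', got {anchor!r}")
    c = (np.asarray(img.shape[:2]) - 1) / 2.0
    minv = np.eye(2) / scale
    offset = c - minv @ c
    out = np.empty_like(img, dtype=np.float32)
    for ch in range(img.shape[2]):
        out[:, :, ch] = ndimage.affine_transform(
            img[:, :, ch].astype(np.float32), minv, offset=offset,
            order=1, mode="constant", cval=0.0)
    return out


def random_contrast(img: np.ndarray, spec: AugmentationSpec,
                    rng: np.random.Generator) -> np.ndarray:
    """Mean-anchored linear contrast stretch with a random factor.

    out = clip((in - mean) * f + mean, 0, 1), f ~ U(contrast_range); the
    per-image mean is preserved before clipping.
    """
    f = rng.uniform(*spec.contrast_range)
    m = img.mean()
    return np.clip((img - m) * f + m, 0.0, 1.0).astype(np.float32)


def _sample_pipeline(spec: AugmentationSpec, rng: np.random.Generator):
    """Random composition over the enabled transform set (never empty)."""
    enabled = []
    if spec.flip_enabled:
        enabled.append("flip")
    if spec.rotation_deg != 0.0:
        enabled.append("rotate")
    if spec.zoom_scale != 1.0:
        enabled.append("zoom")
    if spec.contrast_range != (1.0, 1.0):
        enabled.append("contrast")
    if not enabled:
        raise ValueError("no augmentation transform enabled")
    while True:
        chosen = [t for t in enabled if rng.random() < 0.5]
        if chosen:
            break
    sign = 1.0 if rng.random() < 0.5 else -1.0

    def apply(img):
        out = img
        if "flip" in chosen:
            out = flip_horizontal(out)
        if "rotate" in chosen:
            out = rotate_image(out, sign * spec.rotation_deg)
        if "zoom" in chosen:
            out = zoom_image(out, spec.zoom_scale)
        if "contrast" in chosen:
            out = random_contrast(out, spec, rng)
        return out

    return apply


def balance_augment(data: LabeledImageSet, target_per_class: int,
                    spec: AugmentationSpec) -> LabeledImageSet:
    """Expand every class to exactly ``target_per_class`` images.

    All originals are retained; synthesized images are transform
    compositions of originals.  Candidates duplicating an already-emitted
    image (byte-wise) are rejected and resampled until a retry budget is
    exhausted, so small transform groups are enumerated before any
    duplicate appears.  Deterministic under ``spec.seed``.
    """
    counts = data.class_counts()
    over = {n: c for n, c in counts.items() if c > target_per_class}
    if over:
        raise ValueError(
            f"target_per_class={target_per_class} is below original class "
            f"counts {over}; originals are never discarded")
    if min(counts.values()) == 0:
        raise ValueError("every class must be non-empty")
    rng = np.random.default_rng(spec.seed)
    images = [data.images]
    labels = [data.labels]
    prov = [np.asarray(data.provenance)]
    seen = {im.tobytes() for im in data.images}
    for k, name in enumerate(data.class_names):
        src = data.images[data.labels == k]
        need = target_per_class - len(src)
        new = []
        while len(new) < need:
            for _ in range(20):                      # duplicate retry budget
                img = src[rng.integers(len(src))]
                cand = _sample_pipeline(spec, rng)(img).astype(np.float32)
                key = cand.tobytes()
                if key not in seen:
                    break
            else:
                logger.info("class %s: transform set exhausted, "
                            "accepting a duplicate", name)
            seen.add(key)
            new.append(cand)
        if new:
            images.append(np.stack(new))
            labels.append(np.full(len(new), k, dtype=np.int64))
            prov.append(np.array(["augmented"] * len(new)))
    split = None
    if data.split is not None:
        tags = set(np.unique(data.split))
        if len(tags) > 1:
            raise ValueError("balance_augment must be applied within a single "
                             f"split, got tags {sorted(tags)}")
        total = sum(len(x) for x in labels)
        split = np.full(total, next(iter(tags)))
    return LabeledImageSet(np.concatenate(images), np.concatenate(labels),
                           data.class_names, split, np.concatenate(prov))
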