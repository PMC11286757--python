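"""Grad-CAM heatmaps and intermediate feature-map visualisation.

Grad-CAM in its canonical form: the gradient of the target class score with
respect to a named convolutional stage is spatially averaged into
per-channel weights, the weighted activation sum is rectified, bilinearly
upsampled to the input resolution and max-normalised to [0, 1].  The
heatmap localises the image regions that drove the class score — on blood
smears, ideally the cell body and its nuclear morphology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import resize_bilinear
from .autograd import no_grad
from .network import DDRNet, prepare_images


@dataclass
class CamHeatmap:
    """Non-negative localization map aligned with the input image."""

    values: np.ndarray            # (H, W), in [0, 1] when nonzero
    target_class: int
    source_layer: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if (self.values < 0).any():
            raise ValueError("heatmap entries must be non-negative")

    def argmax_location(self) -> tuple[int, int]:
        r, c = np.unravel_index(int(self.values.argmax()), self.values.shape)
        return int(r), int(c)


def grad_cam(net: DDRNet, image: np.ndarray, target_class: int | None = None,
             layer: str = "head_conv") -> CamHeatmap:
    """Grad-CAM heatmap of ``target_class`` (default: predicted class).

    ``layer`` names a stage recorded by the network's forward pass
    (``net.layer_names()``); the default is the final convolution after the
    attention fusion.
    """
    if layer not in net.layer_names():
        raise ValueError(f"unknown layer {layer!r}; available layers: "
                         f"{list(net.layer_names())}")
    net.eval()
    acts: dict = {}
    x = prepare_images(image[None] if image.ndim == 3 else image)
    logits = net.forward(x, collect=acts)
    if target_class is None:
        target_class = int(logits.data[0].argmax())
    score = logits[0, int(target_class)]
    score.backward()
    act = acts[layer]
    h_in, w_in = net.cfg.input_size[0], net.cfg.input_size[1]
    if act.grad is None:
        # no gradient path from the class score to this layer
        return CamHeatmap(np.zeros((h_in, w_in), dtype=np.float32),
                          int(target_class), layer)
    weights = act.grad[0].mean(axis=(1, 2))                 # (C,)
    cam = np.maximum((weights[:, None, None] * act.data[0]).sum(axis=0), 0.0)
    cam = resize_bilinear(cam[:, :, None], h_in, w_in)[:, :, 0]
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return CamHeatmap(cam.astype(np.float32), int(target_class), layer)


def feature_map_grid(net: DDRNet, image: np.ndarray, layer: str = "stem",
                     max_maps: int = 64) -> np.ndarray:
    """Tile per-channel activations of ``layer`` into one grayscale image.

    Each channel is independently min-max scaled to [0, 1] (a constant
    channel becomes uniform gray); at most ``max_maps`` tiles are arranged
    in a near-square grid separated by 1-pixel borders.
    """
    if layer not in net.layer_names():
        raise ValueError(f"unknown layer {layer!r}; available layers: "
                         f"{list(net.layer_names())}")
    net.eval()
    acts: dict = {}
    with no_grad():
        net.forward(prepare_images(image[None] if image.ndim == 3 else image),
                    collect=acts)
    maps = acts[layer].data[0][:max_maps]                   # (C, h, w)
    tiles = []
    for ch in maps:
        lo, hi = ch.min(), ch.max()
        tiles.append((ch - lo) / (hi - lo) if hi > lo
                     else np.full_like(ch, 0.5))
    n = len(tiles)
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    h, w = tiles[0].shape
    grid = np.zeros((rows * (h + 1) - 1, cols * (w + 1) - 1), dtype=np.float32)
    for i, t in enumerate(tiles):
        r, c = divmod(i, cols)
        grid[r * (h + 1):r * (h + 1) + h, c * (w + 1):c * (w + 1) + w] = t
    return grid


def overlay_heatmap(image: np.ndarray, cam: CamHeatmap,
                    alpha: float = 0.45) -> np.ndarray:
    """Blend a jet-colormapped heatmap over the input image (both HxWx3)."""
    from matplotlib import cm as mpl_cm
    colored = mpl_cm.jet(cam.values)[:, :, :3].astype(np.float32)
    return np.clip((1 - alpha) * image + alpha * colored, 0, 1)
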