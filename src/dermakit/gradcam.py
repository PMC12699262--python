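"""Grad-CAM hotspot tracing.

For a trained classifier the class-activation map at a spatial layer is

    w_c = spatial mean of d(score_class) / d(A_c),     cam = ReLU(sum_c w_c A_c),

min-max normalized to [0, 1] (all-zero raw maps stay zero) and bilinearly
upsampled to the input patch size.  The gradient is taken on the pre-softmax
class logit by default; a loss-gradient mode is available, as is tapping the
first convolutional layer instead of the default last spatial layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize

from .classify import FoldModel
from .images import as_rgb
from .nn import Conv2d, Sequential, softmax
from .sampling import Patch

__all__ = ["Heatmap", "gradcam", "class_contrast_cam", "overlay", "hotspot_summary"]


@dataclass
class Heatmap:
    values: np.ndarray       # [0, 1], spatial shape of the input patch
    target_class: int
    target_layer: int
    raw_min: float
    raw_max: float


def _resolve_layer(net: Sequential, target_layer) -> int:
    if isinstance(target_layer, int):
        return target_layer
    if target_layer in (None, "last_spatial"):
        spatial = [i for i, a in enumerate(net.activations) if a.ndim == 4]
        if not spatial:
            raise ValueError("network has no spatial activations")
        return spatial[-1]
    if target_layer == "first_conv":
        for i, layer in enumerate(net.layers):
            if isinstance(layer, Conv2d):
                return i
        raise ValueError("network has no convolutional layer")
    raise ValueError(f"unknown target layer {target_layer!r}")


def gradcam(model, patch, target_class: int, target_layer=None, mode: str = "logit") -> Heatmap:
    """Class-activation heatmap for one patch.

    ``model`` is a :class:`~dermakit.classify.FoldModel` (patch pixels are
    preprocessed as in training) or a bare :class:`~dermakit.nn.Sequential`
    (then ``patch`` must already be an NCHW input array).
    """
    if isinstance(model, FoldModel):
        net = model.net
        pixels = patch.pixels if isinstance(patch, Patch) else np.asarray(patch)
        x = model.prepare(pixels)
        out_shape = pixels.shape[:2]
    else:
        net = model
        x = np.asarray(patch, dtype=np.float64)
        if x.ndim != 4:
            raise ValueError("with a bare network, patch must be an NCHW array")
        out_shape = x.shape[2:]

    logits = net.forward(x, train=False)
    n_classes = logits.shape[1]
    if not (0 <= target_class < n_classes):
        raise ValueError(f"invalid class {target_class} for {n_classes}-way model")
    tl = _resolve_layer(net, target_layer)
    act = net.activations[tl]
    if act.ndim != 4:
        raise ValueError(f"layer {tl} has no spatial activations")

    if mode == "logit":
        g = np.zeros_like(logits)
        g[0, target_class] = 1.0
    elif mode == "loss":
        g = softmax(logits, axis=1)
        g[0, target_class] -= 1.0
    else:
        raise ValueError("mode must be 'logit' or 'loss'")

    grad = net.backward(g, upto=tl + 1)       # gradient w.r.t. layer tl's output
    weights = grad.mean(axis=(2, 3))          # (1, C)
    cam = np.maximum((weights[0][:, None, None] * act[0]).sum(axis=0), 0.0)
    raw_min, raw_max = float(cam.min()), float(cam.max())
    if raw_max - raw_min < 1e-12:
        norm = np.zeros_like(cam)
    else:
        norm = (cam - raw_min) / (raw_max - raw_min)
    if norm.shape != tuple(out_shape):
        norm = resize(norm, out_shape, order=1, anti_aliasing=False)
        norm = np.clip(norm, 0.0, 1.0)
    return Heatmap(values=norm, target_class=target_class, target_layer=tl, raw_min=raw_min, raw_max=raw_max)


def class_contrast_cam(model: FoldModel, patch, class_a: int = 0, class_b: int = 1, target_layer=None) -> Heatmap:
    """Class-contrast activation map: ``|sum_c w_c A_c|`` where the channel
    weights come from the gradient of the *logit difference* between two
    classes.

    Unlike the single-class map, no ReLU is applied: evidence pushing toward
    either class counts, so the map marks the regions that are informative
    for the decision regardless of direction.  This is the robust choice for
    hotspot localization analyses on binary models, where the sign of the
    discriminative projection is an arbitrary outcome of training.
    """
    net = model.net
    pixels = patch.pixels if isinstance(patch, Patch) else np.asarray(patch)
    x = model.prepare(pixels)
    logits = net.forward(x, train=False)
    n_classes = logits.shape[1]
    if not (0 <= class_a < n_classes and 0 <= class_b < n_classes and class_a != class_b):
        raise ValueError("need two distinct valid class indices")
    tl = _resolve_layer(net, target_layer)
    act = net.activations[tl]
    g = np.zeros_like(logits)
    g[0, class_a] = 1.0
    g[0, class_b] = -1.0
    grad = net.backward(g, upto=tl + 1)
    weights = grad.mean(axis=(2, 3))
    cam = np.abs((weights[0][:, None, None] * act[0]).sum(axis=0))
    raw_min, raw_max = float(cam.min()), float(cam.max())
    if raw_max - raw_min < 1e-12:
        norm = np.zeros_like(cam)
    else:
        norm = (cam - raw_min) / (raw_max - raw_min)
    out_shape = pixels.shape[:2]
    if norm.shape != tuple(out_shape):
        norm = np.clip(resize(norm, out_shape, order=1, anti_aliasing=False), 0.0, 1.0)
    return Heatmap(values=norm, target_class=class_a, target_layer=tl, raw_min=raw_min, raw_max=raw_max)


def overlay(patch, heatmap: Heatmap, colormap: str = "jet", alpha: float = 0.4) -> np.ndarray:
    """Blend a blue-to-red rendering of the heatmap over the patch."""
    from matplotlib import colormaps

    pixels = as_rgb(patch.pixels if isinstance(patch, Patch) else patch)
    if heatmap.values.shape != pixels.shape[:2]:
        raise ValueError("heatmap and patch shapes differ")
    cmap = colormaps[colormap]
    colored = cmap(heatmap.values)[..., :3] * 255.0
    out = (1.0 - alpha) * pixels.astype(np.float64) + alpha * colored
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def hotspot_summary(heatmaps: list, masks: list) -> pd.DataFrame:
    """Per-patch mean heat inside vs outside the epidermis mask.

    Rows with an empty mask or empty complement are flagged and excluded from
    the cohort mean ratio (last row, patch == 'cohort_mean')."""
    rows = []
    ratios = []
    for i, (hm, mask) in enumerate(zip(heatmaps, masks)):
        mask = np.asarray(mask) > 0
        vals = hm.values if isinstance(hm, Heatmap) else np.asarray(hm)
        flagged = not mask.any() or mask.all()
        inside = float(vals[mask].mean()) if mask.any() else np.nan
        outside = float(vals[~mask].mean()) if not mask.all() else np.nan
        if flagged or outside == 0.0:
            ratio = np.inf if (not flagged and inside > 0) else np.nan
            flagged = True
        else:
            ratio = inside / outside
            ratios.append(ratio)
        rows.append({"patch": i, "inside_mean": inside, "outside_mean": outside, "ratio": ratio, "flagged": flagged})
    cohort = float(np.mean(ratios)) if ratios else np.nan
    rows.append({"patch": "cohort_mean", "inside_mean": np.nan, "outside_mean": np.nan, "ratio": cohort, "flagged": False})
    return pd.DataFrame(rows)
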