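"""Unsupervised epidermis extraction.

The segmenter labels pixels without any annotation by alternating between a
small convolutional network and a superpixel consistency constraint:
Felzenszwalb superpixels group visually similar pixels, the network's argmax
labels are replaced by the majority label within each superpixel, and the
cross-entropy between the network's scores and those refined labels is
backpropagated.  Iterating shrinks the number of distinct clusters until it
reaches a floor (default 3 — the minimum able to separate corneum, epidermis
and dermis) or the iteration cap.

The epidermis cluster is then picked by a stain-and-shape heuristic (mean
hematoxylin OD times the elongation of the largest component — the epidermis
is the nucleus-dense, band-shaped cluster), cleaned up by morphological
opening plus small-component removal, and accepted only if one connected
component spans a raster diagonal (which rejects follicle/gland/vessel
blobs).  Accepted masks yield a level-1 crop with the epidermis oriented
diagonally.

How the epidermis cluster is identified among the unsupervised clusters is
this package's heuristic; it can be overridden with an explicit cluster id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology, segmentation as skseg, transform

from .images import as_mask, as_rgb, optical_density, HEMATOXYLIN_OD
from .nn import SGD, build_pixel_net, softmax_cross_entropy
from .sampling import mask_principal_angle

__all__ = [
    "SegConfig", "SuperpixelMap", "EpidermisMaskResult", "NoEpidermisError",
    "compute_superpixels", "iterative_unsupervised_segment", "select_epidermis_cluster",
    "diagonal_span_filter", "refine_mask", "extract_level1", "segment_epidermis",
]


class NoEpidermisError(ValueError):
    """Clustering produced no separable epidermis cluster."""


@dataclass
class SuperpixelMap:
    labels: np.ndarray
    n_segments: int


@dataclass
class SegConfig:
    felzenszwalb_scale: float = 100.0
    felzenszwalb_sigma: float = 0.8
    felzenszwalb_min_size: int = 50
    n_channels: int = 100
    n_conv_blocks: int = 3
    max_iterations: int = 100
    min_clusters: int = 3
    learning_rate: float = 0.1
    seed: int = 0
    # cleanup / level-1 extraction
    kernel_radius: int = 3
    min_component_area: int = 256
    corner_tol_frac: float = 0.15
    rotate_threshold_deg: float = 20.0
    auto_rotate: bool = True
    crop_margin: int = 16
    max_bbox_fill: float = 0.6   # band-likeness: mask fraction of its bounding box

    def __post_init__(self):
        if min(self.n_channels, self.n_conv_blocks, self.max_iterations, self.min_clusters) < 1:
            raise ValueError("all counts must be >= 1")


@dataclass
class EpidermisMaskResult:
    mask: np.ndarray
    cluster_id: int
    accepted: bool = False
    level1_image: np.ndarray | None = None
    level1_mask: np.ndarray | None = None


def compute_superpixels(image: np.ndarray, config: SegConfig | None = None) -> SuperpixelMap:
    """Felzenszwalb graph-based superpixels with contiguous relabeling."""
    config = config or SegConfig()
    image = as_rgb(image)
    labels = skseg.felzenszwalb(
        image,
        scale=config.felzenszwalb_scale,
        sigma=config.felzenszwalb_sigma,
        min_size=config.felzenszwalb_min_size,
    )
    _, labels = np.unique(labels, return_inverse=True)
    labels = labels.reshape(image.shape[:2])
    return SuperpixelMap(labels=labels, n_segments=int(labels.max()) + 1)


def _majority_vote(labels_flat: np.ndarray, seg_flat: np.ndarray, n_segments: int) -> np.ndarray:
    """Replace each pixel's label by the majority label of its superpixel."""
    refined = labels_flat.copy()
    order = np.argsort(seg_flat, kind="stable")
    sorted_seg = seg_flat[order]
    bounds = np.searchsorted(sorted_seg, np.arange(n_segments + 1))
    for s in range(n_segments):
        idx = order[bounds[s] : bounds[s + 1]]
        if len(idx) == 0:
            continue
        maj = np.bincount(labels_flat[idx]).argmax()
        refined[idx] = maj
    return refined


def iterative_unsupervised_segment(
    image: np.ndarray, superpixels: SuperpixelMap, config: SegConfig | None = None
) -> np.ndarray:
    """Superpixel-guided iterative self-labeling; returns the per-pixel
    argmax label raster of the trained network."""
    config = config or SegConfig()
    image = as_rgb(image)
    h, w = image.shape[:2]
    if superpixels.labels.shape != (h, w):
        raise ValueError("superpixels must partition the image")

    rng = np.random.default_rng(config.seed)
    net = build_pixel_net(config.n_channels, config.n_conv_blocks, rng=rng)
    opt = SGD(net.params(), config.learning_rate)

    x = (image.astype(np.float64) / 255.0 - 0.5).transpose(2, 0, 1)[None]
    seg_flat = superpixels.labels.ravel()

    n_distinct = config.n_channels
    for _ in range(config.max_iterations):
        logits = net.forward(x, train=True)                       # (1, K, H, W)
        flat = logits[0].reshape(config.n_channels, h * w).T      # (H*W, K)
        labels_flat = flat.argmax(axis=1)
        refined = _majority_vote(labels_flat, seg_flat, superpixels.n_segments)
        loss, g = softmax_cross_entropy(flat, refined)
        opt.zero_grad()
        net.backward(g.T.reshape(1, config.n_channels, h, w))
        opt.step()
        n_distinct = len(np.unique(refined))
        if n_distinct <= config.min_clusters:
            break

    logits = net.forward(x, train=True)
    labels_flat = logits[0].reshape(config.n_channels, h * w).T.argmax(axis=1)
    final = _majority_vote(labels_flat, seg_flat, superpixels.n_segments).reshape(h, w)
    if len(np.unique(final)) == 1:
        warnings.warn("segmentation collapsed to a single cluster")
    return final


def _largest_component_stats(mask: np.ndarray):
    """(elongation, size) of the mask's largest connected component."""
    lab, n = ndi.label(mask)
    if n == 0:
        return 0.0, 0
    sizes = ndi.sum_labels(mask, lab, index=np.arange(1, n + 1))
    biggest = 1 + int(np.argmax(sizes))
    props = measure.regionprops((lab == biggest).astype(int))[0]
    minor = max(props.axis_minor_length, 1.0)
    return float(props.axis_major_length / minor), int(sizes[biggest - 1])


def select_epidermis_cluster(
    labels: np.ndarray, image: np.ndarray, cluster_id: int | None = None, min_component_area: int = 256
) -> EpidermisMaskResult:
    """Pick the epidermis cluster: highest (mean hematoxylin OD) x (elongation
    of the largest component), among clusters whose largest component reaches
    ``min_component_area`` (a cluster too small to survive refinement — e.g.
    scattered nucleus pixels — cannot be the epidermis band).  Ties break
    toward the lower cluster id; an explicit ``cluster_id`` bypasses the
    heuristic."""
    image = as_rgb(image)
    ids = np.unique(labels)
    if cluster_id is not None:
        return EpidermisMaskResult(mask=labels == cluster_id, cluster_id=int(cluster_id))
    if len(ids) < 2:
        raise NoEpidermisError("single cluster: nothing to select an epidermis from")
    h_od = optical_density(image) @ HEMATOXYLIN_OD
    scored = []
    for cid in ids:   # ids ascending -> strict '>' gives lower-id tie-break
        m = labels == cid
        elong, big = _largest_component_stats(m)
        scored.append((int(cid), float(h_od[m].mean()) * elong, big))
    eligible = [t for t in scored if t[2] >= min_component_area] or scored
    best_id, best_score = None, -np.inf
    for cid, score, _ in eligible:
        if score > best_score:
            best_id, best_score = cid, score
    return EpidermisMaskResult(mask=labels == best_id, cluster_id=best_id)


def diagonal_span_filter(mask: np.ndarray, tolerance_frac: float = 0.15) -> bool:
    """True iff one connected component touches both corner regions (squares
    of side ``tolerance_frac * min(H, W)``) of either raster diagonal."""
    mask = as_mask(mask)
    h, w = mask.shape
    s = max(1, int(round(tolerance_frac * min(h, w))))
    corners = {
        "tl": (slice(0, s), slice(0, s)),
        "br": (slice(h - s, h), slice(w - s, w)),
        "tr": (slice(0, s), slice(w - s, w)),
        "bl": (slice(h - s, h), slice(0, s)),
    }
    lab, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    for i in range(1, n + 1):
        comp = lab == i
        hits = {k: comp[v].any() for k, v in corners.items()}
        if (hits["tl"] and hits["br"]) or (hits["tr"] and hits["bl"]):
            return True
    return False


def refine_mask(mask: np.ndarray, kernel_radius: int = 3, min_component_area: int = 256) -> np.ndarray:
    """Corrosion–expansion cleanup: morphological opening with a disk, then
    removal of small connected components."""
    mask = as_mask(mask)
    out = morphology.opening(mask, morphology.disk(kernel_radius))
    lab, n = ndi.label(out, structure=np.ones((3, 3), dtype=int))
    if n:
        sizes = ndi.sum_labels(out, lab, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_component_area) + 1
        out = np.isin(lab, keep)
    if not out.any():
        warnings.warn("mask is empty after refinement")
    return out


def extract_level1(image: np.ndarray, mask: np.ndarray, config: SegConfig | None = None, cluster_id: int = -1) -> EpidermisMaskResult:
    """Orient the epidermis along the raster diagonal and crop around it.

    When the mask's principal axis deviates more than ``rotate_threshold_deg``
    from a diagonal, image and mask are rotated to align it; the diagonal-span
    filter then decides acceptance, and accepted masks are cropped to their
    padded bounding box."""
    config = config or SegConfig()
    image = as_rgb(image)
    mask = as_mask(mask)
    if not mask.any():
        return EpidermisMaskResult(mask=mask, cluster_id=cluster_id, accepted=False)

    ang = mask_principal_angle(mask)
    dev = min(min(abs(ang - d), 180 - abs(ang - d)) for d in (45.0, -45.0))
    if config.auto_rotate and dev > config.rotate_threshold_deg:
        target = 45.0 if abs(ang - 45.0) <= abs(ang + 45.0) else -45.0
        delta = ang - target   # rotate(delta) maps principal angle ang -> ang - delta
        imf = transform.rotate(image.astype(np.float64) / 255.0, delta, resize=True, mode="constant", cval=1.0, order=1)
        image = np.clip(np.rint(imf * 255.0), 0, 255).astype(np.uint8)
        mask = transform.rotate(mask.astype(float), delta, resize=True, mode="constant", cval=0.0, order=0) > 0.5

    if not mask.any():
        return EpidermisMaskResult(mask=mask, cluster_id=cluster_id, accepted=False)
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    # the span test runs on the tight bounding box: a diagonally oriented band
    # reaches both corner regions of its own box; follicle/gland blobs do not
    tight = mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    # compact structures (follicles, glands, vessels) fill most of their box;
    # a diagonal band fills little of it — both tests must pass
    fill = float(tight.mean())
    accepted = fill <= config.max_bbox_fill and diagonal_span_filter(tight, config.corner_tol_frac)
    m = config.crop_margin
    r0, r1 = max(0, rows[0] - m), min(mask.shape[0], rows[-1] + 1 + m)
    c0, c1 = max(0, cols[0] - m), min(mask.shape[1], cols[-1] + 1 + m)
    crop_mask = mask[r0:r1, c0:c1]
    return EpidermisMaskResult(
        mask=mask,
        cluster_id=cluster_id,
        accepted=accepted,
        level1_image=image[r0:r1, c0:c1] if accepted else None,
        level1_mask=crop_mask if accepted else None,
    )


def segment_epidermis(image: np.ndarray, config: SegConfig | None = None, cluster_id: int | None = None) -> EpidermisMaskResult:
    """Full pipeline: superpixels -> iterative labeling -> cluster selection
    -> refinement -> diagonal orientation and level-1 crop."""
    config = config or SegConfig()
    sp = compute_superpixels(image, config)
    labels = iterative_unsupervised_segment(image, sp, config)
    sel = select_epidermis_cluster(labels, image, cluster_id, min_component_area=config.min_component_area)
    refined = refine_mask(sel.mask, config.kernel_radius, config.min_component_area)
    return extract_level1(image, refined, config, cluster_id=sel.cluster_id)
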