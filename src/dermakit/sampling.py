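"""Epidermis-guided hierarchical patch sampling.

Level-2 patches (default 512x512) are cropped along the traced epidermis
mask of a level-1 image; level-3 patches (default 128x128) are cropped
within a level-2 patch along the EB-side mask boundary — the epidermis–dermis
junction where the basement membrane zone (BMZ) lies.  An inclusion filter
keeps only level-2 patches that show both epidermis and dermis with the band
running diagonally across the patch, so every retained patch composites
dermis, BMZ, epidermis and corneum in a consistent layout.

Coordinates are (row, col), 0-based; a crop of size *s* centred at (r, c)
covers the half-open window ``[r - s//2, r - s//2 + s)`` in each axis.
Sampling is fully deterministic: identical inputs give identical patch lists.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

from .images import as_mask, as_rgb

__all__ = ["Patch", "SamplerConfig", "trace_mask_path", "sample_level2", "bmz_inclusion_filter", "sample_level3", "mask_principal_angle"]


@dataclass
class Patch:
    """A square crop with provenance back to its parent raster."""

    pixels: np.ndarray
    mask_crop: np.ndarray
    level: int
    center: tuple  # (row, col) in parent coordinates
    parent_id: str
    wsi_id: str

    def __post_init__(self):
        self.pixels = as_rgb(self.pixels)
        self.mask_crop = as_mask(self.mask_crop)
        if self.pixels.shape[:2] != self.mask_crop.shape:
            raise ValueError("pixels and mask_crop shapes differ")
        if self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("patches are square")
        if self.level not in (2, 3):
            raise ValueError("level must be 2 or 3")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    @property
    def patch_id(self) -> str:
        r, c = self.center
        return f"{self.parent_id}|L{self.level}@{int(r)},{int(c)}"


@dataclass
class SamplerConfig:
    level2_size: int = 512
    level3_size: int = 128
    stride2: int | None = None    # defaults to level2_size (non-overlapping)
    stride3: int | None = None    # defaults to level3_size
    bmz_filter_on: bool = True
    diag_angle_tol_deg: float = 25.0
    min_mask_frac: float = 0.1

    def __post_init__(self):
        if self.stride2 is None:
            self.stride2 = self.level2_size
        if self.stride3 is None:
            self.stride3 = self.level3_size
        if self.stride2 < 1 or self.stride3 < 1:
            raise ValueError("strides must be >= 1")


# ---------------------------------------------------------------------------
# Path tracing


def _largest_skeleton_component(mask: np.ndarray) -> np.ndarray:
    skel = morphology.skeletonize(mask)
    if not skel.any():
        return skel
    lab, n = ndi.label(skel, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = ndi.sum_labels(skel, lab, index=np.arange(1, n + 1))
        skel = lab == (1 + int(np.argmax(sizes)))
    return skel


def _bfs_farthest(start, pix: set):
    """Unweighted BFS over 8-connected pixels; returns farthest node + parents."""
    parents = {start: None}
    q = deque([start])
    last = start
    while q:
        p = q.popleft()
        last = p
        r, c = p
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                nxt = (r + dr, c + dc)
                if nxt in pix and nxt not in parents:
                    parents[nxt] = p
                    q.append(nxt)
    return last, parents


def trace_mask_path(mask: np.ndarray) -> list:
    """Longest path through the mask skeleton, as ordered (row, col) pixels.

    The skeleton's graph diameter is approximated by a double breadth-first
    sweep.  Ordering is deterministic: the path starts at the endpoint with
    the lexicographically smaller (row, col).
    """
    mask = as_mask(mask)
    if not mask.any():
        return []
    skel = _largest_skeleton_component(mask)
    if not skel.any():
        return []
    pix = set(map(tuple, np.argwhere(skel)))
    start = min(pix)
    a, _ = _bfs_farthest(start, pix)
    b, parents = _bfs_farthest(a, pix)
    path = []
    node = b
    while node is not None:
        path.append(node)
        node = parents[node]
    if path[0] > path[-1]:
        path.reverse()
    return path


def _arc_positions(path) -> np.ndarray:
    pts = np.asarray(path, dtype=np.float64)
    if len(pts) < 2:
        return np.zeros(len(pts))
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(steps)])


def _crop_fits(center, size: int, shape) -> bool:
    r, c = int(center[0]), int(center[1])
    r0, c0 = r - size // 2, c - size // 2
    return r0 >= 0 and c0 >= 0 and r0 + size <= shape[0] and c0 + size <= shape[1]


def _pick_centers(path, stride: int, size: int, shape, img_center) -> list:
    """Centers every ``stride`` arc steps, shifted along the path to fit.

    A center whose crop would cross the raster border is moved to the nearest
    path point whose crop fits (ties broken toward the raster center), which
    keeps every center on the mask.  Duplicates after shifting are dropped.
    """
    if not path:
        return []
    arcs = _arc_positions(path)
    total = arcs[-1]
    if total < stride:
        targets = [total / 2.0]
    else:
        targets = list(np.arange(0.0, total + 1e-9, stride))
    valid = [i for i in range(len(path)) if _crop_fits(path[i], size, shape)]
    if not valid:
        return []
    valid_arr = np.asarray(valid)
    centers, seen = [], set()
    for t in targets:
        idx = int(np.searchsorted(arcs, t, side="left"))
        idx = min(idx, len(path) - 1)
        if not _crop_fits(path[idx], size, shape):
            dist = np.abs(valid_arr - idx)
            best = valid_arr[dist == dist.min()]
            if len(best) > 1:
                dc = [np.hypot(path[i][0] - img_center[0], path[i][1] - img_center[1]) for i in best]
                idx = int(best[int(np.argmin(dc))])
            else:
                idx = int(best[0])
        c = path[idx]
        if c not in seen:
            seen.add(c)
            centers.append(c)
    return centers


def _crop(image, mask, center, size):
    r0 = int(center[0]) - size // 2
    c0 = int(center[1]) - size // 2
    return (
        image[r0 : r0 + size, c0 : c0 + size],
        mask[r0 : r0 + size, c0 : c0 + size],
    )


def sample_level2(level1: np.ndarray, mask: np.ndarray, config: SamplerConfig | None = None, wsi_id: str = "wsi") -> list:
    """512x512 (default) patches centred on the traced epidermis path."""
    config = config or SamplerConfig()
    level1 = as_rgb(level1)
    mask = as_mask(mask)
    path = trace_mask_path(mask)
    if not path:
        return []
    shape = mask.shape
    centers = _pick_centers(path, config.stride2, config.level2_size, shape, (shape[0] / 2, shape[1] / 2))
    patches = []
    for ctr in centers:
        px, mc = _crop(level1, mask, ctr, config.level2_size)
        patches.append(Patch(px, mc, level=2, center=ctr, parent_id=wsi_id, wsi_id=wsi_id))
    return patches


def mask_principal_angle(mask: np.ndarray) -> float:
    """Principal-axis angle of mask pixels, degrees in (-90, 90].

    0 deg means the long axis runs along columns (horizontal band); +/-45 deg
    are the two raster diagonals.
    """
    coords = np.argwhere(as_mask(mask)).astype(np.float64)
    if len(coords) < 2:
        return 0.0
    coords -= coords.mean(axis=0)
    cov = coords.T @ coords / len(coords)
    # orientation of the dominant eigenvector in the (row, col) plane
    mu20, mu02, mu11 = cov[0, 0], cov[1, 1], cov[0, 1]
    theta = 0.5 * np.arctan2(2 * mu11, mu02 - mu20)  # from the column axis
    ang = np.rad2deg(theta)
    if ang <= -90:
        ang += 180
    elif ang > 90:
        ang -= 180
    return float(ang)


def _angle_to_diagonal(angle_deg: float) -> float:
    return min(
        min(abs(angle_deg - d), 180 - abs(angle_deg - d)) for d in (45.0, -45.0)
    )


def bmz_inclusion_filter(patch: Patch, config: SamplerConfig | None = None) -> bool:
    """True iff the patch shows both epidermis and dermis with the band
    crossing the patch roughly diagonally — i.e. it contains the BMZ in the
    canonical orientation."""
    config = config or SamplerConfig()
    frac = float(patch.mask_crop.mean())
    if not (config.min_mask_frac <= frac <= 1.0 - config.min_mask_frac):
        return False
    ang = mask_principal_angle(patch.mask_crop)
    return _angle_to_diagonal(ang) <= config.diag_angle_tol_deg


def _eb_side_path(patch: Patch) -> list:
    """Sampling path for level-3 crops: the EB-side boundary of the mask crop
    (the epidermis–dermis junction), falling back to the skeleton midline when
    the crop's boundary cannot be split into two sides."""
    from .morphometrics import TopologyError, extract_boundaries

    try:
        eb, _ = extract_boundaries(patch.mask_crop, patch.pixels)
        pts = np.rint(eb.points).astype(int)
        # snap sub-pixel contour points onto mask pixels
        snapped = []
        h, w = patch.mask_crop.shape
        for r, c in pts:
            best = None
            for dr in (0, -1, 1):
                for dc in (0, -1, 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and patch.mask_crop[rr, cc]:
                        best = (rr, cc)
                        break
                if best:
                    break
            if best and (not snapped or snapped[-1] != best):
                snapped.append(best)
        if len(snapped) >= 2:
            return snapped
    except TopologyError:
        pass
    return trace_mask_path(patch.mask_crop)


def sample_level3(patch: Patch, config: SamplerConfig | None = None) -> list:
    """128x128 (default) BMZ-detail patches along the EB side of a level-2 patch."""
    config = config or SamplerConfig()
    if patch.level != 2:
        raise ValueError("level-3 sampling starts from a level-2 patch")
    if config.bmz_filter_on and not bmz_inclusion_filter(patch, config):
        warnings.warn("level-2 patch fails the BMZ inclusion filter; no level-3 patches")
        return []
    path = _eb_side_path(patch)
    if not path:
        return []
    shape = patch.mask_crop.shape
    centers = _pick_centers(path, config.stride3, config.level3_size, shape, (shape[0] / 2, shape[1] / 2))
    out = []
    for ctr in centers:
        px, mc = _crop(patch.pixels, patch.mask_crop, ctr, config.level3_size)
        out.append(Patch(px, mc, level=3, center=ctr, parent_id=patch.patch_id, wsi_id=patch.wsi_id))
    return out
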