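"""Epidermal morphometrics: thickness and rete ridge score.

Two boundaries delimit the epidermis band:

* **EB** — the epidermis–dermis boundary (the basal side, carrying the rete
  ridges);
* **ES** — the epidermis–stratum-corneum boundary (the superficial side).

From points sampled along the boundaries the two statistics are

.. math::

    \\mathrm{thickness} = \\mathrm{mean}_i\\, d(ES_i, EB), \\qquad
    \\mathrm{rete\\ ridge\\ score} = \\mathrm{var}_j\\, d(EB_j, ES),

where :math:`d(p, L)` is the shortest Euclidean distance from point *p* to
polyline *L* (point-to-segment, not point-to-vertex).  Rete ridges are the
downward undulations of the epidermis into the dermis; they flatten with
aging, which lowers the variance of the EB-to-ES distances while the mean
ES-to-EB distance tracks overall epidermal thinning.  Both statistics are in
pixel units (pixels and pixels² respectively).

Boundary points are resampled at 1-px arc-length steps before the distance
computations, so the index sets are uniform along each boundary.  The score
uses the population variance (divisor *n*).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology

from .images import as_mask, optical_density, HEMATOXYLIN_OD

__all__ = [
    "BoundaryPolyline",
    "MorphometricResult",
    "TopologyError",
    "extract_boundaries",
    "shortest_distance",
    "compute_morphometrics",
    "resample_polyline",
]


class TopologyError(ValueError):
    """Mask boundary cannot be split into two opposite sides (blob topology)."""


@dataclass
class BoundaryPolyline:
    """Ordered sub-pixel path of (row, col) points along one epidermis side.

    ``role`` is ``"EB"`` (epidermis–dermis) or ``"ES"`` (epidermis–corneum).
    """

    points: np.ndarray  # (n, 2) float array of (row, col)
    role: str = "EB"

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if self.points.shape[1] != 2:
            raise ValueError("polyline points must be (n, 2) (row, col) pairs")
        if len(self.points) < 2:
            raise ValueError("polyline needs at least 2 points")
        if self.role not in ("EB", "ES"):
            raise ValueError("role must be 'EB' or 'ES'")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def arc_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    def resampled(self, step: float = 1.0) -> "BoundaryPolyline":
        return BoundaryPolyline(resample_polyline(self.points, step), role=self.role)

    def transformed(self, rotation_deg: float = 0.0, center=(0.0, 0.0), shift=(0.0, 0.0)) -> "BoundaryPolyline":
        """Rigid motion: rotate about ``center`` then translate by ``shift``."""
        th = np.deg2rad(rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        c = np.asarray(center, dtype=np.float64)
        pts = (self.points - c) @ rot.T + c + np.asarray(shift, dtype=np.float64)
        return BoundaryPolyline(pts, role=self.role)


@dataclass
class MorphometricResult:
    thickness: float          # pixels
    rete_ridge_score: float   # pixels^2
    m: int                    # number of ES sample points
    n: int                    # number of EB sample points
    es_to_eb: np.ndarray = field(repr=False)  # per-ES-point distances
    eb_to_es: np.ndarray = field(repr=False)  # per-EB-point distances


def resample_polyline(points: np.ndarray, step: float = 1.0) -> np.ndarray:
    """Resample a polyline at uniform arc-length steps (endpoints kept)."""
    pts = np.asarray(points, dtype=np.float64)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return pts[:1].repeat(2, axis=0)
    # epsilon guards the floor at exact-integer arc lengths, so rigid motion
    # (which perturbs the computed total by fp rounding) cannot change the count
    n_steps = max(int(np.floor(total / step + 1e-9)), 1)
    targets = np.linspace(0.0, total, n_steps + 1)
    rows = np.interp(targets, s, pts[:, 0])
    cols = np.interp(targets, s, pts[:, 1])
    return np.column_stack([rows, cols])


def _point_segment_distances(points: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Min distance from each point to any segment of the target polyline.

    Vectorised over points x segments; memory is kept bounded by chunking the
    point set.
    """
    p = np.atleast_2d(np.asarray(points, dtype=np.float64))
    a = np.asarray(target, dtype=np.float64)[:-1]   # (s, 2) segment starts
    b = np.asarray(target, dtype=np.float64)[1:]    # (s, 2) segment ends
    ab = b - a
    ab2 = np.einsum("ij,ij->i", ab, ab)
    ab2 = np.where(ab2 == 0, 1.0, ab2)  # degenerate segments behave as points
    out = np.empty(len(p))
    chunk = max(1, int(4e6 / max(len(a), 1)))
    for i in range(0, len(p), chunk):
        pc = p[i : i + chunk]
        ap = pc[:, None, :] - a[None, :, :]                      # (c, s, 2)
        t = np.clip(np.einsum("csj,sj->cs", ap, ab) / ab2, 0.0, 1.0)
        closest = a[None, :, :] + t[..., None] * ab[None, :, :]
        d = np.linalg.norm(pc[:, None, :] - closest, axis=2)
        out[i : i + chunk] = d.min(axis=1)
    return out


def shortest_distance(point, target: BoundaryPolyline) -> float:
    """Shortest Euclidean distance from a (row, col) point to the polyline."""
    return float(_point_segment_distances(np.asarray(point, dtype=np.float64)[None, :], target.points)[0])


def compute_morphometrics(eb: BoundaryPolyline, es: BoundaryPolyline, resample_step: float = 1.0) -> MorphometricResult:
    """Thickness (mean ES→EB shortest distance) and rete ridge score
    (population variance of EB→ES shortest distances).

    The definition is deliberately asymmetric: swapping the arguments changes
    both statistics, because ridge undulation lives on EB.
    """
    if len(eb) < 2 or len(es) < 2:
        raise ValueError("insufficient boundary: each polyline needs >= 2 points")
    eb_r = eb.resampled(resample_step)
    es_r = es.resampled(resample_step)
    es_to_eb = _point_segment_distances(es_r.points, eb_r.points)
    eb_to_es = _point_segment_distances(eb_r.points, es_r.points)
    return MorphometricResult(
        thickness=float(np.mean(es_to_eb)),
        rete_ridge_score=float(np.var(eb_to_es)),
        m=len(es_to_eb),
        n=len(eb_to_es),
        es_to_eb=es_to_eb,
        eb_to_es=eb_to_es,
    )


# ---------------------------------------------------------------------------
# Boundary extraction from a mask


def _longest_contour(mask: np.ndarray) -> np.ndarray:
    # pad so masks touching the raster border still yield one closed contour
    padded = np.pad(mask, 1)
    contours = measure.find_contours(padded.astype(float), 0.5)
    if not contours:
        raise TopologyError("mask has no boundary contour")
    return max(contours, key=len) - 1.0


def _mean_h_od_outside(side: np.ndarray, mask: np.ndarray, image: np.ndarray, band: int = 10) -> float:
    """Mean hematoxylin OD in the exterior band adjacent to one boundary side."""
    h, w = mask.shape
    sel = np.zeros_like(mask, dtype=bool)
    rr = np.clip(np.rint(side[:, 0]).astype(int), 0, h - 1)
    cc = np.clip(np.rint(side[:, 1]).astype(int), 0, w - 1)
    sel[rr, cc] = True
    sel = ndi.binary_dilation(sel, structure=morphology.disk(band))
    sel &= ~mask
    if not sel.any():
        return 0.0
    od = optical_density(image)
    return float(np.mean(od[sel] @ HEMATOXYLIN_OD))


def _circular_runs(keep: np.ndarray) -> list:
    """Index runs of consecutive True values on a circular sequence."""
    n = len(keep)
    if keep.all():
        return [np.arange(n)]
    if not keep.any():
        return []
    # rotate so the sequence starts on a False element, then split
    start = int(np.argmin(keep))
    order = np.arange(start, start + n) % n
    rotated = keep[order]
    runs, current = [], []
    for pos, flag in zip(order, rotated):
        if flag:
            current.append(pos)
        elif current:
            runs.append(np.array(current))
            current = []
    if current:
        runs.append(np.array(current))
    return runs


def _band_half_width(mask: np.ndarray) -> float:
    dist = ndi.distance_transform_edt(mask)
    skel = morphology.skeletonize(mask)
    if skel.any():
        return float(np.median(dist[skel]))
    return float(dist.max())


def extract_boundaries(mask: np.ndarray, image: np.ndarray | None = None, resample_step: float = 1.0):
    """Split the mask boundary into the EB and ES polylines.

    Every boundary-contour point is projected onto the nearest point of the
    skeleton path; points projecting near the path's ends (the short end caps
    of the band) are discarded, and the two longest remaining contour runs
    are the band's two long sides.  Role assignment: with an image, the side
    whose adjacent exterior band (10 px) carries the higher mean hematoxylin
    OD is EB (the dermis side stains darker than the corneum); without an
    image, the more undulating side (greater arc length per unit chord) is
    EB, since the rete ridges live on the dermal side.

    Raises :class:`TopologyError` for blob-like masks without two sides.
    """
    from scipy.spatial import cKDTree

    from .sampling import trace_mask_path

    mask = as_mask(mask)
    if not mask.any():
        raise TopologyError("empty mask")
    contour = _longest_contour(mask)
    path = trace_mask_path(mask)
    if len(path) < 4:
        raise TopologyError("mask skeleton too short to define two sides")
    perim = len(contour)
    if len(path) < 0.1 * perim:
        raise TopologyError("mask boundary does not form two opposite sides")

    half_w = _band_half_width(mask)
    k_end = int(np.ceil(half_w)) + 2
    if len(path) <= 2 * k_end + 2:
        raise TopologyError("mask too short relative to its width")
    _, idx = cKDTree(np.asarray(path, dtype=np.float64)).query(contour)
    keep = (idx >= k_end) & (idx < len(path) - k_end)
    sides = _circular_runs(keep)
    if len(sides) < 2:
        raise TopologyError("mask boundary does not form two opposite sides")
    sides = sorted(sides, key=len, reverse=True)[:2]
    # clip both sides to the common along-path interval: otherwise one side
    # can extend past the other's trimmed end and the overhanging points
    # measure distances to a truncated counterpart, inflating the statistics
    lo = max(idx[run].min() for run in sides)
    hi = min(idx[run].max() for run in sides)
    sides = [run[(idx[run] >= lo) & (idx[run] <= hi)] for run in sides]
    if min(len(run) for run in sides) < 2:
        raise TopologyError("mask boundary does not form two opposite sides")
    side_a, side_b = (contour[run] for run in sides)
    if min(len(side_a), len(side_b)) < 0.1 * perim:
        raise TopologyError("mask boundary does not form two opposite sides")

    if image is not None:
        score_a = _mean_h_od_outside(side_a, mask, image)
        score_b = _mean_h_od_outside(side_b, mask, image)
        if abs(score_a - score_b) < 1e-6:
            image = None  # indistinguishable staining: fall back to undulation
    if image is None:
        def undulation(side):
            chord = np.linalg.norm(side[-1] - side[0])
            arc = np.sum(np.linalg.norm(np.diff(side, axis=0), axis=1))
            return arc / max(chord, 1.0)
        score_a, score_b = undulation(side_a), undulation(side_b)

    if score_a >= score_b:
        eb_pts, es_pts = side_a, side_b
    else:
        eb_pts, es_pts = side_b, side_a
    eb = BoundaryPolyline(resample_polyline(eb_pts, resample_step), role="EB")
    es = BoundaryPolyline(resample_polyline(es_pts, resample_step), role="ES")
    return eb, es


def morphometrics_from_mask(mask: np.ndarray, image: np.ndarray | None = None, resample_step: float = 1.0) -> MorphometricResult:
    """Convenience: extract boundaries from a mask and compute both statistics."""
    eb, es = extract_boundaries(mask, image, resample_step)
    return compute_morphometrics(eb, es, resample_step)
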