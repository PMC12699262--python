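"""Macenko stain normalization.

H&E color variation between slides is removed by expressing each pixel's
optical density (OD) as a non-negative mixture of two stain vectors
(hematoxylin and eosin), estimated per image from the extreme angles of the
OD point cloud inside its dominant plane, then re-rendering the image through
a reference stain basis.

Conventions: ``OD = -log10((I + 1) / 256)`` (the +1 avoids log(0));
transparency threshold ``beta = 0.15`` OD; angle percentile ``alpha = 1``
(1st/99th).  Background pixels (every channel below ``beta``) bypass
normalization so white regions never acquire a stain tint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .images import as_rgb, optical_density

__all__ = ["StainModel", "DegenerateImageError", "estimate_stains", "normalize_to_reference"]

I0 = 256.0


class DegenerateImageError(ValueError):
    """Too few stained pixels, or a rank-deficient (single-stain) OD cloud."""


@dataclass
class StainModel:
    """Two unit-norm stain vectors (columns, hematoxylin first) in OD space
    plus per-stain robust (99th percentile) maximum concentrations."""

    stain_matrix: np.ndarray       # (3, 2), column unit norm, entries >= 0
    max_concentrations: np.ndarray  # (2,), positive

    def __post_init__(self):
        self.stain_matrix = np.asarray(self.stain_matrix, dtype=np.float64)
        self.max_concentrations = np.asarray(self.max_concentrations, dtype=np.float64)
        if self.stain_matrix.shape != (3, 2):
            raise ValueError("stain_matrix must be 3x2")
        norms = np.linalg.norm(self.stain_matrix, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain columns must have unit norm")
        if (self.stain_matrix < -1e-9).any():
            raise ValueError("stain OD entries must be non-negative")

    def to_json(self) -> str:
        return json.dumps({
            "stain_matrix": self.stain_matrix.tolist(),
            "max_concentrations": self.max_concentrations.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "StainModel":
        d = json.loads(text)
        return cls(np.array(d["stain_matrix"]), np.array(d["max_concentrations"]))


def _tissue_od(image: np.ndarray, od_threshold: float):
    od = optical_density(image).reshape(-1, 3)
    tissue = ~np.any(od < od_threshold, axis=1)
    return od, tissue


def estimate_stains(
    image: np.ndarray,
    od_threshold: float = 0.15,
    angle_percentile: float = 1.0,
    min_tissue_pixels: int = 50,
) -> StainModel:
    """Estimate the two-stain basis of an H&E image (Macenko method).

    Raises :class:`DegenerateImageError` on near-blank images or when the OD
    cloud is effectively one-dimensional (single stain).
    """
    image = as_rgb(image)
    od, tissue = _tissue_od(image, od_threshold)
    x = od[tissue]
    if len(x) < min_tissue_pixels:
        raise DegenerateImageError(
            f"only {len(x)} pixels above {od_threshold} OD (< {min_tissue_pixels}); image is near-blank"
        )

    cov = np.cov(x, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] < 1e-3 * evals[2]:
        raise DegenerateImageError("rank-1 OD cloud: image carries a single stain")
    plane = evecs[:, [2, 1]]                       # two largest-variance directions
    plane *= np.where(plane.sum(axis=0) < 0, -1.0, 1.0)

    proj = x @ plane
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo = np.percentile(phi, angle_percentile)
    hi = np.percentile(phi, 100.0 - angle_percentile)
    if abs(hi - lo) < 1e-4:
        raise DegenerateImageError("extreme-angle stain vectors collapse: single-stain OD cloud")
    v1 = plane @ np.array([np.cos(lo), np.sin(lo)])
    v2 = plane @ np.array([np.cos(hi), np.sin(hi)])

    def unit_nonneg(v):
        v = np.clip(v, 0.0, None)
        n = np.linalg.norm(v)
        if n < 1e-8:
            raise DegenerateImageError("estimated stain vector degenerate after clipping")
        return v / n

    v1, v2 = unit_nonneg(v1), unit_nonneg(v2)
    # hematoxylin first: the larger blue-channel OD component
    cols = (v1, v2) if v1[2] >= v2[2] else (v2, v1)
    m = np.column_stack(cols)
    conc = _concentrations(od, m)
    max_c = np.percentile(conc[:, tissue], 99.0, axis=1) if tissue.any() else conc.max(axis=1)
    max_c = np.maximum(max_c, 1e-6)
    return StainModel(m, max_c)


def _concentrations(od: np.ndarray, stain_matrix: np.ndarray, exact_nnls: bool = False) -> np.ndarray:
    """Per-pixel stain concentrations: least squares clipped at zero, or
    exact NNLS per pixel when requested (slow, for verification)."""
    if exact_nnls:
        from scipy.optimize import nnls

        out = np.empty((2, len(od)))
        for i, row in enumerate(od):
            out[:, i] = nnls(stain_matrix, row)[0]
        return out
    sol, *_ = np.linalg.lstsq(stain_matrix, od.T, rcond=None)
    return np.clip(sol, 0.0, None)


def normalize_to_reference(
    image: np.ndarray,
    reference: StainModel,
    source: StainModel | None = None,
    od_threshold: float = 0.15,
    exact_nnls: bool = False,
) -> np.ndarray:
    """Re-render ``image`` through the reference stain basis.

    Concentrations are solved against the image's own stain basis, rescaled by
    the ratio of reference to source 99th-percentile maxima, and recombined
    with the reference stain matrix.  Background pixels pass through
    unmodified.
    """
    image = as_rgb(image)
    if source is None:
        source = estimate_stains(image, od_threshold)
    od, _ = _tissue_od(image, od_threshold)
    background = np.all(od < od_threshold, axis=1)

    conc = _concentrations(od, source.stain_matrix, exact_nnls)
    conc *= (reference.max_concentrations / source.max_concentrations)[:, None]
    od_new = (reference.stain_matrix @ conc).T
    out = np.clip(np.rint(I0 * np.power(10.0, -od_new) - 1.0), 0, 255).astype(np.uint8)
    out = out.reshape(image.shape)
    flat_in = image.reshape(-1, 3)
    out.reshape(-1, 3)[background] = flat_in[background]
    return out
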