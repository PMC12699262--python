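"""Synthetic H&E-like skin histology with exact ground truth.

Each sample is a three-layer tissue stack — stratum corneum on top, the
epidermis band below it, dermis underneath — with a sinusoidal
epidermis–dermis boundary (EB) emulating rete ridges and a flat
epidermis–corneum boundary (ES).  Before rotation,

* ES is the horizontal line ``row = corneum_thickness``;
* EB is ``row = corneum_thickness + epidermis_thickness
  + ridge_amplitude * sin(2*pi*col / ridge_wavelength)``;
* the epidermis mask is exactly the set of pixel rows between them
  (``es <= row < eb(col)``).

Nuclei are drawn as small dark ellipses inside the epidermis band at a
controlled density, giving the texture statistics something to measure;
additive Gaussian noise is the only other stochastic element.  The same
parameters and seed always produce bit-identical output, and the returned
mask and boundary polylines are consistent by construction, so every
downstream stage (segmentation, sampling, morphometrics, radiomics,
classification) can be validated against known truth.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from skimage import draw, transform

from .images import as_rgb, save_mask, save_rgb
from .morphometrics import BoundaryPolyline

__all__ = [
    "SyntheticSkinParams",
    "SyntheticSkinSample",
    "LabeledSample",
    "generate_sample",
    "generate_cohort",
    "write_cohort",
    "YOUNG_PARAMS",
    "AGED_PARAMS",
]

#: Default H&E-ish palette: (corneum, epidermis, dermis) RGB.
DEFAULT_PALETTE = ((236, 205, 209), (196, 146, 200), (238, 178, 187))
NUCLEUS_COLOR = (72, 34, 112)


@dataclass(frozen=True)
class SyntheticSkinParams:
    """Generative ground truth for one synthetic skin raster.

    ``nucleus_density`` is nuclei per 10^4 epidermis pixels;
    ``ridge_amplitude`` is half the peak-to-trough EB excursion;
    ``orientation_deg`` rotates the whole layer stack (0 = horizontal layers).
    """

    image_height: int = 256
    image_width: int = 256
    corneum_thickness: int = 25
    epidermis_thickness: int = 40
    ridge_amplitude: float = 10.0
    ridge_wavelength: float = 96.0
    nucleus_density: float = 60.0
    orientation_deg: float = 0.0
    stain_palette: tuple = DEFAULT_PALETTE
    noise_sd: float = 4.0
    n_distractors: int = 0    # dark blobs in the dermis (follicle/gland stand-ins)
    seed: int = 0

    def validate(self) -> None:
        if not self.epidermis_thickness > self.ridge_amplitude >= 0:
            raise ValueError(
                "requires epidermis_thickness > ridge_amplitude >= 0 "
                f"(got {self.epidermis_thickness} vs {self.ridge_amplitude})"
            )
        if self.corneum_thickness < 1 or self.epidermis_thickness < 1:
            raise ValueError("all layer thicknesses must be >= 1 pixel")
        if self.ridge_wavelength < 4:
            raise ValueError("ridge_wavelength must be >= 4 pixels")
        if self.image_height < 4 or self.image_width < 4:
            raise ValueError("image must be at least 4x4 pixels")


@dataclass
class SyntheticSkinSample:
    image: np.ndarray
    epidermis_mask: np.ndarray
    eb_polyline: BoundaryPolyline
    es_polyline: BoundaryPolyline
    params: SyntheticSkinParams


@dataclass
class LabeledSample:
    label: str
    sample: SyntheticSkinSample


def _eb_row(params: SyntheticSkinParams, cols: np.ndarray) -> np.ndarray:
    return (
        params.corneum_thickness
        + params.epidermis_thickness
        + params.ridge_amplitude * np.sin(2.0 * np.pi * cols / params.ridge_wavelength)
    )


def _draw_nuclei(image: np.ndarray, mask: np.ndarray, params: SyntheticSkinParams, rng: np.random.Generator) -> None:
    """Dark elliptical nuclei inside the band, non-overlapping by rejection
    sampling (<= 100 attempts each), clipped to the mask."""
    area = int(mask.sum())
    n = int(round(params.nucleus_density * area / 1e4))
    if n == 0 or area == 0:
        return
    coords = np.argwhere(mask)
    occupied = np.zeros_like(mask)
    color = np.array(NUCLEUS_COLOR, dtype=np.float64)
    for _ in range(n):
        for _attempt in range(100):
            r, c = coords[rng.integers(len(coords))]
            a = rng.uniform(2.0, 4.0)   # semi-axes: 4-8 px full axes
            b = rng.uniform(2.0, 4.0)
            th = rng.uniform(0.0, np.pi)
            rr, cc = draw.ellipse(r, c, a, b, shape=mask.shape, rotation=th)
            inside = mask[rr, cc]
            rr, cc = rr[inside], cc[inside]
            if len(rr) == 0 or occupied[rr, cc].any():
                continue
            shade = rng.uniform(0.85, 1.15)
            image[rr, cc] = np.clip(color * shade, 0, 255)
            occupied[rr, cc] = True
            break


def _draw_distractors(image: np.ndarray, dermis: np.ndarray, rng: np.random.Generator, n: int) -> None:
    coords = np.argwhere(dermis)
    if len(coords) == 0:
        return
    for _ in range(n):
        r, c = coords[rng.integers(len(coords))]
        rad = rng.uniform(6.0, 14.0)
        rr, cc = draw.disk((r, c), rad, shape=dermis.shape)
        image[rr, cc] = np.clip(np.array(NUCLEUS_COLOR) * rng.uniform(1.0, 1.4), 0, 255)


def _rotate_points(points: np.ndarray, angle_deg: float, center: np.ndarray) -> np.ndarray:
    """Analytic counterpart of ``skimage.transform.rotate`` for (row, col)
    points: the image rotates counter-clockwise on screen, which in (row, col)
    coordinates maps a point p to R(-theta) @ (p - c) + c with the row axis
    pointing down."""
    th = np.deg2rad(angle_deg)
    # skimage.transform.rotate(angle) maps a feature with (row, col)
    # direction angle phi to phi - angle; points transform accordingly.
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return (points - center) @ rot.T + center


def generate_sample(params: SyntheticSkinParams) -> SyntheticSkinSample:
    """Render one synthetic sample; deterministic in (params, seed)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.image_height, params.image_width
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]

    eb = _eb_row(params, np.arange(w, dtype=np.float64))
    es_row = float(params.corneum_thickness)
    mask = (rows >= es_row) & (rows < eb[None, :])

    image = np.empty((h, w, 3), dtype=np.float64)
    corneum_c, epi_c, dermis_c = (np.array(c, dtype=np.float64) for c in params.stain_palette)
    image[:] = dermis_c
    image[np.broadcast_to(rows < es_row, (h, w))] = corneum_c
    image[mask] = epi_c

    _draw_nuclei(image, mask, params, rng)
    if params.n_distractors:
        dermis = np.broadcast_to(rows >= 0, (h, w)) & ~mask & (rows >= es_row)
        _draw_distractors(image, dermis, rng, params.n_distractors)

    if params.noise_sd > 0:
        image = image + rng.normal(0.0, params.noise_sd, size=image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    col_axis = np.arange(w, dtype=np.float64)
    eb_pts = np.column_stack([eb, col_axis])
    es_pts = np.column_stack([np.full(w, es_row), col_axis])

    if params.orientation_deg != 0.0:
        angle = params.orientation_deg
        image = transform.rotate(image.astype(np.float64) / 255.0, angle, mode="reflect", order=1)
        image = np.clip(np.rint(image * 255.0), 0, 255).astype(np.uint8)
        mask = transform.rotate(mask.astype(np.float64), angle, mode="constant", cval=0.0, order=0) > 0.5
        center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        eb_pts = _rotate_points(eb_pts, angle, center)
        es_pts = _rotate_points(es_pts, angle, center)

    return SyntheticSkinSample(
        image=as_rgb(image),
        epidermis_mask=mask,
        eb_polyline=BoundaryPolyline(eb_pts, role="EB"),
        es_polyline=BoundaryPolyline(es_pts, role="ES"),
        params=params,
    )


#: Study-condition defaults: aged skin is thinner, with flatter rete ridges
#: and reduced epidermal cellularity.
YOUNG_PARAMS = SyntheticSkinParams(epidermis_thickness=40, ridge_amplitude=10.0, nucleus_density=70.0)
AGED_PARAMS = SyntheticSkinParams(epidermis_thickness=20, ridge_amplitude=3.0, nucleus_density=30.0)


def generate_cohort(
    n_young: int,
    n_aged: int,
    young_params: SyntheticSkinParams = YOUNG_PARAMS,
    aged_params: SyntheticSkinParams = AGED_PARAMS,
    seed: int = 0,
    jitter_rel_sd: float = 0.10,
) -> list:
    """Labeled cohort with per-sample lognormal-free multiplicative jitter.

    Epidermis thickness and ridge amplitude are jittered around the group
    means by a relative Gaussian sd (default 10%), mimicking inter-subject
    variability; each sample gets its own derived seed so the cohort is
    reproducible from the single ``seed``.
    """
    if n_young < 1 or n_aged < 1:
        raise ValueError("need at least one sample per group")
    rng = np.random.default_rng(seed)
    out = []
    for label, n, base in (("young", n_young, young_params), ("aged", n_aged, aged_params)):
        for _ in range(n):
            thick = max(2.0, base.epidermis_thickness * (1.0 + jitter_rel_sd * rng.standard_normal()))
            amp = max(0.0, base.ridge_amplitude * (1.0 + jitter_rel_sd * rng.standard_normal()))
            amp = min(amp, 0.9 * thick)  # keep the band from self-intersecting
            p = replace(
                base,
                epidermis_thickness=int(round(thick)),
                ridge_amplitude=float(amp),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            out.append(LabeledSample(label=label, sample=generate_sample(p)))
    return out


def write_cohort(samples: list, out_dir) -> Path:
    """Write PNGs plus a manifest.csv (file, label, true thickness/amplitude, seed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["file", "label", "true_thickness", "true_amplitude", "seed"])
        for i, ls in enumerate(samples):
            stem = f"sample_{i:04d}"
            save_rgb(out / f"{stem}.png", ls.sample.image)
            save_mask(out / f"{stem}_mask.png", ls.sample.epidermis_mask)
            p = ls.sample.params
            writer.writerow([f"{stem}.png", ls.label, p.epidermis_thickness, p.ridge_amplitude, p.seed])
    return manifest
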