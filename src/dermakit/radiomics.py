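"""Radiomic feature extraction: a pinned 106-feature schema per patch.

Each patch is converted to luminance grayscale and discretized at a fixed
bin width (default 25 intensity units); the feature vector then combines

* 13 numeric diagnostics (raw-image and mask bookkeeping),
* 18 first-order intensity statistics,
* 24 gray-level co-occurrence (GLCM) features,
* 16 gray-level run-length (GLRLM) features,
* 16 gray-level size-zone (GLSZM) features,
* 5 neighbouring gray-tone difference (NGTDM) features,
* 14 gray-level dependence (GLDM) features,

for exactly 106 named values in a fixed, documented order (``FEATURE_NAMES``).
First-order statistics are computed on the raw gray values except Entropy and
Uniformity, which use the discretized histogram.  Texture matrices use
distance 1 and, where directional, the four 2-D directions; the GLCM is
symmetric and the four per-angle matrices are averaged before the features
are evaluated, and GLRLM run matrices are summed over directions.  The GLDM
dependence size is the count of neighbours within ``alpha = 0`` gray levels
of the centre plus one.  Non-finite values (e.g. skewness of a constant
patch) are replaced by 0 and flagged, keeping vectors rectangular.

Feature regions: the whole patch (``mask_mode="full"``, the default) or the
epidermis mask crop (``mask_mode="mask_crop"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import graycomatrix

from .images import rgb_to_gray
from .sampling import Patch

__all__ = ["RadiomicFeatureVector", "FEATURE_NAMES", "extract_features", "N_FEATURES", "N_FIRST_ORDER"]

_EPS = np.finfo(np.float64).eps

DIAGNOSTIC_NAMES = tuple(
    "diagnostics_" + n
    for n in (
        "Image_Mean", "Image_Minimum", "Image_Maximum", "Image_StandardDeviation",
        "Image_Rows", "Image_Columns", "Image_GrayLevels",
        "Mask_VoxelNum", "Mask_MaskFraction", "Mask_CentroidRow", "Mask_CentroidCol",
        "Mask_BoundingBoxRows", "Mask_BoundingBoxColumns",
    )
)

FIRST_ORDER_NAMES = tuple(
    "firstorder_" + n
    for n in (
        "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile", "90Percentile",
        "Maximum", "Mean", "Median", "InterquartileRange", "Range",
        "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation", "RootMeanSquared",
        "Skewness", "Kurtosis", "Variance", "Uniformity",
    )
)

GLCM_NAMES = tuple(
    "glcm_" + n
    for n in (
        "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
        "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
        "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
        "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy",
        "MaximumProbability", "MCC", "SumAverage", "SumEntropy", "SumSquares",
    )
)

GLRLM_NAMES = tuple(
    "glrlm_" + n
    for n in (
        "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized", "GrayLevelVariance",
        "HighGrayLevelRunEmphasis", "LongRunEmphasis", "LongRunHighGrayLevelEmphasis",
        "LongRunLowGrayLevelEmphasis", "LowGrayLevelRunEmphasis", "RunEntropy",
        "RunLengthNonUniformity", "RunLengthNonUniformityNormalized", "RunPercentage",
        "RunVariance", "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
        "ShortRunLowGrayLevelEmphasis",
    )
)

GLSZM_NAMES = tuple(
    "glszm_" + n
    for n in (
        "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized", "GrayLevelVariance",
        "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis", "LargeAreaHighGrayLevelEmphasis",
        "LargeAreaLowGrayLevelEmphasis", "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
        "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis", "SmallAreaHighGrayLevelEmphasis",
        "SmallAreaLowGrayLevelEmphasis", "ZoneEntropy", "ZonePercentage", "ZoneVariance",
    )
)

NGTDM_NAMES = tuple("ngtdm_" + n for n in ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength"))

GLDM_NAMES = tuple(
    "gldm_" + n
    for n in (
        "DependenceEntropy", "DependenceNonUniformity", "DependenceNonUniformityNormalized",
        "DependenceVariance", "GrayLevelNonUniformity", "GrayLevelVariance",
        "HighGrayLevelEmphasis", "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
        "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis", "SmallDependenceEmphasis",
        "SmallDependenceHighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    )
)

FEATURE_NAMES: tuple = (
    DIAGNOSTIC_NAMES + FIRST_ORDER_NAMES + GLCM_NAMES + GLRLM_NAMES + GLSZM_NAMES + NGTDM_NAMES + GLDM_NAMES
)
N_FEATURES = len(FEATURE_NAMES)       # 106
N_FIRST_ORDER = len(FIRST_ORDER_NAMES)  # 18


@dataclass
class RadiomicFeatureVector:
    patch_id: str
    wsi_id: str
    values: dict                      # ordered: FEATURE_NAMES -> float
    label: str | None = None
    nan_flags: tuple = ()

    def __post_init__(self):
        if tuple(self.values.keys()) != FEATURE_NAMES:
            raise ValueError(f"feature vector must carry exactly the {N_FEATURES}-name schema in order")

    def as_array(self) -> np.ndarray:
        return np.fromiter(self.values.values(), dtype=np.float64, count=N_FEATURES)


# ---------------------------------------------------------------------------
# Helpers


def _discretize(gray: np.ndarray, region: np.ndarray, bin_width: float):
    """Levels 1..Ng inside the region (0 outside): floor((x - min)/width) + 1."""
    vals = gray[region]
    gmin = vals.min()
    disc = np.zeros(gray.shape, dtype=np.int64)
    disc[region] = np.floor((gray[region] - gmin) / bin_width).astype(np.int64) + 1
    return disc, int(disc.max())


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def _diagnostics(gray, region, disc_levels):
    h, w = gray.shape
    coords = np.argwhere(region)
    r0, c0 = coords.min(axis=0)
    r1, c1 = coords.max(axis=0)
    return {
        "diagnostics_Image_Mean": float(gray.mean()),
        "diagnostics_Image_Minimum": float(gray.min()),
        "diagnostics_Image_Maximum": float(gray.max()),
        "diagnostics_Image_StandardDeviation": float(gray.std()),
        "diagnostics_Image_Rows": float(h),
        "diagnostics_Image_Columns": float(w),
        "diagnostics_Image_GrayLevels": float(disc_levels),
        "diagnostics_Mask_VoxelNum": float(region.sum()),
        "diagnostics_Mask_MaskFraction": float(region.mean()),
        "diagnostics_Mask_CentroidRow": float(coords[:, 0].mean()),
        "diagnostics_Mask_CentroidCol": float(coords[:, 1].mean()),
        "diagnostics_Mask_BoundingBoxRows": float(r1 - r0 + 1),
        "diagnostics_Mask_BoundingBoxColumns": float(c1 - c0 + 1),
    }


def _first_order(x: np.ndarray, disc_vals: np.ndarray, n_levels: int):
    n = len(x)
    mean = x.mean()
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    hist = np.bincount(disc_vals, minlength=n_levels + 1)[1:].astype(np.float64)
    p = hist / hist.sum()
    sd = x.std()
    m3 = np.mean((x - mean) ** 3)
    m4 = np.mean((x - mean) ** 4)
    return {
        "firstorder_Energy": float(np.sum(x**2)),
        "firstorder_TotalEnergy": float(np.sum(x**2)),   # unit pixel volume
        "firstorder_Entropy": _entropy(p),
        "firstorder_Minimum": float(x.min()),
        "firstorder_10Percentile": float(p10),
        "firstorder_90Percentile": float(p90),
        "firstorder_Maximum": float(x.max()),
        "firstorder_Mean": float(mean),
        "firstorder_Median": float(p50),
        "firstorder_InterquartileRange": float(p75 - p25),
        "firstorder_Range": float(x.max() - x.min()),
        "firstorder_MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "firstorder_RobustMeanAbsoluteDeviation": float(np.mean(np.abs(robust - robust.mean()))) if len(robust) else 0.0,
        "firstorder_RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "firstorder_Skewness": float(m3 / sd**3) if sd > 0 else 0.0,
        "firstorder_Kurtosis": float(m4 / sd**4) if sd > 0 else 0.0,
        "firstorder_Variance": float(x.var()),
        "firstorder_Uniformity": float(np.sum(p**2)),
    }


def glcm_matrix(disc: np.ndarray, n_levels: int) -> np.ndarray:
    """Mean of the four symmetric, normalized distance-1 co-occurrence
    matrices (angles 0/45/90/135 degrees); level 0 (outside region) dropped."""
    img = disc.astype(np.uint16) if n_levels > 254 else disc.astype(np.uint8)
    counts = graycomatrix(
        img, distances=[1], angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
        levels=n_levels + 1, symmetric=True, normed=False,
    )[:, :, 0, :].astype(np.float64)
    counts = counts[1:, 1:, :]   # drop pairs involving out-of-region pixels
    mats = []
    for a in range(counts.shape[2]):
        s = counts[:, :, a].sum()
        if s > 0:
            mats.append(counts[:, :, a] / s)
    return np.mean(mats, axis=0) if mats else np.full((n_levels, n_levels), 1.0 / n_levels**2)


def _glcm_features(P: np.ndarray):
    ng = P.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(np.sum(px * i))
    mu_y = float(np.sum(py * i))
    sig_x = float(np.sqrt(np.sum(px * (i - mu_x) ** 2)))
    sig_y = float(np.sqrt(np.sum(py * (i - mu_y) ** 2)))

    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.array([P[(ii + jj) == k].sum() for k in k_sum])
    k_diff = np.arange(0, ng, dtype=np.float64)
    p_diff = np.array([P[np.abs(ii - jj) == k].sum() for k in k_diff])

    autoc = float(np.sum(P * ii * jj))
    da = float(np.sum(k_diff * p_diff))
    hxy = _entropy(P.ravel())
    hx, hy = _entropy(px), _entropy(py)
    pxpy = np.outer(px, py)
    nz = pxpy > 0
    hxy1 = float(-np.sum(P[nz] * np.log2(pxpy[nz])))
    hxy2 = float(-np.sum(pxpy[nz] * np.log2(pxpy[nz])))
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0

    # maximal correlation coefficient: sqrt of the 2nd-largest eigenvalue of Q
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = px[:, None] * py[None, :]
        Q = np.where(denom > 0, (P @ (P / np.where(py > 0, py, 1.0)).T) / np.where(px[:, None] > 0, px[:, None], 1.0), 0.0)
    try:
        ev = np.sort(np.abs(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(ev[-2])) if len(ev) > 1 else 1.0
    except np.linalg.LinAlgError:
        mcc = 0.0

    off = np.abs(ii - jj) > 0
    corr = float((autoc - mu_x * mu_y) / (sig_x * sig_y)) if sig_x * sig_y > 0 else 1.0
    return {
        "glcm_Autocorrelation": autoc,
        "glcm_ClusterProminence": float(np.sum(P * (ii + jj - mu_x - mu_y) ** 4)),
        "glcm_ClusterShade": float(np.sum(P * (ii + jj - mu_x - mu_y) ** 3)),
        "glcm_ClusterTendency": float(np.sum(P * (ii + jj - mu_x - mu_y) ** 2)),
        "glcm_Contrast": float(np.sum(P * (ii - jj) ** 2)),
        "glcm_Correlation": corr,
        "glcm_DifferenceAverage": da,
        "glcm_DifferenceEntropy": _entropy(p_diff),
        "glcm_DifferenceVariance": float(np.sum(p_diff * (k_diff - da) ** 2)),
        "glcm_Id": float(np.sum(P / (1.0 + np.abs(ii - jj)))),
        "glcm_Idm": float(np.sum(P / (1.0 + (ii - jj) ** 2))),
        "glcm_Idmn": float(np.sum(P / (1.0 + ((ii - jj) ** 2) / ng**2))),
        "glcm_Idn": float(np.sum(P / (1.0 + np.abs(ii - jj) / ng))),
        "glcm_Imc1": float(imc1),
        "glcm_Imc2": imc2,
        "glcm_InverseVariance": float(np.sum(P[off] / (ii[off] - jj[off]) ** 2)),
        "glcm_JointAverage": mu_x,
        "glcm_JointEnergy": float(np.sum(P**2)),
        "glcm_JointEntropy": hxy,
        "glcm_MaximumProbability": float(P.max()),
        "glcm_MCC": mcc,
        "glcm_SumAverage": float(np.sum(k_sum * p_sum)),
        "glcm_SumEntropy": _entropy(p_sum),
        "glcm_SumSquares": float(np.sum(P * (ii - mu_x) ** 2)),
    }


def _run_lengths(line: np.ndarray):
    """(level, length) runs of a 1-D discretized line; level 0 breaks runs."""
    if len(line) == 0:
        return
    change = np.flatnonzero(np.diff(line)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(line)]])
    for s, e in zip(starts, ends):
        if line[s] > 0:
            yield int(line[s]), int(e - s)


def _glrlm_matrix(disc: np.ndarray, n_levels: int) -> np.ndarray:
    h, w = disc.shape
    max_len = max(h, w)
    R = np.zeros((n_levels, max_len), dtype=np.float64)

    def add(line):
        for g, ln in _run_lengths(line):
            R[g - 1, ln - 1] += 1

    for r in range(h):
        add(disc[r])
    for c in range(w):
        add(disc[:, c])
    for off in range(-h + 1, w):
        add(np.diagonal(disc, offset=off))
        add(np.diagonal(np.fliplr(disc), offset=off))
    used = np.flatnonzero(R.sum(axis=0))
    return R[:, : used[-1] + 1] if len(used) else R[:, :1]


def _size_weighted_features(M: np.ndarray, prefix: str, size_name: dict, n_px: int):
    """Shared feature algebra for run-length / size-zone / dependence matrices:
    M[g-1, s-1] counts occurrences of gray level g at size s."""
    n_tot = M.sum()
    if n_tot == 0:
        return {k: 0.0 for k in size_name["names"]}
    g = np.arange(1, M.shape[0] + 1, dtype=np.float64)
    s = np.arange(1, M.shape[1] + 1, dtype=np.float64)
    gg, ss = np.meshgrid(g, s, indexing="ij")
    p = M / n_tot
    mg = M.sum(axis=1)
    ms = M.sum(axis=0)
    mu_g = np.sum(gg * p)
    mu_s = np.sum(ss * p)
    f = {
        "GrayLevelNonUniformity": float(np.sum(mg**2) / n_tot),
        "GrayLevelNonUniformityNormalized": float(np.sum(mg**2) / n_tot**2),
        "GrayLevelVariance": float(np.sum(p * (gg - mu_g) ** 2)),
        "High": float(np.sum(M * gg**2) / n_tot),
        "Low": float(np.sum(M / gg**2) / n_tot),
        "SizeNonUniformity": float(np.sum(ms**2) / n_tot),
        "SizeNonUniformityNormalized": float(np.sum(ms**2) / n_tot**2),
        "Large": float(np.sum(M * ss**2) / n_tot),
        "Small": float(np.sum(M / ss**2) / n_tot),
        "LargeHigh": float(np.sum(M * ss**2 * gg**2) / n_tot),
        "LargeLow": float(np.sum(M * ss**2 / gg**2) / n_tot),
        "SmallHigh": float(np.sum(M * gg**2 / ss**2) / n_tot),
        "SmallLow": float(np.sum(M / (gg**2 * ss**2)) / n_tot),
        "SizeVariance": float(np.sum(p * (ss - mu_s) ** 2)),
        "Entropy": _entropy(p.ravel()),
        "Percentage": float(n_tot / n_px),
    }
    return {full: f[short] for full, short in size_name["map"].items()}


def _glszm_matrix(disc: np.ndarray, n_levels: int) -> np.ndarray:
    sizes_by_level = {}
    max_size = 1
    st = np.ones((3, 3), dtype=int)
    for g in range(1, n_levels + 1):
        lab, n = ndi.label(disc == g, structure=st)
        if n == 0:
            continue
        sz = ndi.sum_labels(disc == g, lab, index=np.arange(1, n + 1)).astype(int)
        sizes_by_level[g] = sz
        max_size = max(max_size, int(sz.max()))
    Z = np.zeros((n_levels, max_size), dtype=np.float64)
    for g, sz in sizes_by_level.items():
        for v in sz:
            Z[g - 1, v - 1] += 1
    return Z


def _neighbor_stats(gray: np.ndarray, region: np.ndarray):
    """Mean of valid 8-neighbors per pixel (NGTDM) via shifted sums."""
    vals = np.where(region, gray, 0.0)
    cnt = region.astype(np.float64)
    sum_n = np.zeros_like(vals)
    cnt_n = np.zeros_like(vals)
    h, w = gray.shape
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            sr = slice(max(0, dr), min(h, h + dr))
            tr = slice(max(0, -dr), min(h, h - dr))
            sc = slice(max(0, dc), min(w, w + dc))
            tc = slice(max(0, -dc), min(w, w - dc))
            sum_n[tr, tc] += vals[sr, sc]
            cnt_n[tr, tc] += cnt[sr, sc]
    return sum_n, cnt_n


def _ngtdm_features(disc: np.ndarray, region: np.ndarray, n_levels: int):
    sum_n, cnt_n = _neighbor_stats(disc.astype(np.float64), region & (disc > 0))
    valid = region & (disc > 0) & (cnt_n > 0)
    mean_n = np.where(valid, sum_n / np.where(cnt_n > 0, cnt_n, 1.0), 0.0)
    diff = np.abs(disc - mean_n)

    n_px = int(valid.sum())
    levels = np.arange(1, n_levels + 1)
    n_g = np.array([(valid & (disc == g)).sum() for g in levels], dtype=np.float64)
    s_g = np.array([diff[valid & (disc == g)].sum() for g in levels])
    p_g = n_g / max(n_px, 1)
    present = p_g > 0
    ngp = int(present.sum())
    iv = levels[present].astype(np.float64)
    pv, sv = p_g[present], s_g[present]

    coarse_den = float(np.sum(pv * sv))
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6
    if ngp > 1 and n_px > 0:
        pi, pj = np.meshgrid(pv, pv, indexing="ij")
        si, sj = np.meshgrid(sv, sv, indexing="ij")
        di = iv[:, None] - iv[None, :]
        contrast = float(np.sum(pi * pj * di**2) / (ngp * (ngp - 1)) * np.sum(sv) / n_px)
        busy_den = float(np.sum(np.abs(iv[:, None] * pi - iv[None, :] * pj)))
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        complexity = float(np.sum(np.abs(di) * (pi * si + pj * sj) / (pi + pj)) / n_px)
        strength_num = float(np.sum((pi + pj) * di**2))
        strength = strength_num / np.sum(sv) if np.sum(sv) > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "ngtdm_Busyness": busyness,
        "ngtdm_Coarseness": coarseness,
        "ngtdm_Complexity": complexity,
        "ngtdm_Contrast": contrast,
        "ngtdm_Strength": strength,
    }


def _gldm_matrix(disc: np.ndarray, region: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """D[g-1, d]: gray level g with d neighbours within alpha levels; size
    index is d + 1 so the smallest dependence is 1."""
    h, w = disc.shape
    dep = np.zeros((h, w), dtype=np.int64)
    inr = region & (disc > 0)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            sr = slice(max(0, dr), min(h, h + dr))
            tr = slice(max(0, -dr), min(h, h - dr))
            sc = slice(max(0, dc), min(w, w + dc))
            tc = slice(max(0, -dc), min(w, w - dc))
            ok = inr[tr, tc] & inr[sr, sc] & (np.abs(disc[tr, tc] - disc[sr, sc]) <= alpha)
            dep[tr, tc] += ok
    D = np.zeros((n_levels, 9), dtype=np.float64)
    g_flat = disc[inr]
    d_flat = dep[inr]
    np.add.at(D, (g_flat - 1, d_flat), 1.0)
    return D


def extract_features(
    patch,
    mask_mode: str = "full",
    bin_width: float = 25.0,
    patch_id: str | None = None,
    wsi_id: str | None = None,
    label: str | None = None,
) -> RadiomicFeatureVector:
    """Compute the full 106-feature vector for a patch.

    ``patch`` is a :class:`~dermakit.sampling.Patch` or a bare RGB/gray
    array (then ``mask_mode`` must be ``"full"`` unless a Patch is given).
    """
    if isinstance(patch, Patch):
        pixels, mask = patch.pixels, patch.mask_crop
        patch_id = patch_id or patch.patch_id
        wsi_id = wsi_id or patch.wsi_id
    else:
        pixels, mask = np.asarray(patch), None
        patch_id = patch_id or "patch"
        wsi_id = wsi_id or "wsi"

    gray = rgb_to_gray(pixels) if pixels.ndim == 3 else np.asarray(pixels, dtype=np.float64)
    if mask_mode == "full":
        region = np.ones(gray.shape, dtype=bool)
    elif mask_mode == "mask_crop":
        if mask is None or not mask.any():
            raise ValueError("mask_crop mode requires a non-empty mask crop")
        region = mask.astype(bool)
    else:
        raise ValueError("mask_mode must be 'full' or 'mask_crop'")

    disc, n_levels = _discretize(gray, region, bin_width)
    x = gray[region]

    values = {}
    values.update(_diagnostics(gray, region, n_levels))
    values.update(_first_order(x, disc[region], n_levels))
    values.update(_glcm_features(glcm_matrix(disc, n_levels)))

    n_px = int(region.sum())
    glrlm_map = {
        "glrlm_GrayLevelNonUniformity": "GrayLevelNonUniformity",
        "glrlm_GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
        "glrlm_GrayLevelVariance": "GrayLevelVariance",
        "glrlm_HighGrayLevelRunEmphasis": "High",
        "glrlm_LongRunEmphasis": "Large",
        "glrlm_LongRunHighGrayLevelEmphasis": "LargeHigh",
        "glrlm_LongRunLowGrayLevelEmphasis": "LargeLow",
        "glrlm_LowGrayLevelRunEmphasis": "Low",
        "glrlm_RunEntropy": "Entropy",
        "glrlm_RunLengthNonUniformity": "SizeNonUniformity",
        "glrlm_RunLengthNonUniformityNormalized": "SizeNonUniformityNormalized",
        "glrlm_RunPercentage": "Percentage",
        "glrlm_RunVariance": "SizeVariance",
        "glrlm_ShortRunEmphasis": "Small",
        "glrlm_ShortRunHighGrayLevelEmphasis": "SmallHigh",
        "glrlm_ShortRunLowGrayLevelEmphasis": "SmallLow",
    }
    values.update(
        _size_weighted_features(
            _glrlm_matrix(disc, n_levels), "glrlm",
            {"names": GLRLM_NAMES, "map": glrlm_map}, n_px * 4,  # 4 directions of runs
        )
    )
    glszm_map = {
        "glszm_GrayLevelNonUniformity": "GrayLevelNonUniformity",
        "glszm_GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
        "glszm_GrayLevelVariance": "GrayLevelVariance",
        "glszm_HighGrayLevelZoneEmphasis": "High",
        "glszm_LargeAreaEmphasis": "Large",
        "glszm_LargeAreaHighGrayLevelEmphasis": "LargeHigh",
        "glszm_LargeAreaLowGrayLevelEmphasis": "LargeLow",
        "glszm_LowGrayLevelZoneEmphasis": "Low",
        "glszm_SizeZoneNonUniformity": "SizeNonUniformity",
        "glszm_SizeZoneNonUniformityNormalized": "SizeNonUniformityNormalized",
        "glszm_SmallAreaEmphasis": "Small",
        "glszm_SmallAreaHighGrayLevelEmphasis": "SmallHigh",
        "glszm_SmallAreaLowGrayLevelEmphasis": "SmallLow",
        "glszm_ZoneEntropy": "Entropy",
        "glszm_ZonePercentage": "Percentage",
        "glszm_ZoneVariance": "SizeVariance",
    }
    values.update(
        _size_weighted_features(_glszm_matrix(disc, n_levels), "glszm", {"names": GLSZM_NAMES, "map": glszm_map}, n_px)
    )
    values.update(_ngtdm_features(disc, region, n_levels))
    gldm_map = {
        "gldm_DependenceEntropy": "Entropy",
        "gldm_DependenceNonUniformity": "SizeNonUniformity",
        "gldm_DependenceNonUniformityNormalized": "SizeNonUniformityNormalized",
        "gldm_DependenceVariance": "SizeVariance",
        "gldm_GrayLevelNonUniformity": "GrayLevelNonUniformity",
        "gldm_GrayLevelVariance": "GrayLevelVariance",
        "gldm_HighGrayLevelEmphasis": "High",
        "gldm_LargeDependenceEmphasis": "Large",
        "gldm_LargeDependenceHighGrayLevelEmphasis": "LargeHigh",
        "gldm_LargeDependenceLowGrayLevelEmphasis": "LargeLow",
        "gldm_LowGrayLevelEmphasis": "Low",
        "gldm_SmallDependenceEmphasis": "Small",
        "gldm_SmallDependenceHighGrayLevelEmphasis": "SmallHigh",
        "gldm_SmallDependenceLowGrayLevelEmphasis": "SmallLow",
    }
    values.update(
        _size_weighted_features(_gldm_matrix(disc, region, n_levels), "gldm", {"names": GLDM_NAMES, "map": gldm_map}, n_px)
    )

    ordered = {name: values[name] for name in FEATURE_NAMES}
    flags = tuple(k for k, v in ordered.items() if not np.isfinite(v))
    for k in flags:
        ordered[k] = 0.0
    return RadiomicFeatureVector(patch_id=patch_id, wsi_id=wsi_id, values=ordered, label=label, nan_flags=flags)
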