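"""Canonical synthetic study designs.

These functions freeze the study conditions used throughout the package's
validation work: the aging-cohort classification study, the matched-geometry
cellularity study for hotspot localization, the no-signal (chance) study, and
the segmentation benchmark.  Problem sizes are chosen so that every study
runs on a single CPU in minutes; the methods note discusses what these scales
do and do not show.

Aging conditions follow the biology: aged epidermis is thinner, its rete
ridges flatter, and its cellularity lower than young epidermis.
"""

from __future__ import annotations

import numpy as np

from .classify import EvalReport, TrainConfig, evaluate, make_folds, train
from .sampling import SamplerConfig, sample_level2
from .synthetic import SyntheticSkinParams, generate_cohort, generate_sample

__all__ = [
    "aging_params", "cellularity_params", "segmentation_sample_params",
    "cohort_patches", "aging_study", "chance_study", "localization_study", "segmentation_study",
    "SEG_CONFIG",
]


def aging_params():
    """Young vs aged condition pair for the classification study: the groups
    differ in epidermal thickness (28 vs 14 px), ridge amplitude (7 vs 2 px)
    and nucleus density (70 vs 25 per 10^4 px)."""
    young = SyntheticSkinParams(
        image_height=192, image_width=192, corneum_thickness=28,
        epidermis_thickness=28, ridge_amplitude=7.0, ridge_wavelength=56.0,
        nucleus_density=70.0,
    )
    aged = SyntheticSkinParams(
        image_height=192, image_width=192, corneum_thickness=28,
        epidermis_thickness=14, ridge_amplitude=2.0, ridge_wavelength=56.0,
        nucleus_density=25.0,
    )
    return young, aged


def cellularity_params():
    """Young vs aged pair with *matched geometry* (thickness 24 px, amplitude
    6 px for both): only epidermal cellularity differs (70 vs 25 nuclei per
    10^4 px).  Because every class difference lives strictly inside the
    epidermis band, this is the appropriate design for testing whether
    activation hotspots localize to the epidermis."""
    young = SyntheticSkinParams(
        image_height=192, image_width=192, corneum_thickness=28,
        epidermis_thickness=24, ridge_amplitude=6.0, ridge_wavelength=48.0,
        nucleus_density=70.0,
    )
    aged = SyntheticSkinParams(
        image_height=192, image_width=192, corneum_thickness=28,
        epidermis_thickness=24, ridge_amplitude=6.0, ridge_wavelength=48.0,
        nucleus_density=25.0,
    )
    return young, aged


def segmentation_sample_params(seed: int) -> SyntheticSkinParams:
    """One 128x128 three-layer sample for the segmentation benchmark."""
    return SyntheticSkinParams(
        image_height=128, image_width=128, corneum_thickness=14,
        epidermis_thickness=24, ridge_amplitude=6.0, ridge_wavelength=48.0,
        nucleus_density=60.0, seed=seed,
    )


#: Segmentation configuration used at benchmark scale (128 px rasters).
def SEG_CONFIG(seed: int = 0):
    from .segmentation import SegConfig

    return SegConfig(
        n_channels=16, n_conv_blocks=2, max_iterations=60, min_clusters=3,
        learning_rate=0.1, seed=seed, min_component_area=200,
    )


def cohort_patches(young: SyntheticSkinParams, aged: SyntheticSkinParams, seed: int,
                   n_per_group: int = 10, patch_size: int = 64, stride: int = 24,
                   max_per_wsi: int | None = None):
    """Generate a labeled cohort and cut ground-truth-mask-guided patches.

    Returns (patches, labels); each synthetic sample plays the role of one
    WSI, its index becoming the ``wsi_id`` every patch inherits.
    """
    cohort = generate_cohort(n_per_group, n_per_group, young, aged, seed=seed)
    cfg = SamplerConfig(level2_size=patch_size, stride2=stride, bmz_filter_on=False)
    patches, labels = [], []
    for i, ls in enumerate(cohort):
        ps = sample_level2(ls.sample.image, ls.sample.epidermis_mask, cfg, wsi_id=f"wsi{i:03d}")
        if max_per_wsi is not None:
            ps = ps[:max_per_wsi]
        patches += ps
        labels += [ls.label] * len(ps)
    return patches, labels


def _run_cv(patches, labels, config: TrainConfig, k: int = 5, seed: int = 0) -> EvalReport:
    wsis = list(dict.fromkeys(p.wsi_id for p in patches))
    per_wsi = {p.wsi_id: l for p, l in zip(patches, labels)}
    folds = make_folds(wsis, per_wsi, k=k, seed=seed)
    models = train(patches, labels, folds, config)
    return evaluate(models, patches, labels, folds), models, folds


def aging_study(seed: int, epochs: int = 12, input_size: int = 32, backbone: str = "small_cnn"):
    """Slide-level 5-fold CV of the patch classifier on the aging cohort.

    Returns (EvalReport, models, folds, patches, labels)."""
    young, aged = aging_params()
    patches, labels = cohort_patches(young, aged, seed)
    config = TrainConfig(backbone=backbone, epochs=epochs, learning_rate=0.01, input_size=input_size, seed=seed)
    report, models, folds = _run_cv(patches, labels, config, seed=seed)
    return report, models, folds, patches, labels


def chance_study(seed: int, n_per_group: int = 100) -> float:
    """AUC of the classifier when the two groups have identical generative
    conditions (no signal): one patch per slide keeps the out-of-fold AUC's
    sampling variance small."""
    base = SyntheticSkinParams(
        image_height=96, image_width=96, corneum_thickness=24,
        epidermis_thickness=24, ridge_amplitude=5.0, ridge_wavelength=48.0,
        nucleus_density=60.0,
    )
    patches, labels = cohort_patches(base, base, seed, n_per_group=n_per_group, patch_size=48, stride=96, max_per_wsi=1)
    config = TrainConfig(epochs=3, learning_rate=0.01, input_size=32, seed=seed)
    report, _, _ = _run_cv(patches, labels, config, seed=seed)
    return report.pooled["roc_auc"]


def localization_study(seed: int, epochs: int = 8, input_size: int = 64):
    """Hotspot localization on the matched-geometry cellularity cohort.

    Trains the normalization-free backbone under slide-level 5-fold CV, then
    computes the class-contrast activation map for every out-of-fold patch
    and compares mean heat inside vs outside the ground-truth epidermis mask.
    Returns (fraction of patches with inside > outside, per-patch ratios).
    """
    from .gradcam import class_contrast_cam

    young, aged = cellularity_params()
    patches, labels = cohort_patches(young, aged, seed)
    config = TrainConfig(backbone="plain_cnn", epochs=epochs, learning_rate=0.01, input_size=input_size, seed=seed)
    wsis = list(dict.fromkeys(p.wsi_id for p in patches))
    per_wsi = {p.wsi_id: l for p, l in zip(patches, labels)}
    folds = make_folds(wsis, per_wsi, k=5, seed=seed)
    models = train(patches, labels, folds, config)
    wins, ratios = [], []
    for fold in folds:
        model = models[fold.fold_id]
        for i, p in enumerate(patches):
            if p.wsi_id not in fold.test_wsi_ids:
                continue
            hm = class_contrast_cam(model, p)
            m = p.mask_crop
            inside = float(hm.values[m].mean())
            outside = float(hm.values[~m].mean())
            wins.append(inside > outside)
            ratios.append(inside / max(outside, 1e-9))
    return float(np.mean(wins)), ratios


def segmentation_study(seed: int, n_samples: int = 10):
    """Unsupervised epidermis segmentation vs ground truth on ``n_samples``
    seeded three-layer rasters; returns the list of per-sample IoUs."""
    from .segmentation import iterative_unsupervised_segment, compute_superpixels, refine_mask, select_epidermis_cluster

    ious = []
    for i in range(n_samples):
        cfg = SEG_CONFIG(seed)
        sample = generate_sample(segmentation_sample_params(seed + i))
        sp = compute_superpixels(sample.image, cfg)
        lab = iterative_unsupervised_segment(sample.image, sp, cfg)
        sel = select_epidermis_cluster(lab, sample.image, min_component_area=cfg.min_component_area)
        ref = refine_mask(sel.mask, cfg.kernel_radius, cfg.min_component_area)
        gt = sample.epidermis_mask
        ious.append(float((ref & gt).sum() / max((ref | gt).sum(), 1)))
    return ious
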