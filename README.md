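# dermakit

Epidermis-centric analysis of skin histology images.

Skin biopsies carry most of their diagnostic signal in the epidermis and the
basement membrane zone (BMZ) — the dermis–epidermis junction where rete
ridges undulate, basal keratinocytes reside and many pathologies first
manifest. `dermakit` implements a whole-slide-style analysis pipeline built
around that anatomy:

* **Stain normalization** — Macenko's method: pixel optical densities are
  decomposed over two stain vectors (hematoxylin, eosin) found from the
  extreme angles of the OD point cloud's principal plane, and re-rendered
  through a reference basis.
* **Unsupervised epidermis segmentation** — Felzenszwalb superpixels guide an
  iteratively self-trained per-image CNN (conv/ReLU/batch-norm blocks, 1×1
  conv + softmax); the epidermis cluster is picked by a stain × shape
  heuristic, cleaned by morphological opening, and accepted only when the
  mask runs diagonally across its frame (which rejects follicles, glands and
  vessels). Accepted masks yield *level-1* images.
* **BMZ-centric hierarchical patch sampling** — 512×512 *level-2* patches
  centred along the traced epidermis path, and 128×128 *level-3* patches
  along the EB-side boundary (the BMZ); an inclusion filter keeps patches
  that composite dermis, BMZ, epidermis and corneum diagonally.
* **Morphometrics** — with EB/ES the epidermis–dermis / epidermis–corneum
  boundaries,
  `thickness = mean_i d(ES_i, EB)` and
  `rete ridge score = var_j d(EB_j, ES)`
  (shortest point-to-polyline distances, pixel units). Thickness tracks
  epidermal atrophy; the score quantifies rete-ridge flattening.
* **Radiomics** — a pinned 106-feature vector per patch (18 first-order +
  GLCM/GLRLM/GLSZM/NGTDM/GLDM texture families + numeric diagnostics),
  random-forest ranking, top-5 feature selection.
* **CNN classification** — patch-level training (SGD, learning rate 0.01,
  mini-batch 1) under strict slide-level 5-fold cross-validation with
  accuracy / ROC-AUC / PR-AUC / macro-F1.
* **Grad-CAM hotspot tracing** — gradient-weighted class activation maps,
  overlays, and inside/outside-mask hotspot summaries, plus a class-contrast
  variant for binary models.

Everything is validated against a built-in **synthetic skin generator**:
three-layer H&E-like rasters (corneum / epidermis with sinusoidal rete
ridges and elliptical nuclei / dermis) with exact ground-truth masks and
boundary polylines, controllable thickness, ridge amplitude and wavelength,
cellularity, orientation and seed.

The neural networks (the segmenter, the classifiers and the Grad-CAM
machinery) run on a small numpy engine included in the package; no GPU or
deep-learning framework is needed, and every run is bit-reproducible from
its seed.

## Worked example

```python
from dermakit.studies import aging_study

report, models, folds, patches, labels = aging_study(seed=11)
p = report.pooled
print(f"pooled accuracy={p['accuracy']:.3f} roc_auc={p['roc_auc']:.3f}")
```

prints (10 young + 10 aged synthetic slides, 150 out-of-fold patches):

```
pooled accuracy=0.960 roc_auc=1.000
```

— the classifier separates young from aged skin almost perfectly because the
groups differ in epidermal thickness (28 vs 14 px), ridge amplitude (7 vs
2 px) and cellularity (70 vs 25 nuclei per 10⁴ px), and the evaluation is
leakage-free: no patch of a test slide was seen during training.

The `examples/` directory holds one short script per capability
(`simulate_cohort.py`, `stain_normalize.py`, `segment_and_measure.py`,
`radiomics_ranking.py`, `train_classifier.py`, `hotspot_tracing.py`); each
builds its own input, runs the method and explains the numbers it prints.
A thin CLI (`dermakit simulate|normalize|segment|sample|morpho|radiomics`)
wraps the same functions for shell use.

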