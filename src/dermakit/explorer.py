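"""Radiomic feature exploration: random-forest ranking and group summaries.

A random forest is fit on the per-patch radiomic vectors, features are ranked
by impurity importance (normalized to sum to 1) and the top-k (default 5) are
reported as the group-discriminating features.  All cross-validation respects
slide identity: patches from one WSI never straddle a train/test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupKFold

from .radiomics import FEATURE_NAMES, RadiomicFeatureVector

__all__ = ["FeatureRanking", "RFConfig", "fit_rf_classifier", "grouped_cv_auc", "feature_group_summary", "features_to_frame"]


@dataclass
class RFConfig:
    n_trees: int = 500
    max_depth: int | None = None


@dataclass
class FeatureRanking:
    """(feature, importance) pairs sorted non-increasing; importances sum to 1."""

    items: list  # list of (name, importance)
    top_k: int = 5

    def __post_init__(self):
        imps = np.array([v for _, v in self.items])
        if np.any(np.diff(imps) > 1e-12):
            raise ValueError("importances must be sorted non-increasing")
        if abs(imps.sum() - 1.0) > 1e-6:
            raise ValueError("importances must sum to 1")

    @property
    def top_names(self) -> list:
        return [name for name, _ in self.items[: self.top_k]]


def features_to_frame(features: list) -> pd.DataFrame:
    rows = []
    for fv in features:
        row = {"patch_id": fv.patch_id, "wsi_id": fv.wsi_id, "label": fv.label}
        row.update(fv.values)
        rows.append(row)
    return pd.DataFrame(rows)


def _design(features: list, labels=None):
    X = np.stack([fv.as_array() for fv in features])
    y = np.asarray(labels if labels is not None else [fv.label for fv in features])
    groups = np.asarray([fv.wsi_id for fv in features])
    if any(v is None for v in y):
        raise ValueError("labels missing for some feature vectors")
    return X, y, groups


def fit_rf_classifier(features: list, labels=None, rf_config: RFConfig | None = None, seed: int = 0, top_k: int = 5):
    """Fit the forest on all vectors and return (model, FeatureRanking)."""
    rf_config = rf_config or RFConfig()
    X, y, _ = _design(features, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate labels: need at least 2 classes")
    model = RandomForestClassifier(
        n_estimators=rf_config.n_trees, max_depth=rf_config.max_depth, random_state=seed
    )
    model.fit(X, y)
    imp = model.feature_importances_
    s = imp.sum()
    imp = imp / s if s > 0 else np.full_like(imp, 1.0 / len(imp))
    order = np.argsort(-imp, kind="stable")
    ranking = FeatureRanking(items=[(FEATURE_NAMES[i], float(imp[i])) for i in order], top_k=top_k)
    return model, ranking


def grouped_cv_auc(features: list, labels=None, rf_config: RFConfig | None = None, seed: int = 0, n_splits: int = 5) -> float:
    """Out-of-group ROC-AUC of the forest under WSI-grouped cross-validation."""
    rf_config = rf_config or RFConfig()
    X, y, groups = _design(features, labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("grouped_cv_auc supports binary labels")
    scores = np.zeros(len(y))
    for tr, te in GroupKFold(n_splits=n_splits).split(X, y, groups):
        m = RandomForestClassifier(n_estimators=rf_config.n_trees, max_depth=rf_config.max_depth, random_state=seed)
        m.fit(X[tr], y[tr])
        pos = list(m.classes_).index(classes[1])
        scores[te] = m.predict_proba(X[te])[:, pos]
    return float(roc_auc_score(y == classes[1], scores))


def feature_group_summary(features: list, labels=None, n_bins: int = 20) -> pd.DataFrame:
    """Per-feature class means, delta, standardized mean difference and
    histogram densities (one row per schema feature)."""
    X, y, _ = _design(features, labels)
    classes = sorted(np.unique(y))
    rows = []
    for j, name in enumerate(FEATURE_NAMES):
        col = X[:, j]
        means = {f"mean_{c}": float(col[y == c].mean()) for c in classes}
        row = {"feature": name, **means}
        if len(classes) == 2:
            a, b = (col[y == c] for c in classes)
            delta = float(b.mean() - a.mean())
            pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0) if min(len(a), len(b)) > 1 else 0.0
            row["delta"] = delta
            row["smd"] = float(delta / pooled) if pooled > 0 else 0.0
        edges = np.histogram_bin_edges(col, bins=n_bins)
        for c in classes:
            dens, _ = np.histogram(col[y == c], bins=edges, density=True)
            row[f"density_{c}"] = dens.tolist()
        row["bin_edges"] = edges.tolist()
        rows.append(row)
    return pd.DataFrame(rows)
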