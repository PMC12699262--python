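"""Patch-level CNN classification with WSI-level cross-validation.

Slides, not patches, are the unit of data splitting: a stratified k-fold
(default 5, i.e. 80/20) partition of WSI ids guarantees that no patch of a
test slide was seen in training, which is the leakage guard every evaluation
re-asserts.  Training is plain SGD (default learning rate 0.01, mini-batch
size 1) with cross-entropy loss on per-channel-normalized RGB input.

Backbones: ``small_cnn`` (three conv stages, the default — fast enough for
CPU-scale fixtures) and ``resnet_small`` (a residual variant).  Pretrained
weights are not bundled; requesting them raises.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import resize
from sklearn.metrics import f1_score, precision_recall_curve, roc_auc_score

from .nn import SGD, Sequential, build_plain_cnn, build_resnet_small, build_small_cnn, softmax, softmax_cross_entropy
from .sampling import Patch

__all__ = [
    "TrainConfig", "FoldSplit", "FoldModel", "EvalReport",
    "make_folds", "train", "evaluate", "pr_auc_envelope",
]

#: Fixed input normalization: x -> (x/255 - MEAN) / STD per channel.
INPUT_MEAN = 0.5
INPUT_STD = 0.25


@dataclass
class TrainConfig:
    backbone: str = "small_cnn"       # or "resnet_small"
    pretrained: bool = False
    learning_rate: float = 0.01
    batch_size: int = 1
    epochs: int = 10
    seed: int = 0
    n_classes: int = 2
    input_size: int | None = 32       # resize patches to this side before the net
    width: int = 8

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.pretrained:
            raise ValueError(
                "pretrained backbone weights are not bundled with this package; "
                "set pretrained=False or load weights explicitly"
            )


@dataclass
class FoldSplit:
    fold_id: int
    train_wsi_ids: frozenset
    test_wsi_ids: frozenset

    def __post_init__(self):
        if self.train_wsi_ids & self.test_wsi_ids:
            raise ValueError("train and test WSI sets overlap")


@dataclass
class FoldModel:
    net: Sequential
    classes: tuple
    config: TrainConfig
    fold_id: int
    loss_history: list = field(default_factory=list)

    def prepare(self, pixels: np.ndarray) -> np.ndarray:
        return prepare_input(pixels, self.config.input_size)

    def predict_scores(self, patches: list) -> np.ndarray:
        out = np.empty((len(patches), len(self.classes)))
        for i, p in enumerate(patches):
            x = self.prepare(p.pixels if isinstance(p, Patch) else p)
            out[i] = softmax(self.net.forward(x, train=False), axis=1)[0]
        return out


def prepare_input(pixels: np.ndarray, input_size: int | None) -> np.ndarray:
    x = np.asarray(pixels, dtype=np.float64) / 255.0
    if input_size is not None and x.shape[0] != input_size:
        x = resize(x, (input_size, input_size), order=1, anti_aliasing=True)
    x = (x - INPUT_MEAN) / INPUT_STD
    return x.transpose(2, 0, 1)[None]


def make_folds(wsi_ids: list, labels_per_wsi: dict, k: int = 5, seed: int = 0) -> list:
    """Stratified-by-label partition of WSI ids into k folds (deterministic)."""
    wsi_ids = list(dict.fromkeys(wsi_ids))
    rng = np.random.default_rng(seed)
    by_label: dict = {}
    for w in wsi_ids:
        by_label.setdefault(labels_per_wsi[w], []).append(w)
    assignment: dict = {}
    for label in sorted(by_label):
        members = sorted(by_label[label])
        if len(members) < k:
            raise ValueError(f"class {label!r} has {len(members)} WSIs < {k} folds")
        rng.shuffle(members)
        for i, w in enumerate(members):
            assignment[w] = i % k
    folds = []
    all_ids = frozenset(wsi_ids)
    for f in range(k):
        test = frozenset(w for w, a in assignment.items() if a == f)
        folds.append(FoldSplit(fold_id=f, train_wsi_ids=all_ids - test, test_wsi_ids=test))
    return folds


def _build_net(config: TrainConfig, rng: np.random.Generator) -> Sequential:
    if config.backbone == "small_cnn":
        net = build_small_cnn(config.n_classes, width=config.width, rng=rng)
    elif config.backbone == "plain_cnn":
        net = build_plain_cnn(config.n_classes, width=config.width, rng=rng)
    elif config.backbone == "resnet_small":
        net = build_resnet_small(config.n_classes, width=2 * config.width, rng=rng)
    else:
        raise ValueError(f"unknown backbone {config.backbone!r}")
    if config.batch_size == 1:
        # batch-size-1 training makes batch norm instance norm; inference
        # must normalize with the same per-sample statistics
        for layer in net.layers:
            for bn in getattr(layer, "body", [layer]):
                if hasattr(bn, "use_batch_stats_at_eval"):
                    bn.use_batch_stats_at_eval = True
    return net


def train(patches: list, labels: list, folds: list, config: TrainConfig | None = None) -> dict:
    """Train one model per fold on its training slides only.

    Returns ``{fold_id: FoldModel}``; folds without trainable patches are
    skipped with a warning entry (missing key)."""
    import warnings

    from dataclasses import replace as _replace

    config = config or TrainConfig()
    classes = tuple(sorted(set(labels)))
    if config.n_classes != len(classes):
        config = _replace(config, n_classes=len(classes))
    label_idx = {c: i for i, c in enumerate(classes)}
    y = np.array([label_idx[l] for l in labels])
    models = {}
    for fold in folds:
        idx = [i for i, p in enumerate(patches) if p.wsi_id in fold.train_wsi_ids]
        if not idx:
            warnings.warn(f"fold {fold.fold_id}: no trainable patches; skipped")
            continue
        rng = np.random.default_rng((config.seed, fold.fold_id))
        net = _build_net(config, rng)
        opt = SGD(net.params(), config.learning_rate)
        xs = [prepare_input(patches[i].pixels, config.input_size) for i in idx]
        ys = y[idx]
        history = []
        order = np.arange(len(idx))
        for _epoch in range(config.epochs):
            rng.shuffle(order)
            losses = []
            for s in range(0, len(order), config.batch_size):
                sel = order[s : s + config.batch_size]
                xb = np.concatenate([xs[i] for i in sel], axis=0)
                logits = net.forward(xb, train=True)
                loss, g = softmax_cross_entropy(logits, ys[sel])
                opt.zero_grad()
                net.backward(g)
                opt.step()
                losses.append(loss)
            history.append(float(np.mean(losses)))
        models[fold.fold_id] = FoldModel(net=net, classes=classes, config=config, fold_id=fold.fold_id, loss_history=history)
    return models


def pr_auc_envelope(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the precision-recall curve using the step-wise precision
    envelope (each recall level gets the best precision achievable at or
    above it)."""
    precision, recall, _ = precision_recall_curve(y_true, scores)
    # precision_recall_curve returns points from high threshold (recall 0) to
    # low; make recall increasing, apply the running-max envelope, integrate steps
    order = np.argsort(recall)
    r, p = recall[order], precision[order]
    p_env = np.maximum.accumulate(p[::-1])[::-1]
    return float(np.sum(np.diff(np.concatenate([[0.0], r])) * p_env))


def _metrics_from_table(df: pd.DataFrame, classes: tuple) -> dict:
    y_true = df["true"].to_numpy()
    y_pred = df["pred"].to_numpy()
    scores = df[[f"score_{c}" for c in classes]].to_numpy()
    out = {"n": int(len(df)), "accuracy": float(np.mean(y_true == y_pred))}
    out["macro_f1"] = float(f1_score(y_true, y_pred, labels=list(classes), average="macro", zero_division=0))
    present = [c for c in classes if np.any(y_true == c)]
    if len(present) < 2:
        out["roc_auc"] = None
        out["pr_auc"] = None
        return out
    if len(classes) == 2:
        pos = classes[1]
        out["roc_auc"] = float(roc_auc_score(y_true == pos, scores[:, 1]))
        out["pr_auc"] = pr_auc_envelope(y_true == pos, scores[:, 1])
    else:
        aucs, prs = [], []
        for i, c in enumerate(classes):
            if np.any(y_true == c) and not np.all(y_true == c):
                aucs.append(roc_auc_score(y_true == c, scores[:, i]))
                prs.append(pr_auc_envelope(y_true == c, scores[:, i]))
        out["roc_auc"] = float(np.mean(aucs)) if aucs else None
        out["pr_auc"] = float(np.mean(prs)) if prs else None
    return out


@dataclass
class EvalReport:
    per_fold: list
    pooled: dict
    table: pd.DataFrame
    classes: tuple


def evaluate(models: dict, patches: list, labels: list, folds: list) -> EvalReport:
    """Out-of-fold evaluation: per-fold metrics on each fold's test slides and
    pooled metrics over the concatenated out-of-fold prediction table."""
    rows = []
    classes = None
    for fold in folds:
        if fold.fold_id not in models:
            continue
        model = models[fold.fold_id]
        classes = model.classes
        idx = [i for i, p in enumerate(patches) if p.wsi_id in fold.test_wsi_ids]
        if not idx:
            continue
        # leakage guard: test slides must be absent from this fold's training set
        leaked = {patches[i].wsi_id for i in idx} & set(fold.train_wsi_ids)
        if leaked:
            raise AssertionError(f"WSI leakage in fold {fold.fold_id}: {sorted(leaked)}")
        scores = model.predict_scores([patches[i] for i in idx])
        for j, i in enumerate(idx):
            row = {
                "patch_id": patches[i].patch_id,
                "wsi_id": patches[i].wsi_id,
                "fold": fold.fold_id,
                "true": labels[i],
                "pred": classes[int(np.argmax(scores[j]))],
            }
            row.update({f"score_{c}": scores[j][k] for k, c in enumerate(classes)})
            rows.append(row)
    if not rows:
        raise ValueError("no out-of-fold predictions to evaluate")
    table = pd.DataFrame(rows)
    per_fold = [
        {"fold": int(f), **_metrics_from_table(g, classes)} for f, g in table.groupby("fold")
    ]
    pooled = _metrics_from_table(table, classes)
    return EvalReport(per_fold=per_fold, pooled=pooled, table=table, classes=classes)
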