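"""Data splitting, the training loop, cross-validation and evaluation.

Training minimizes mean binary cross-entropy with ADAM (alpha=0.0002,
beta1=0.9, beta2=0.999, eps=1e-8).  After every epoch the selection metric
(validation AUROC by default, validation loss as the alternative) is
computed and the best-so-far parameters are retained; training stops at
``max_epochs`` or after ``patience`` epochs without improvement.  The
output node weight is fixed at 1.0 throughout.  All randomness (parameter
init, epoch shuffling, dropout masks) flows from ``TrainConfig.seed``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from clipbind._backprop import (
    AdamOptimizer,
    batch_backward,
    batch_forward,
    batch_predict,
    bce_loss,
    encode_dataset,
)
from clipbind.network import (
    DEFAULT_FILTER_SIZES,
    DEFAULT_HIDDEN_SIZE,
    ModelBundle,
    ModelParams,
)
from clipbind.seq_io import NamedSequence

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Training hyper-parameters.

    Defaults: ADAM(0.0002, 0.9, 0.999, 1e-8), 10% dropout on H, batch size
    64, convolution weights initialized to the constant 0.01, BLSTM weights
    from N(0, 0.01^2).  ``patience`` defaults to ceil(0.10 * max_epochs)
    epochs without selection-metric improvement.
    """

    max_epochs: int = 50
    patience: Optional[int] = None
    selection_metric: str = "val_auroc"   # or "val_loss"
    adam_alpha: float = 0.0002
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    dropout: float = 0.10
    batch_size: int = 64
    seed: int = 0
    filter_sizes: tuple = DEFAULT_FILTER_SIZES
    hidden_size: int = DEFAULT_HIDDEN_SIZE
    conv_init: float = 0.01
    blstm_init_std: float = 0.01
    max_length: Optional[int] = None      # inferred from data when None

    def __post_init__(self) -> None:
        if self.patience is None:
            self.patience = max(1, math.ceil(0.10 * self.max_epochs))
        if self.patience > self.max_epochs and self.max_epochs > 0:
            raise ValueError("patience must not exceed max_epochs")
        if self.selection_metric not in ("val_auroc", "val_loss"):
            raise ValueError(f"unknown selection metric {self.selection_metric!r}")


@dataclass
class FoldPlan:
    """10 disjoint index bins with per-fold (test, validation, train) roles.

    Fold k tests on bin k and validates on bin (k+1) mod 10; the remaining
    8 bins train.  Every index is therefore a test item exactly once, a
    validation item exactly once and a training item exactly 8 times.
    """

    bins: list[np.ndarray]

    @property
    def n_folds(self) -> int:
        return len(self.bins)

    def fold(self, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n = self.n_folds
        test = self.bins[k]
        val = self.bins[(k + 1) % n]
        train = np.concatenate(
            [self.bins[j] for j in range(n) if j not in (k, (k + 1) % n)]
        )
        return train, val, test


def split_80_10_10(
    pos: Sequence, neg: Sequence, seed: int
) -> tuple[list, list, list]:
    """Stratified 80/10/10 split into (train, validation, test).

    Validation and test each take floor(n/10) items per class; the
    remainder trains.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    train: list = []
    val: list = []
    test: list = []
    for items in (pos, neg):
        n = len(items)
        if n == 0:
            raise ValueError("both classes must be non-empty")
        if n < 10:
            warnings.warn(
                f"class with {n} members is too small for a 10% holdout; "
                "using floor-based allocation"
            )
        order = rng.permutation(n)
        n_hold = n // 10
        test += [items[i] for i in order[:n_hold]]
        val += [items[i] for i in order[n_hold : 2 * n_hold]]
        train += [items[i] for i in order[2 * n_hold :]]
    return train, val, test


def make_cv_folds(n_items: int, seed: int, n_folds: int = 10) -> FoldPlan:
    """Shuffle indices and cut them into ``n_folds`` near-equal bins."""
    if n_items < n_folds:
        raise ValueError(f"need at least {n_folds} items, got {n_items}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_items)
    return FoldPlan(bins=[b for b in np.array_split(order, n_folds)])


def evaluate_auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUROC (Mann-Whitney form, ties counted 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC is undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def train_model(
    train: Sequence[NamedSequence],
    validation: Sequence[NamedSequence],
    cfg: TrainConfig,
    init_params: Optional[ModelParams] = None,
) -> tuple[ModelBundle, list[dict]]:
    """Train a model and return the best checkpoint plus a per-epoch history.

    ``train`` and ``validation`` are labelled sequences (label 0 or 1).
    History rows carry ``epoch``, ``train_loss``, ``val_metric`` and a
    ``best`` flag marking strict improvements (first-best retained on ties).
    """
    if not train or not validation:
        raise ValueError("train and validation sets must be non-empty")
    val_labels = np.array([s.label for s in validation], dtype=float)
    if len(np.unique(val_labels)) < 2:
        raise ValueError("validation set must contain both classes")
    train_labels = np.array([s.label for s in train], dtype=float)
    if len(np.unique(train_labels)) < 2:
        raise ValueError("training set must contain both classes")
    n_pos = int(train_labels.sum())
    if n_pos * 2 != len(train_labels):
        warnings.warn(
            f"training classes are imbalanced ({n_pos} positive of "
            f"{len(train_labels)}); no reweighting is applied"
        )

    max_length = cfg.max_length or max(
        max(len(s) for s in train), max(len(s) for s in validation)
    )
    rng = np.random.default_rng(cfg.seed)
    params = (
        init_params.copy()
        if init_params is not None
        else ModelParams.initialize(
            cfg.filter_sizes, cfg.hidden_size, rng,
            conv_init=cfg.conv_init, blstm_std=cfg.blstm_init_std,
        )
    )
    opt = AdamOptimizer(
        params, alpha=cfg.adam_alpha, beta1=cfg.adam_beta1,
        beta2=cfg.adam_beta2, eps=cfg.adam_eps,
    )
    X, M, y = encode_dataset(train, cfg.filter_sizes, max_length)
    Xv, Mv, yv = encode_dataset(validation, cfg.filter_sizes, max_length)

    maximize = cfg.selection_metric == "val_auroc"
    best_params = params.copy()
    best_metric = -np.inf if maximize else np.inf
    epochs_since_best = 0
    history: list[dict] = []

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(train))
        losses = []
        for lo in range(0, len(order), cfg.batch_size):
            sel = order[lo : lo + cfg.batch_size]
            cache = batch_forward(
                X[sel], M[sel], params, drop_rng=rng, dropout=cfg.dropout
            )
            losses.append(bce_loss(cache.score, y[sel]))
            dz = (cache.score - y[sel]) / len(sel)
            grads = batch_backward(cache, params, dz)
            opt.step(params, grads)
        val_cache = batch_forward(Xv, Mv, params)
        if maximize:
            metric = evaluate_auroc(val_cache.score, yv)
            improved = metric > best_metric
        else:
            metric = bce_loss(val_cache.score, yv)
            improved = metric < best_metric
        if improved:
            best_metric = metric
            best_params = params.copy()
            epochs_since_best = 0
        else:
            epochs_since_best += 1
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_metric": float(metric),
                "best": bool(improved),
            }
        )
        logger.info(
            "epoch %d: train_loss=%.4f %s=%.4f%s",
            epoch, history[-1]["train_loss"], cfg.selection_metric, metric,
            " *" if improved else "",
        )
        if epochs_since_best >= cfg.patience:
            break

    config = {
        "max_length": int(max_length),
        "filter_sizes": list(cfg.filter_sizes),
        "hidden_size": cfg.hidden_size,
        "dropout": cfg.dropout,
        "batch_size": cfg.batch_size,
        "selection_metric": cfg.selection_metric,
        "adam": [cfg.adam_alpha, cfg.adam_beta1, cfg.adam_beta2, cfg.adam_eps],
    }
    metadata = {
        "seed": cfg.seed,
        "epochs_run": len(history),
        "max_epochs": cfg.max_epochs,
        "patience": cfg.patience,
        "best_metric": float(best_metric) if history else None,
        "selection_metric": cfg.selection_metric,
    }
    bundle = ModelBundle(params=best_params, config=config, metadata=metadata)
    return bundle, history


def cv_auroc(
    pos: Sequence[NamedSequence],
    neg: Sequence[NamedSequence],
    cfg: TrainConfig,
    n_folds: int = 10,
) -> tuple[float, list[ModelBundle]]:
    """10-fold cross-validation with pooled test predictions.

    Fold plans are built per class and paired bin-by-bin so every fold's
    training and validation sets contain both classes.  Each input is
    predicted exactly once (by the fold holding it out for test); a single
    AUROC is computed on the pooled predictions.
    """
    pos = [replace(s, label=1) for s in pos]
    neg = [replace(s, label=0) for s in neg]
    plan_pos = make_cv_folds(len(pos), cfg.seed, n_folds)
    plan_neg = make_cv_folds(len(neg), cfg.seed + 1, n_folds)
    max_length = cfg.max_length or max(len(s) for s in [*pos, *neg])
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    bundles = []
    for k in range(n_folds):
        tr_p, va_p, te_p = plan_pos.fold(k)
        tr_n, va_n, te_n = plan_neg.fold(k)
        train = [pos[i] for i in tr_p] + [neg[i] for i in tr_n]
        val = [pos[i] for i in va_p] + [neg[i] for i in va_n]
        test = [pos[i] for i in te_p] + [neg[i] for i in te_n]
        fold_cfg = replace(cfg, seed=cfg.seed + 1000 + k, max_length=max_length)
        bundle, _ = train_model(train, val, fold_cfg)
        bundles.append(bundle)
        scores = batch_predict(test, bundle.params, bundle.max_length)
        pooled_scores.append(scores)
        pooled_labels.append(np.array([s.label for s in test], dtype=float))
    auroc = evaluate_auroc(
        np.concatenate(pooled_scores), np.concatenate(pooled_labels)
    )
    return auroc, bundles


def rnacompete_classes(
    intensities: dict[str, float], n: int = 1000
) -> tuple[list[str], list[str]]:
    """Top-n / bottom-n class assignment from per-probe intensities.

    Returns (positives, negatives) as key lists; ties broken by key
    insertion order (stable sort), so the partition is deterministic.
    """
    keys = list(intensities.keys())
    if len(keys) < 2 * n:
        raise ValueError(
            f"need at least {2 * n} items for top/bottom-{n} classes, "
            f"got {len(keys)}"
        )
    order = sorted(range(len(keys)), key=lambda i: intensities[keys[i]])
    negatives = [keys[i] for i in order[:n]]
    positives = [keys[i] for i in order[-n:]][::-1]
    return positives, negatives
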