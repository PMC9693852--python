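"""Dataset splitting, imbalance oversampling, SGD training, k-fold CV.

Splits are at epoch granularity (the evaluation protocol splits scored
30-s epochs, not subjects; a subject-wise split is stricter and can be had
by passing per-epoch group ids).  Oversampling balances the training
portion only -- evaluation data is never resampled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .stages import N_STAGES, STAGE_NAMES
from .evalmetrics import PerClassMetrics, confusion, per_class_metrics, cv_summary, CVSummary

logger = logging.getLogger(__name__)

__all__ = [
    "SplitSpec",
    "TrainConfig",
    "CVSpec",
    "split_train_test",
    "oversample_indices",
    "oversample",
    "train_model",
    "TrainResult",
    "kfold_cv",
]


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test split at epoch granularity (default 90/10)."""

    train_fraction: float = 0.9
    stratified: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    """SGD-with-momentum training hyperparameters.

    The backbone can learn at a reduced rate (``backbone_lr``) when
    fine-tuning transferred features; ``oversample`` balances class counts
    in the training portion by random duplication.
    """

    lr: float = 1e-3
    backbone_lr: float = 1e-4
    momentum: float = 0.9
    batch_size: int = 32
    max_epochs: int = 20
    oversample: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lr, self.backbone_lr) < 0 or not 0 <= self.momentum < 1:
            raise ValueError("learning rates must be >= 0 and momentum in [0, 1)")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be positive")


@dataclass(frozen=True)
class CVSpec:
    """k-fold cross-validation specification (default k=20)."""

    k: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")


def split_train_test(labels: np.ndarray, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test index partition.

    |train| = round(train_fraction * N).  With ``stratified=True`` each
    class contributes its own fraction of epochs (within one epoch of the
    target, largest-remainder rounding).  Deterministic given the seed.
    """
    labels = np.asarray(labels, dtype=np.int64)
    n = labels.size
    if n < 10:
        raise ValueError(f"cannot honor a {spec.train_fraction:.0%} split with {n} epochs")
    rng = np.random.default_rng(spec.seed)
    n_train = int(round(spec.train_fraction * n))
    if not spec.stratified:
        perm = rng.permutation(n)
        return np.sort(perm[:n_train]), np.sort(perm[n_train:])
    train_parts: list[np.ndarray] = []
    quotas = []
    classes = [c for c in range(N_STAGES) if (labels == c).any()]
    for c in classes:
        exact = spec.train_fraction * (labels == c).sum()
        quotas.append([int(np.floor(exact)), exact - np.floor(exact), c])
    deficit = n_train - sum(q[0] for q in quotas)
    for q in sorted(quotas, key=lambda q: -q[1])[: int(deficit)]:
        q[0] += 1
    for base, _, c in quotas:
        idx = np.flatnonzero(labels == c)
        perm = rng.permutation(idx)
        train_parts.append(perm[:base])
    train_idx = np.sort(np.concatenate(train_parts))
    mask = np.ones(n, dtype=bool)
    mask[train_idx] = False
    return train_idx, np.flatnonzero(mask)


def oversample_indices(labels: np.ndarray, seed: int = 0) -> np.ndarray:
    """Balance class counts by random duplication with replacement.

    Returns the original indices followed by duplicated minority-class
    indices so that every class matches the majority count.  An
    already-balanced input comes back unchanged.  A class with zero
    training epochs is an error (nothing to duplicate).
    """
    labels = np.asarray(labels, dtype=np.int64)
    counts = np.bincount(labels, minlength=N_STAGES)
    present = np.flatnonzero(counts)
    if present.size == 0:
        raise ValueError("empty training set")
    zero = [STAGE_NAMES[c] for c in range(N_STAGES) if counts[c] == 0]
    if zero:
        raise ValueError(f"cannot oversample: no training epochs for class(es) {zero}")
    majority = int(counts.max())
    rng = np.random.default_rng(seed)
    extra: list[np.ndarray] = []
    for c in range(N_STAGES):
        deficit = majority - counts[c]
        if deficit > 0:
            pool = np.flatnonzero(labels == c)
            extra.append(rng.choice(pool, size=deficit, replace=True))
    if not extra:
        return np.arange(labels.size)
    return np.concatenate([np.arange(labels.size)] + extra)


def oversample(train_set, seed: int = 0):
    """Oversample an EpochDataset (or (X, y) pair) to balanced class counts."""
    from .preprocess import EpochDataset

    if isinstance(train_set, EpochDataset):
        labels = np.array([e.label for e in train_set], dtype=np.int64)
        idx = oversample_indices(labels, seed)
        return EpochDataset(epochs=[train_set.epochs[i] for i in idx])
    X, y = train_set
    idx = oversample_indices(np.asarray(y), seed)
    return X[idx], np.asarray(y)[idx]


@dataclass
class TrainResult:
    """Trained model plus its per-epoch loss trace."""

    model: object
    loss_trace: list[float] = field(default_factory=list)


class _SGD:
    """SGD with momentum over named parameter groups."""

    def __init__(self, groups: dict[str, list], lrs: dict[str, float], momentum: float) -> None:
        self.groups = groups
        self.lrs = lrs
        self.momentum = momentum
        self.velocity: dict[int, np.ndarray] = {}

    def step(self) -> None:
        for gname, items in self.groups.items():
            lr = self.lrs[gname]
            if lr == 0:
                continue
            for layer, key in items:
                g = layer.grads.get(key)
                if g is None:
                    continue
                vkey = (id(layer), key)
                v = self.velocity.get(vkey)
                v = self.momentum * v - lr * g if v is not None else -lr * g
                self.velocity[vkey] = v
                layer.params[key] += v.astype(layer.params[key].dtype)


def train_model(model, images: np.ndarray, labels: np.ndarray, cfg: TrainConfig) -> TrainResult:
    """Minimize cross-entropy with mini-batch SGD.

    ``images`` is (N, 224, 224, 3) in [0, 1]; ``labels`` the stage codes.
    The loss trace records the mean training loss per pass.  Oversampling,
    when enabled, is applied to the training arrays here (never to any
    evaluation data, which this function does not see).
    """
    from .nets.layers import softmax_xent

    labels = np.asarray(labels, dtype=np.int64)
    if cfg.oversample:
        idx = oversample_indices(labels, seed=cfg.seed + 1)
    else:
        idx = np.arange(labels.size)
    rng = np.random.default_rng(cfg.seed)
    groups = model.parameter_groups()
    lrs = {"head": cfg.lr,
           "backbone": 0.0 if model.config.freeze_backbone else cfg.backbone_lr}
    opt = _SGD(groups, lrs, cfg.momentum)
    trace: list[float] = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(idx)
        losses = []
        for start in range(0, order.size, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            logits = model.logits(images[sel], train=True)
            loss, dlogits = softmax_xent(logits, labels[sel])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged: non-finite loss at pass {epoch}, batch {start // cfg.batch_size}"
                )
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        trace.append(float(np.mean(losses)))
        logger.info("pass %d/%d: loss %.4f", epoch + 1, cfg.max_epochs, trace[-1])
    return TrainResult(model=model, loss_trace=trace)


def kfold_folds(n: int, cv: CVSpec) -> list[np.ndarray]:
    """Pairwise disjoint, exhaustive folds with sizes differing by <= 1."""
    if n < cv.k:
        raise ValueError(f"cannot make {cv.k} folds from {n} epochs")
    rng = np.random.default_rng(cv.seed)
    return [np.sort(f) for f in np.array_split(rng.permutation(n), cv.k)]


def kfold_cv(labels: np.ndarray, cv: CVSpec, train_fn, eval_fn,
             oversample_train: bool = True) -> tuple[list[PerClassMetrics], CVSummary]:
    """k-fold cross-validation driver.

    ``train_fn(train_idx)`` builds and fits a model on the (optionally
    oversampled) training indices and returns it; ``eval_fn(model,
    test_idx)`` returns predicted labels for the held-out fold.  Only the
    training portion is ever oversampled; evaluation folds keep their
    original composition.
    """
    labels = np.asarray(labels, dtype=np.int64)
    folds = kfold_folds(labels.size, cv)
    per_fold: list[PerClassMetrics] = []
    for i, test_idx in enumerate(folds):
        mask = np.ones(labels.size, dtype=bool)
        mask[test_idx] = False
        train_idx = np.flatnonzero(mask)
        if oversample_train:
            local = oversample_indices(labels[train_idx], seed=cv.seed * 100_003 + i)
            train_idx = train_idx[local]
        model = train_fn(train_idx)
        pred = np.asarray(eval_fn(model, test_idx))
        cm = confusion(labels[test_idx], pred)
        per_fold.append(per_class_metrics(cm))
        logger.info("fold %d/%d done", i + 1, cv.k)
    return per_fold, cv_summary(per_fold)
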