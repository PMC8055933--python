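"""Patient-stratified cross-validation training of the gated-attention net.

Folds partition *patients*, never patches, so patches from one subject can
never appear in both training and validation.  Class imbalance is handled by
an inverse-frequency weighted sampler (with replacement); augmentation flips
the left-right axis and adds Gaussian noise; optimization is AdamW with a
reduce-on-plateau schedule on the validation loss.  By default the
checkpoint with the best validation AUC is kept (latest among ties) and its
metrics reported, together with the mean attention over correctly predicted
validation samples; null experiments evaluate the final epoch instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from ._nn import AdamW
from .network import ArchitectureSpec, GatedAttentionNet

log = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "Metrics",
    "FoldResult",
    "split_by_patient",
    "class_balance_weights",
    "augment",
    "evaluate",
    "train_fold",
    "cross_validate",
]


@dataclass
class TrainConfig:
    batch_size: int = 256
    learning_rate: float = 5e-5
    weight_decay: float = 1e-2
    scheduler_patience: int = 15
    scheduler_factor: float = 0.5
    max_epochs: int = 200
    early_stop_patience: int = 40
    flip_prob: float = 0.5
    noise_sd: float = 1.0
    n_folds: int = 5
    #: spatial axis flipped by augmentation (0 = first spatial axis)
    flip_axis: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.weight_decay < 0 or self.batch_size < 1:
            raise ValueError("rates and batch size must be positive")
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")


@dataclass
class Metrics:
    auc: float
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    f1: float


@dataclass
class FoldResult:
    fold_index: int
    metrics: Metrics
    mean_attention_correct: np.ndarray
    n_train: int
    n_val: int
    best_epoch: int
    history: list = field(default_factory=list)
    checkpoint: dict | None = None


def split_by_patient(subject_ids, n_folds: int, seed: int) -> dict[str, int]:
    """Deterministic partition of subjects into near-equal folds."""
    unique = np.unique(np.asarray(subject_ids))
    if len(unique) < n_folds:
        raise ValueError(f"{len(unique)} subjects cannot fill {n_folds} folds")
    order = np.random.default_rng(seed).permutation(len(unique))
    assignment = {}
    for fold, chunk in enumerate(np.array_split(unique[order], n_folds)):
        for sid in chunk:
            assignment[str(sid)] = fold
    return assignment


def class_balance_weights(labels: np.ndarray) -> np.ndarray:
    """Inverse-class-frequency sampling weights, renormalized to mean one."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    per_class = {c: len(labels) / (len(classes) * n) for c, n in zip(classes, counts)}
    w = np.array([per_class[y] for y in labels], dtype=np.float64)
    return w / w.mean()


def augment(x: np.ndarray, rng: np.random.Generator,
            flip_prob: float = 0.5, noise_sd: float = 1.0, flip_axis: int = 0) -> np.ndarray:
    """Random left-right flip (all contrasts of a sample together) + noise.

    ``x``: (N, n_contrasts, p, p, p).  The flip reverses one spatial axis
    identically across contrasts; Gaussian noise is i.i.d. per voxel.
    """
    out = x.copy()
    ax = 2 + flip_axis
    if flip_prob > 0:
        flips = rng.random(len(out)) < flip_prob
        out[flips] = np.flip(out[flips], axis=ax)
    if noise_sd > 0:
        noise = rng.standard_normal(out.shape, dtype=np.float32)
        if noise_sd != 1.0:
            noise *= noise_sd
        out += noise.astype(out.dtype, copy=False)
    return out


def evaluate(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> Metrics:
    """AUC plus thresholded confusion metrics.

    Balanced accuracy is the mean of sensitivity and specificity; F1 the
    harmonic mean of precision and recall (0 when undefined).
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present in labels")
    auc = float(roc_auc_score(labels, scores))
    pred = np.asarray(scores) >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return Metrics(auc=auc, balanced_accuracy=(sens + spec) / 2.0,
                   sensitivity=sens, specificity=spec, f1=f1)


def _bce(prob: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(prob, 1e-7, 1 - 1e-7)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def train_fold(X_train: np.ndarray, y_train: np.ndarray,
               X_val: np.ndarray, y_val: np.ndarray,
               arch: ArchitectureSpec, config: TrainConfig,
               fold_index: int = 0, keep_checkpoint: bool = True,
               checkpoint_policy: str = "best") -> FoldResult:
    """Train one fold and report checkpoint metrics and mean attention.

    ``checkpoint_policy='best'`` reports the best-validation-AUC epoch
    (latest among ties); ``'final'`` reports the last epoch.  Null
    experiments should use ``'final'``: selecting the best of several noisy
    AUC estimates is upward-biased even when no signal exists.
    """
    if checkpoint_policy not in ("best", "final"):
        raise ValueError("checkpoint_policy must be 'best' or 'final'")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, fold_index)))
    model_seed = int(rng.integers(2 ** 31))
    net = GatedAttentionNet(arch, seed=model_seed)
    opt = AdamW(net.parameters(), lr=config.learning_rate,
                weight_decay=config.weight_decay)
    weights = class_balance_weights(y_train)
    prob_w = weights / weights.sum()
    n = len(y_train)
    s = arch.spatial_size

    Xv = X_val.reshape(len(X_val), arch.n_contrasts, s).astype(np.float32)
    best_auc, best_epoch, best_state = -np.inf, -1, None
    best_loss, plateau, stall = np.inf, 0, 0
    history = []
    for epoch in range(config.max_epochs):
        idx = rng.choice(n, size=n, replace=True, p=prob_w)
        for start in range(0, n, config.batch_size):
            batch = idx[start:start + config.batch_size]
            xb = augment(X_train[batch], rng, config.flip_prob, config.noise_sd,
                         config.flip_axis)
            xb = xb.reshape(len(batch), arch.n_contrasts, s)
            net.zero_grad()
            loss, _ = net.loss_and_grad(xb, y_train[batch], training=True)
            if not np.isfinite(loss):
                raise FloatingPointError(f"training diverged at epoch {epoch} (loss={loss})")
            opt.step(net.gradients())
        probs, _ = net.predict(Xv)
        val_loss = _bce(probs, y_val)
        val_auc = float(roc_auc_score(y_val, probs))
        history.append({"epoch": epoch, "val_loss": val_loss, "val_auc": val_auc,
                        "lr": opt.lr})
        # >= so that among AUC ties the latest (most-converged) epoch wins;
        # attention keeps differentiating after the AUC saturates
        if val_auc >= best_auc:
            best_auc, best_epoch = val_auc, epoch
            best_state = net.state_dict()
            stall = 0
        else:
            stall += 1
        if val_loss < best_loss - 1e-6:
            best_loss, plateau = val_loss, 0
        else:
            plateau += 1
            if plateau > config.scheduler_patience:
                opt.lr *= config.scheduler_factor
                plateau = 0
        if stall > config.early_stop_patience:
            break
    if checkpoint_policy == "best":
        net.load_state_dict(best_state)
        report_epoch = best_epoch
    else:
        report_epoch = epoch
    probs, attn = net.predict(Xv)
    metrics = evaluate(probs, y_val)
    correct = (probs >= 0.5).astype(int) == y_val
    if not correct.any():
        raise RuntimeError("no correctly predicted validation samples in fold")
    mean_attn = attn[correct].mean(axis=0)
    return FoldResult(fold_index=fold_index, metrics=metrics,
                      mean_attention_correct=mean_attn,
                      n_train=len(y_train), n_val=len(y_val),
                      best_epoch=report_epoch, history=history,
                      checkpoint=net.state_dict() if keep_checkpoint else None)


def cross_validate(X: np.ndarray, y: np.ndarray, subject_ids: np.ndarray,
                   arch: ArchitectureSpec, config: TrainConfig,
                   keep_checkpoints: bool = False) -> list[FoldResult]:
    """Patient-level k-fold cross-validation; returns one FoldResult per fold."""
    assignment = split_by_patient(subject_ids, config.n_folds, config.seed)
    folds = np.array([assignment[str(s)] for s in subject_ids])
    results = []
    for f in range(config.n_folds):
        tr, va = folds != f, folds == f
        assert not set(subject_ids[tr]) & set(subject_ids[va])
        res = train_fold(X[tr], y[tr], X[va], y[va], arch, config,
                         fold_index=f, keep_checkpoint=keep_checkpoints)
        log.info("fold %d: AUC %.3f (best epoch %d, %d train / %d val patches)",
                 f, res.metrics.auc, res.best_epoch, res.n_train, res.n_val)
        results.append(res)
    return results
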