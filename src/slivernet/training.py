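"""Training protocol: splitting, learning-rate finding, fitting with early
stopping, auxiliary pretraining, and the transfer fine-tuning recipe.

The protocol follows the method's published recipe: Adam with default
moments and weight decay 0.01, batch size 32, early stopping after 20
epochs without validation improvement, best-validation checkpointing, a
learning-rate finder sweeping [1e-7, 1.0], auxiliary pretraining at lr 1e-3
for up to 50 epochs, and whole-network fine-tuning at lr 1e-5. All of those
are defaults on :class:`TrainConfig` and scale down for small models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .nn.losses import softmax_cross_entropy
from .nn.optim import SGD, Adam
from . import nn as _nn
from .sliver_model import BackboneConfig, BackboneModel, SliverNet
from .volume_data import VolumeDataset


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    weight_decay: float = 0.01
    batch_size: int = 32
    patience_epochs: int = 20
    max_epochs: int = 100
    seed: int = 0
    finetune_learning_rate: float = 1e-5
    aux_learning_rate: float = 1e-3
    aux_max_epochs: int = 50
    # optional prevalence-based positive weighting for the multi-label BCE
    # (off by default); an array of per-task weights when enabled
    pos_weight: object = None
    # optional label-preserving augmentation (horizontal flips, slice-order
    # reversal, small lateral shifts); off by default
    augment: bool = False
    # epoch budget for the whole-network fine-tune phase (None: reuse max_epochs)
    finetune_max_epochs: int | None = None

    def __post_init__(self):
        if self.batch_size < 1 or self.patience_epochs < 1 or self.learning_rate <= 0:
            raise ValueError("batch size, patience, and learning rate must be positive")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")


@dataclass
class TrainHistory:
    """Per-epoch losses and the checkpointed (best-validation) epoch."""

    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    checkpoint_epoch: int = -1

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(self.n_epochs),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
            }
        )


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_train_val(dataset: VolumeDataset, fraction: float = 0.8, seed: int = 0):
    """Random subject-level split into (train, validation).

    All volumes of a subject land on the same side, preventing leakage from
    the two-volumes-per-patient acquisition. Proportions are applied to
    subjects and are within one subject of the target.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly inside (0, 1)")
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    subjects = sorted(set(dataset.subject_ids))
    if len(subjects) < 2:
        raise ValueError("cannot split a single-subject dataset")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    n_train = int(round(fraction * len(subjects)))
    n_train = min(max(n_train, 1), len(subjects) - 1)
    train_subjects = {subjects[i] for i in order[:n_train]}
    tr = [i for i, s in enumerate(dataset.subject_ids) if s in train_subjects]
    va = [i for i, s in enumerate(dataset.subject_ids) if s not in train_subjects]
    return dataset.subset(tr), dataset.subset(va)


# ---------------------------------------------------------------------------
# Generic batch plumbing (models follow the forward_loss/backward protocol)
# ---------------------------------------------------------------------------

def _as_batches(x, y, batch_size, order):
    for start in range(0, len(order), batch_size):
        idx = order[start : start + batch_size]
        xb = np.stack([x[i] for i in idx])
        yb = y[idx]
        yield xb, yb


def _augment_batch(xb, rng):
    """Label-preserving augmentation: lateral flip, slice-order reversal
    (volumes only), and a small lateral roll, each decided per sample."""
    xb = xb.copy()
    for i in range(len(xb)):
        if rng.uniform() < 0.5:
            xb[i] = xb[i][..., ::-1]
        if xb.ndim == 4 and rng.uniform() < 0.5:
            xb[i] = xb[i][::-1]
        shift = int(rng.integers(-3, 4))
        if shift:
            xb[i] = np.roll(xb[i], shift, axis=-1)
    return xb


def _dataset_xy(ds):
    if isinstance(ds, VolumeDataset):
        return ds.volumes, ds.labels
    x, y = ds  # (images, labels) tuple for 2D auxiliary sets
    return x, np.asarray(y)


def _loss_kwargs(cfg):
    return {} if cfg is None or cfg.pos_weight is None else {"pos_weight": cfg.pos_weight}


def _eval_loss(model, ds, batch_size, cfg=None):
    x, y = _dataset_xy(ds)
    total, n = 0.0, 0
    kw = _loss_kwargs(cfg)
    for xb, yb in _as_batches(x, y, batch_size, np.arange(len(x))):
        total += model.forward_loss(xb, yb, train=False, **kw) * len(xb)
        n += len(xb)
    return total / max(n, 1)


# ---------------------------------------------------------------------------
# Learning-rate finder
# ---------------------------------------------------------------------------

def find_learning_rate(
    model,
    train_set,
    sweep: tuple[float, float] = (1e-7, 1.0),
    num_iters: int = 50,
    cfg: TrainConfig | None = None,
    optimizer: str = "adam",
    seed: int = 0,
) -> float:
    """Exponential learning-rate sweep; returns the lr at the steepest
    smoothed loss decrease, clamped to the sweep range.

    Losses are smoothed with an exponential moving average (factor 0.98,
    bias-corrected); the sweep aborts once the smoothed loss exceeds 4x its
    minimum. Model weights are restored afterwards.
    """
    cfg = cfg or TrainConfig()
    x, y = _dataset_xy(train_set)
    if len(x) < 1:
        raise ValueError("need at least one batch")
    lo, hi = sweep
    init_state = {k: v.copy() for k, v in model.state_dict().items()}
    params = model.trainable_parameters()
    opt = (
        Adam(params, lr=lo, weight_decay=cfg.weight_decay)
        if optimizer == "adam"
        else SGD(params, lr=lo)
    )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(x))
    lrs = np.geomspace(lo, hi, num_iters)
    smoothed, raw_lrs = [], []
    ema, beta = 0.0, 0.98
    pos = 0
    for t, lr in enumerate(lrs):
        if pos + cfg.batch_size > len(order):
            order = rng.permutation(len(x))
            pos = 0
        idx = order[pos : pos + cfg.batch_size]
        pos += cfg.batch_size
        xb = np.stack([x[i] for i in idx])
        loss = model.forward_loss(xb, y[idx], train=True)
        if not np.isfinite(loss):
            break
        ema = beta * ema + (1 - beta) * loss
        smoothed.append(ema / (1 - beta ** (t + 1)))
        raw_lrs.append(lr)
        if len(smoothed) > 5 and smoothed[-1] > 4.0 * min(smoothed):
            break
        opt.zero_grad()
        model.backward_from_loss()
        opt.lr = lr
        opt.step()
    model.load_state_dict(init_state)
    if len(smoothed) < 3:
        warnings.warn("loss diverged immediately; returning sweep minimum")
        return lo
    grads = np.gradient(np.asarray(smoothed), np.log(np.asarray(raw_lrs)))
    best = int(np.argmin(grads))
    return float(np.clip(raw_lrs[best], lo, hi))


# ---------------------------------------------------------------------------
# Fit with early stopping and best-validation checkpointing
# ---------------------------------------------------------------------------

def fit(model, train_set, val_set, cfg: TrainConfig):
    """Train until validation loss stops improving for ``patience_epochs``.

    Returns (model restored to the best-validation weights, TrainHistory).
    Shuffling is seeded; a non-finite loss aborts with diagnostics.
    """
    x, y = _dataset_xy(train_set)
    if len(x) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(
        model.trainable_parameters(),
        lr=cfg.learning_rate,
        weight_decay=cfg.weight_decay,
    )
    history = TrainHistory()
    best_val, best_state, best_epoch = np.inf, None, -1
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(x))
        total, seen = 0.0, 0
        kw = _loss_kwargs(cfg)
        for xb, yb in _as_batches(x, y, cfg.batch_size, order):
            if cfg.augment:
                xb = _augment_batch(xb, rng)
            loss = model.forward_loss(xb, yb, train=True, **kw)
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite training loss at epoch {epoch} after {seen} samples"
                )
            opt.zero_grad()
            model.backward_from_loss()
            opt.step()
            total += loss * len(xb)
            seen += len(xb)
        val = _eval_loss(model, val_set, cfg.batch_size, cfg)
        if not np.isfinite(val):
            raise TrainingDiverged(f"non-finite validation loss at epoch {epoch}")
        history.train_loss.append(total / seen)
        history.val_loss.append(float(val))
        if val < best_val:
            best_val, best_epoch = val, epoch
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
        if epoch - best_epoch >= cfg.patience_epochs:
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    history.checkpoint_epoch = best_epoch
    return model, history


# ---------------------------------------------------------------------------
# Auxiliary pretraining (step 1 of the transfer protocol)
# ---------------------------------------------------------------------------

class AuxiliaryClassifier(_nn.Module):
    """Backbone + temporary K-way decision layer for the auxiliary 2D task."""

    def __init__(self, backbone_cfg: BackboneConfig, n_classes: int, seed: int = 0):
        ss = np.random.SeedSequence(seed).spawn(2)
        self.backbone = BackboneModel(backbone_cfg, seed=ss[0].generate_state(1)[0] % 2**31)
        rng = np.random.default_rng(ss[1].generate_state(1)[0] % 2**31)
        self.fc = _nn.Linear(backbone_cfg.output_channels, n_classes, rng=rng)
        self._cache = None

    def forward(self, x, train: bool = False):
        x = np.asarray(x)
        if x.dtype == np.uint8:
            x = x.astype(np.float32) / 255.0
        if x.ndim == 3:
            x = x[:, None]
        feats = self.backbone.forward(x.astype(np.float32), train=train)
        pooled = feats.mean(axis=(2, 3))
        if train:
            self._cache = feats.shape
        return self.fc.forward(pooled, train=train)

    def backward(self, dlogits):
        feats_shape = self._cache
        dpooled = self.fc.backward(dlogits)
        hw = feats_shape[2] * feats_shape[3]
        dfeats = np.broadcast_to(
            dpooled[:, :, None, None] / hw, feats_shape
        ).astype(np.float32)
        self._cache = None
        return self.backbone.backward(np.ascontiguousarray(dfeats))

    def forward_loss(self, xb, yb, train: bool = True):
        logits = self.forward(xb, train=train)
        loss, dlogits = softmax_cross_entropy(logits, np.asarray(yb))
        if train:
            self._dlogits = dlogits
        return loss

    def backward_from_loss(self):
        self.backward(self._dlogits)

    def trainable_parameters(self):
        return self.parameters()


def pretrain_auxiliary(
    backbone_cfg: BackboneConfig,
    aux_set,
    lr: float = 1e-3,
    max_epochs: int = 50,
    cfg: TrainConfig | None = None,
    seed: int = 0,
) -> dict:
    """Train backbone + temporary K-way head on the auxiliary 2D set.

    Returns the backbone weights only (the auxiliary decision layer is
    discarded). The auxiliary set is split 80/20 internally for the early
    stopping rule.
    """
    images, labels = aux_set
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("auxiliary set must contain at least two classes")
    cfg = cfg or TrainConfig()
    cfg = replace(cfg, learning_rate=lr, max_epochs=max_epochs, seed=seed)
    model = AuxiliaryClassifier(backbone_cfg, n_classes=int(classes.max()) + 1, seed=seed)
    if max_epochs == 0:
        return model.backbone.state_dict()
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(images))
    n_val = max(int(round(0.2 * len(images))), 1)
    va, tr = order[:n_val], order[n_val:]
    train_set = ([images[i] for i in tr], labels[tr])
    val_set = ([images[i] for i in va], labels[va])
    model, _ = fit(model, train_set, val_set, cfg)
    return model.backbone.state_dict()


# ---------------------------------------------------------------------------
# Transfer fine-tuning (steps 3-5 of the protocol)
# ---------------------------------------------------------------------------

def transfer_finetune(
    pretrained_backbone: dict,
    train_set: VolumeDataset,
    val_set: VolumeDataset,
    cfg: TrainConfig,
    backbone_cfg: BackboneConfig,
    head_hidden: int = 1024,
):
    """Attach a fresh aggregator+head to a pretrained backbone and fine-tune.

    Phase A trains only the new layers with the backbone frozen (backbone
    weights are bit-identical before and after). Phase B then updates the
    whole network at the reduced ``cfg.finetune_learning_rate``. Each phase
    uses :func:`fit`'s early stopping. Returns (model, {phase: history}).
    """
    model = SliverNet(backbone_cfg, head_hidden=head_hidden, seed=cfg.seed)
    model.backbone.load_state_dict(pretrained_backbone)

    model.freeze_backbone = True
    before = model.backbone.state_dict()
    model, hist_a = fit(model, train_set, val_set, cfg)
    after = model.backbone.state_dict()
    for k in before:
        if not np.array_equal(before[k], after[k]):
            raise AssertionError(f"backbone parameter {k} changed during frozen phase")

    model.freeze_backbone = False
    cfg_b = replace(
        cfg,
        learning_rate=cfg.finetune_learning_rate,
        seed=cfg.seed + 1,
        max_epochs=cfg.max_epochs if cfg.finetune_max_epochs is None else cfg.finetune_max_epochs,
    )
    model, hist_b = fit(model, train_set, val_set, cfg_b)
    return model, {"frozen_head": hist_a, "finetune_all": hist_b}
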