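"""Scaled-down study recipes shared by the test suite, the CLI and the
acceptance script.

These bundle the full protocol — synthetic cohort generation, preprocessing,
auxiliary pretraining, transfer fine-tuning vs. training from scratch, and
held-out evaluation — at sizes a single CPU handles in minutes: the spec's
small volume preset (16 slices of 64x64), a 32x32 network input, the small
residual backbone (C=16), 200 training volumes, 300 test volumes and a
400-image auxiliary set. Sizes and prevalences are study conditions, not
tuning knobs; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import ScoredSet, mean_auroc, roc_auc, SingleClassError
from .sliver_model import BackboneConfig, SliverNet
from .synthetic import SyntheticSpec, generate_auxiliary_2d, generate_dataset
from .training import TrainConfig, fit, pretrain_auxiliary, split_train_val, transfer_finetune
from .volume_data import BIOMARKERS, RawVolume, VolumeDataset, preprocess_volume

SMALL_INPUT = (48, 48)
SMALL_HEAD_HIDDEN = 32


@dataclass
class SmallStudyConfig:
    """Problem sizes and protocol settings for the scaled transfer study."""

    n_train: int = 200
    n_test: int = 300
    n_aux: int = 400
    spec: SyntheticSpec = field(default_factory=SyntheticSpec)
    input_size: tuple = SMALL_INPUT
    backbone: BackboneConfig = field(default_factory=BackboneConfig.small)
    head_hidden: int = SMALL_HEAD_HIDDEN
    learning_rate: float = 3e-3
    max_epochs: int = 45
    patience: int = 15
    aux_max_epochs: int = 30
    finetune_max_epochs: int = 10  # phase B at the protocol rate 1e-5
    use_pos_weight: bool = True  # prevalence-based BCE positive weighting


def preprocess_dataset(ds: VolumeDataset, target=SMALL_INPUT) -> VolumeDataset:
    """Resample + contrast-enhance every volume in a dataset."""
    return ds.map_volumes(
        lambda arr: preprocess_volume(RawVolume(slices=np.asarray(arr)), target=target).data
    )


def _pos_weight(labels: np.ndarray, cap: float = 25.0) -> np.ndarray:
    npos = labels.sum(axis=0)
    w = (len(labels) - npos) / np.maximum(npos, 1)
    return np.clip(w, 1.0, cap)


def _train_cfg(study: SmallStudyConfig, seed: int, lr=None, max_epochs=None,
               train_labels=None) -> TrainConfig:
    pw = None
    if study.use_pos_weight and train_labels is not None:
        pw = _pos_weight(np.asarray(train_labels))
    return TrainConfig(
        learning_rate=lr if lr is not None else study.learning_rate,
        batch_size=32,
        patience_epochs=study.patience,
        max_epochs=max_epochs if max_epochs is not None else study.max_epochs,
        seed=seed,
        pos_weight=pw,
        augment=True,
        finetune_max_epochs=study.finetune_max_epochs,
    )


def make_study_data(study: SmallStudyConfig, seed: int):
    """Generate and preprocess the train and held-out test cohorts.

    The subject pools are disjoint by construction (independent draws from
    separate seed streams), mirroring an external-validation layout.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    train_raw, _ = generate_dataset(study.spec, study.n_train, seed=ss[0])
    test_raw, _ = generate_dataset(study.spec, study.n_test, seed=ss[1])
    test_raw.volume_ids = [f"T{i:05d}" for i in range(len(test_raw))]
    test_raw.subject_ids = [f"TS{i // 2:05d}" for i in range(len(test_raw))]
    return (
        preprocess_dataset(train_raw, study.input_size),
        preprocess_dataset(test_raw, study.input_size),
        ss[2],
    )


def score_dataset(model, ds: VolumeDataset, batch_size: int = 32) -> ScoredSet:
    scores = []
    for start in range(0, len(ds), batch_size):
        xb = np.stack(ds.volumes[start : start + batch_size])
        scores.append(model.predict(xb))
    return ScoredSet(
        scores=np.vstack(scores), labels=ds.labels, volume_ids=list(ds.volume_ids)
    )


def train_scratch(study: SmallStudyConfig, train_ds, val_ds, seed: int):
    model = SliverNet(study.backbone, head_hidden=study.head_hidden, seed=seed)
    return fit(model, train_ds, val_ds, _train_cfg(study, seed, train_labels=train_ds.labels))


def train_pretrained(study: SmallStudyConfig, train_ds, val_ds, seed: int, aux_seed):
    images, aux_labels = generate_auxiliary_2d(study.spec, study.n_aux, classes=4, seed=aux_seed)
    from .volume_data import enhance_contrast, resample_slice

    images = np.stack(
        [enhance_contrast(resample_slice(im, study.input_size)) for im in images]
    )
    backbone_weights = pretrain_auxiliary(
        study.backbone,
        ((images / 255.0).astype(np.float32), aux_labels),
        lr=1e-3,
        max_epochs=study.aux_max_epochs,
        cfg=_train_cfg(study, seed),
        seed=seed,
    )
    cfg = _train_cfg(study, seed, train_labels=train_ds.labels)
    model, hists = transfer_finetune(
        backbone_weights,
        train_ds,
        val_ds,
        cfg,
        backbone_cfg=study.backbone,
        head_hidden=study.head_hidden,
    )
    return model, hists


def transfer_vs_scratch_study(seed: int, study: SmallStudyConfig | None = None) -> dict:
    """One seed of the transfer-benefit experiment.

    Returns per-arm mean AUROC over the 5 biomarker analogs plus the AUROC of
    the peripheral-only rpd analog, all on the held-out cohort.
    """
    study = study or SmallStudyConfig()
    train_pre, test_pre, aux_seed = make_study_data(study, seed)
    tr, va = split_train_val(train_pre, 0.8, seed=seed)

    scratch_model, _ = train_scratch(study, tr, va, seed)
    scratch_scored = score_dataset(scratch_model, test_pre)

    pre_model, _ = train_pretrained(study, tr, va, seed, aux_seed)
    pre_scored = score_dataset(pre_model, test_pre)

    out = {"seed": seed}
    rpd_k = BIOMARKERS.index("rpd")
    for arm, scored in (("scratch", scratch_scored), ("pretrained", pre_scored)):
        out[f"mean_auroc_{arm}"] = mean_auroc(scored)
        try:
            out[f"rpd_auroc_{arm}"] = roc_auc(scored.scores[:, rpd_k], scored.labels[:, rpd_k])
        except SingleClassError:
            out[f"rpd_auroc_{arm}"] = float("nan")
        out[f"scored_{arm}"] = scored
    return out


def make_sweep_protocol(study: SmallStudyConfig | None = None):
    """A (train_ds, test_ds, seed) -> ScoredSet protocol for acquisition sweeps.

    Inputs are raw datasets; the protocol preprocesses, splits by subject,
    trains a small network from scratch and scores the test cohort.
    """
    study = study or SmallStudyConfig()

    def protocol(train_ds, test_ds, seed):
        train_pre = preprocess_dataset(train_ds, study.input_size)
        test_pre = preprocess_dataset(test_ds, study.input_size)
        tr, va = split_train_val(train_pre, 0.8, seed=seed)
        model, _ = train_scratch(study, tr, va, seed)
        return score_dataset(model, test_pre)

    return protocol
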