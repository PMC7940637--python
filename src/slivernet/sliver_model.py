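"""SLIVER-net architecture and baselines.

The model turns a preprocessed volume into five biomarker probabilities in
three stages:

1. *Backbone*: an 18-layer-style residual 2D CNN maps each slice (or the
   whole vertical mosaic in one pass) to an h x w x C feature grid. C = 512
   in the standard configuration; the spatial grid is computed from the
   instantiated network, never assumed.
2. *Slice integration*: average- and max-pooling within each slice's grid
   gives an S x 2C matrix, which a small 1D CNN aggregates along the slice
   axis; global average+max pooling over slices yields a fixed-length
   embedding independent of S.
3. *Decision head*: one hidden layer feeding 5 sigmoid outputs (multi-task).

Two baselines isolate the contributions: a 3D residual CNN operating on the
volume directly, and a tiled 2D CNN that pools globally over the mosaic
(i.e., SLIVER-net without slice integration).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn.losses import bce_with_logits, sigmoid
from .volume_data import BIOMARKERS, PreprocessedVolume, tile_volume


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

@dataclass
class BackboneConfig:
    """Residual backbone descriptor; ``small()`` variants keep CPU tests fast."""

    in_channels: int = 3
    stem_channels: int = 64
    stem_kernel: int = 7
    stem_stride: int = 2
    stem_pool: bool = True  # 3x3 stride-2 max pool after the stem
    stage_channels: tuple = (64, 128, 256, 512)
    blocks_per_stage: int = 2
    stage_strides: tuple = (1, 2, 2, 2)

    def __post_init__(self):
        if len(self.stage_channels) != len(self.stage_strides):
            raise ValueError("stage_channels and stage_strides must align")
        if min(self.stage_channels) < 1 or self.blocks_per_stage < 1:
            raise ValueError("invalid backbone widths/depth")

    @property
    def output_channels(self) -> int:
        return self.stage_channels[-1]

    @property
    def total_stride(self) -> int:
        s = self.stem_stride * (2 if self.stem_pool else 1)
        for st in self.stage_strides:
            s *= st
        return s

    def feature_grid_shape(self, height: int, width: int) -> tuple[int, int]:
        """Output spatial dims by per-layer ceil-division stride arithmetic."""
        h, w = height, width
        strides = [self.stem_stride] + ([2] if self.stem_pool else []) + list(self.stage_strides)
        for s in strides:
            h = -(-h // s)
            w = -(-w // s)
        return h, w

    @classmethod
    def standard(cls) -> "BackboneConfig":
        return cls()

    @classmethod
    def small(cls) -> "BackboneConfig":
        return cls(
            in_channels=1,
            stem_channels=8,
            stem_kernel=3,
            stem_stride=2,
            stem_pool=False,
            stage_channels=(12, 16),
            blocks_per_stage=1,
            stage_strides=(2, 2),
        )


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SliceFeatureMaps:
    """Per-slice spatial feature grids: maps is (S, h, w, C)."""

    maps: np.ndarray
    config: BackboneConfig | None = None

    def __post_init__(self):
        if self.maps.ndim != 4:
            raise ValueError("feature maps must be (S, h, w, C)")
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("feature maps must be finite")


@dataclass
class PooledRepresentation:
    """S x 2C matrix: per slice, channel means concatenated with channel maxima."""

    matrix: np.ndarray

    def __post_init__(self):
        if self.matrix.ndim != 2 or self.matrix.shape[1] % 2 != 0:
            raise ValueError("pooled representation must be (S, 2C)")


@dataclass
class VolumeEmbedding:
    vector: np.ndarray

    def __post_init__(self):
        self.vector = np.asarray(self.vector).ravel()
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("embedding must be finite")


@dataclass
class PredictionScores:
    """Per-biomarker probabilities in [0, 1]."""

    scores: dict

    def __post_init__(self):
        for name in BIOMARKERS:
            v = self.scores.get(name)
            if v is None or not 0.0 <= v <= 1.0:
                raise ValueError(f"score for {name} missing or outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.scores[n] for n in BIOMARKERS])


# ---------------------------------------------------------------------------
# Backbone
# ---------------------------------------------------------------------------

class BackboneModel(nn.Module):
    """Residual feature extractor: (N, 1 or in_channels, H, W) -> (N, C, h, w)."""

    def __init__(self, cfg: BackboneConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        stem = [nn.Conv2d(cfg.in_channels, cfg.stem_channels, cfg.stem_kernel,
                          stride=cfg.stem_stride, rng=rng), nn.ReLU()]
        if cfg.stem_pool:
            stem.append(nn.MaxPool2d(3, 2))
        blocks = []
        prev = cfg.stem_channels
        for ch, st in zip(cfg.stage_channels, cfg.stage_strides):
            for b in range(cfg.blocks_per_stage):
                blocks.append(nn.ResidualBlock2d(prev, ch, stride=st if b == 0 else 1, rng=rng))
                prev = ch
        self.net = nn.Sequential(*stem, *blocks)

    def _replicate(self, x: np.ndarray) -> np.ndarray:
        cin = self.cfg.in_channels
        if x.shape[1] == cin:
            return x
        if x.shape[1] == 1:
            return np.repeat(x, cin, axis=1)
        raise ValueError(f"expected 1 or {cin} input channels, got {x.shape[1]}")

    def forward(self, x, train: bool = False):
        x = self._replicate(np.asarray(x, dtype=np.float32))
        self._replicated = x.shape[1] != 1
        return self.net.forward(x, train=train)

    def backward(self, dy):
        dx = self.net.backward(dy)
        if self.cfg.in_channels > 1:
            dx = dx.sum(axis=1, keepdims=True)
        return dx

    @property
    def output_channels(self) -> int:
        return self.cfg.output_channels


def build_backbone(cfg: BackboneConfig, pretrained_weights: dict | None = None,
                   seed: int = 0) -> BackboneModel:
    """Instantiate the backbone, optionally loading a pretrained weight store."""
    model = BackboneModel(cfg, seed=seed)
    if pretrained_weights is not None:
        model.load_state_dict(pretrained_weights)
    return model


# ---------------------------------------------------------------------------
# Stage operations (reference semantics; also usable standalone)
# ---------------------------------------------------------------------------

def _as_input_batch(v) -> np.ndarray:
    """PreprocessedVolume or (S, H, W) array -> (S, 1, H, W) float32 in [0, 1]."""
    data = v.data if isinstance(v, PreprocessedVolume) else np.asarray(v)
    return (data.astype(np.float32) / 255.0)[:, None, :, :]


def extract_slice_features(model: BackboneModel, v, mode: str = "per_slice") -> SliceFeatureMaps:
    """Run the backbone over a volume and return S per-slice feature grids.

    ``per_slice`` (reference semantics) applies the backbone to each slice
    independently. ``tiled`` applies it once to the vertical mosaic and cuts
    the output grid back into S blocks of equal height — one forward pass,
    with possible convolutional leakage across tile seams on boundary rows.
    """
    if not isinstance(v, PreprocessedVolume):
        v = PreprocessedVolume(data=np.asarray(v))
    s = v.n_slices
    if mode == "per_slice":
        feats = model.forward(_as_input_batch(v))  # (S, C, h, w)
        maps = feats.transpose(0, 2, 3, 1)
    elif mode == "tiled":
        mosaic = tile_volume(v).data.astype(np.float32) / 255.0
        feats = model.forward(mosaic[None, None, :, :])[0]  # (C, Hm, w)
        if feats.shape[1] % s != 0:
            raise ValueError(
                f"mosaic feature rows {feats.shape[1]} not divisible by {s} slices"
            )
        h = feats.shape[1] // s
        maps = feats.reshape(feats.shape[0], s, h, feats.shape[2]).transpose(1, 2, 3, 0)
    else:
        raise ValueError(f"unknown extraction mode {mode!r}")
    return SliceFeatureMaps(maps=np.ascontiguousarray(maps), config=model.cfg)


def pool_slice_features(f: SliceFeatureMaps) -> PooledRepresentation:
    """Average+max pool each slice's h x w grid per channel -> (S, 2C)."""
    avg = f.maps.mean(axis=(1, 2))
    mx = f.maps.max(axis=(1, 2))
    return PooledRepresentation(matrix=np.concatenate([avg, mx], axis=1))


class AggregatorModel(nn.Module):
    """Small 1D CNN along the slice axis: 2C -> C -> C, kernel 3, same padding.

    Global average+max pooling over slices afterwards makes the embedding
    length (2C) independent of the slice count.
    """

    def __init__(self, in_width: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        if in_width % 2 != 0:
            raise ValueError("aggregator input width must be 2C")
        c = in_width // 2
        self.in_width = in_width
        self.channels = c
        self.conv1 = nn.Conv1d(in_width, c, 3, rng=rng)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv1d(c, c, 3, rng=rng)
        self.relu2 = nn.ReLU()
        self._cache = None

    @property
    def embedding_length(self) -> int:
        return 2 * self.channels

    def forward(self, x, train: bool = False):
        """(N, 2C, S) -> (N, 2C) embedding."""
        if x.shape[1] != self.in_width:
            raise ValueError(f"aggregator built for width {self.in_width}, got {x.shape[1]}")
        y = self.relu1.forward(self.conv1.forward(x, train), train)
        z = self.relu2.forward(self.conv2.forward(y, train), train)
        gavg = z.mean(axis=2)
        amax = z.argmax(axis=2)
        gmax = np.take_along_axis(z, amax[:, :, None], axis=2)[:, :, 0]
        if train:
            self._cache = (z.shape, amax)
        return np.concatenate([gavg, gmax], axis=1)

    def backward(self, dy):
        (n, c, s), amax = self._cache
        dz = np.repeat(dy[:, :c, None] / s, s, axis=2)
        ni, ci = np.ogrid[0:n, 0:c]
        dz[ni, ci, amax] += dy[:, c:]
        self._cache = None
        return self.conv1.backward(self.relu1.backward(
            self.conv2.backward(self.relu2.backward(dz))))


def aggregate_slices(p: PooledRepresentation, agg: AggregatorModel) -> VolumeEmbedding:
    """(S, 2C) pooled representation -> fixed-length embedding."""
    x = p.matrix.T[None].astype(np.float32)  # (1, 2C, S)
    return VolumeEmbedding(vector=agg.forward(x)[0])


class DecisionHead(nn.Module):
    """One hidden layer (1024 units in the standard setup) -> 5 sigmoid units."""

    def __init__(self, in_features: int, hidden: int = 1024, n_tasks: int = len(BIOMARKERS),
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.fc1 = nn.Linear(in_features, hidden, rng=rng)
        self.relu = nn.ReLU()
        self.fc2 = nn.Linear(hidden, n_tasks, rng=rng)
        self.in_features = in_features

    def forward(self, x, train: bool = False):
        if x.shape[-1] != self.in_features:
            raise ValueError(f"head built for {self.in_features} inputs, got {x.shape[-1]}")
        return self.fc2.forward(self.relu.forward(self.fc1.forward(x, train), train), train)

    def backward(self, dy):
        return self.fc1.backward(self.relu.backward(self.fc2.backward(dy)))


def predict_biomarkers(e: VolumeEmbedding, head: DecisionHead) -> PredictionScores:
    logits = head.forward(e.vector[None].astype(np.float32))[0]
    probs = sigmoid(logits)
    return PredictionScores(scores={n: float(p) for n, p in zip(BIOMARKERS, probs)})


# ---------------------------------------------------------------------------
# Full models
# ---------------------------------------------------------------------------

class SliverNet(nn.Module):
    """End-to-end map: (N, S, H, W) preprocessed volume batch -> 5 logits."""

    def __init__(self, backbone_cfg: BackboneConfig, head_hidden: int = 1024, seed: int = 0):
        ss = np.random.SeedSequence(seed).spawn(3)
        self.backbone = BackboneModel(backbone_cfg, seed=ss[0].generate_state(1)[0] % 2**31)
        c = backbone_cfg.output_channels
        self.aggregator = AggregatorModel(2 * c, seed=ss[1].generate_state(1)[0] % 2**31)
        self.head = DecisionHead(self.aggregator.embedding_length, hidden=head_hidden,
                                 seed=ss[2].generate_state(1)[0] % 2**31)
        self.head_hidden = head_hidden
        self.freeze_backbone = False
        self._cache = None

    # -- parameter groups ---------------------------------------------------
    def trainable_parameters(self):
        ps = []
        if not self.freeze_backbone:
            ps += self.backbone.parameters()
        ps += self.aggregator.parameters()
        ps += self.head.parameters()
        return ps

    # -- forward / backward -------------------------------------------------
    def forward(self, x, train: bool = False):
        """x: (N, S, H, W) float in [0, 1] (or uint8 in [0,255]) -> (N, 5) logits."""
        x = np.asarray(x)
        if x.dtype == np.uint8:
            x = x.astype(np.float32) / 255.0
        n, s, h, w = x.shape
        slices = x.reshape(n * s, 1, h, w).astype(np.float32)
        feats = self.backbone.forward(slices, train=train and not self.freeze_backbone)
        c = feats.shape[1]
        avg = feats.mean(axis=(2, 3))
        flat = feats.reshape(n * s, c, -1)
        amax = flat.argmax(axis=2)
        mx = np.take_along_axis(flat, amax[:, :, None], axis=2)[:, :, 0]
        pooled = np.concatenate([avg, mx], axis=1)  # (N*S, 2C)
        seq = pooled.reshape(n, s, 2 * c).transpose(0, 2, 1)  # (N, 2C, S)
        emb = self.aggregator.forward(seq, train=train)
        logits = self.head.forward(emb, train=train)
        if train:
            self._cache = (feats.shape, amax, (n, s, c))
        return logits

    def backward(self, dlogits):
        feats_shape, amax, (n, s, c) = self._cache
        demb = self.head.backward(dlogits)
        dseq = self.aggregator.backward(demb)  # (N, 2C, S)
        dpooled = dseq.transpose(0, 2, 1).reshape(n * s, 2 * c)
        hw = feats_shape[2] * feats_shape[3]
        dflat = np.repeat(dpooled[:, :c, None] / hw, hw, axis=2)
        ni, ci = np.ogrid[0 : n * s, 0:c]
        dflat[ni, ci, amax] += dpooled[:, c:]
        dfeats = dflat.reshape(feats_shape).astype(np.float32)
        self._cache = None
        if not self.freeze_backbone:
            return self.backbone.backward(dfeats)
        return None

    # -- training protocol ---------------------------------------------------
    def forward_loss(self, xb, yb, train: bool = True, pos_weight=None):
        logits = self.forward(xb, train=train)
        loss, dlogits = bce_with_logits(logits, yb, pos_weight=pos_weight)
        if train:
            self._dlogits = dlogits
        return loss

    def backward_from_loss(self):
        self.backward(self._dlogits)

    def predict(self, xb) -> np.ndarray:
        return sigmoid(self.forward(xb, train=False))


def build_sliver_net(backbone_cfg: BackboneConfig, head_hidden: int = 1024,
                     seed: int = 0) -> SliverNet:
    return SliverNet(backbone_cfg, head_hidden=head_hidden, seed=seed)


class Baseline2DTiled(nn.Module):
    """Tiled 2D CNN baseline: global pooling over the whole mosaic grid.

    Shares the backbone/head design with SLIVER-net but skips per-slice
    pooling and 1D aggregation, isolating slice integration as the delta.
    """

    def __init__(self, backbone_cfg: BackboneConfig, head_hidden: int = 1024, seed: int = 0):
        ss = np.random.SeedSequence(seed).spawn(2)
        self.backbone = BackboneModel(backbone_cfg, seed=ss[0].generate_state(1)[0] % 2**31)
        c = backbone_cfg.output_channels
        self.head = DecisionHead(2 * c, hidden=head_hidden,
                                 seed=ss[1].generate_state(1)[0] % 2**31)
        self._cache = None

    def forward(self, x, train: bool = False):
        """x: (N, S, H, W) -> (N, 5) logits via mosaic global avg+max pooling."""
        x = np.asarray(x)
        if x.dtype == np.uint8:
            x = x.astype(np.float32) / 255.0
        n, s, h, w = x.shape
        mosaic = x.reshape(n, 1, s * h, w).astype(np.float32)
        feats = self.backbone.forward(mosaic, train=train)
        c = feats.shape[1]
        flat = feats.reshape(n, c, -1)
        avg = flat.mean(axis=2)
        amax = flat.argmax(axis=2)
        mx = np.take_along_axis(flat, amax[:, :, None], axis=2)[:, :, 0]
        if train:
            self._cache = (feats.shape, amax)
        return self.head.forward(np.concatenate([avg, mx], axis=1), train=train)

    def backward(self, dlogits):
        feats_shape, amax = self._cache
        n, c = feats_shape[0], feats_shape[1]
        hw = feats_shape[2] * feats_shape[3]
        dpooled = self.head.backward(dlogits)
        dflat = np.repeat(dpooled[:, :c, None] / hw, hw, axis=2)
        ni, ci = np.ogrid[0:n, 0:c]
        dflat[ni, ci, amax] += dpooled[:, c:]
        self._cache = None
        return self.backbone.backward(dflat.reshape(feats_shape).astype(np.float32))

    def forward_loss(self, xb, yb, train: bool = True, pos_weight=None):
        logits = self.forward(xb, train=train)
        loss, dlogits = bce_with_logits(logits, yb, pos_weight=pos_weight)
        if train:
            self._dlogits = dlogits
        return loss

    def backward_from_loss(self):
        self.backward(self._dlogits)

    def trainable_parameters(self):
        return self.parameters()

    def predict(self, xb) -> np.ndarray:
        return sigmoid(self.forward(xb, train=False))


def build_baseline_2d_tiled(cfg: BackboneConfig, head_hidden: int = 1024,
                            seed: int = 0) -> Baseline2DTiled:
    return Baseline2DTiled(cfg, head_hidden=head_hidden, seed=seed)


class Baseline3D(nn.Module):
    """3D residual CNN: volume (N, S, H, W) -> 5 logits via 3D convolutions.

    Mirrors the 2D backbone design with inflated (cubic) kernels, so the
    parameter count strictly exceeds the matched 2D variant's.
    """

    def __init__(self, cfg: BackboneConfig, head_hidden: int = 1024, seed: int = 0):
        ss = np.random.SeedSequence(seed).spawn(2)
        rng = np.random.default_rng(ss[0].generate_state(1)[0] % 2**31)
        self.cfg = cfg
        stem = [nn.Conv3d(1, cfg.stem_channels, cfg.stem_kernel, stride=cfg.stem_stride,
                          rng=rng), nn.ReLU()]
        blocks = []
        prev = cfg.stem_channels
        for ch, st in zip(cfg.stage_channels, cfg.stage_strides):
            for b in range(cfg.blocks_per_stage):
                blocks.append(nn.ResidualBlock3d(prev, ch, stride=st if b == 0 else 1, rng=rng))
                prev = ch
        self.net = nn.Sequential(*stem, *blocks)
        self.head = DecisionHead(2 * cfg.output_channels, hidden=head_hidden,
                                 seed=ss[1].generate_state(1)[0] % 2**31)
        self._cache = None

    def forward(self, x, train: bool = False):
        x = np.asarray(x)
        if x.dtype == np.uint8:
            x = x.astype(np.float32) / 255.0
        feats = self.net.forward(x[:, None].astype(np.float32), train=train)
        n, c = feats.shape[:2]
        flat = feats.reshape(n, c, -1)
        avg = flat.mean(axis=2)
        amax = flat.argmax(axis=2)
        mx = np.take_along_axis(flat, amax[:, :, None], axis=2)[:, :, 0]
        if train:
            self._cache = (feats.shape, amax)
        return self.head.forward(np.concatenate([avg, mx], axis=1), train=train)

    def backward(self, dlogits):
        feats_shape, amax = self._cache
        n, c = feats_shape[:2]
        nvox = int(np.prod(feats_shape[2:]))
        dpooled = self.head.backward(dlogits)
        dflat = np.repeat(dpooled[:, :c, None] / nvox, nvox, axis=2)
        ni, ci = np.ogrid[0:n, 0:c]
        dflat[ni, ci, amax] += dpooled[:, c:]
        self._cache = None
        return self.net.backward(dflat.reshape(feats_shape).astype(np.float32))

    def forward_loss(self, xb, yb, train: bool = True, pos_weight=None):
        logits = self.forward(xb, train=train)
        loss, dlogits = bce_with_logits(logits, yb, pos_weight=pos_weight)
        if train:
            self._dlogits = dlogits
        return loss

    def backward_from_loss(self):
        self.backward(self._dlogits)

    def trainable_parameters(self):
        return self.parameters()

    def predict(self, xb) -> np.ndarray:
        return sigmoid(self.forward(xb, train=False))


def build_baseline_3d(cfg: BackboneConfig, head_hidden: int = 1024, seed: int = 0) -> Baseline3D:
    return Baseline3D(cfg, head_hidden=head_hidden, seed=seed)


# ---------------------------------------------------------------------------
# Weight stores
# ---------------------------------------------------------------------------

def save_checkpoint(path, model_or_state, config: dict | None = None) -> Path:
    """Single-file checkpoint: named parameter arrays + config JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = (
        model_or_state
        if isinstance(model_or_state, dict)
        else model_or_state.state_dict()
    )
    payload = {f"param::{k}": v for k, v in state.items()}
    payload["config_json"] = np.array(json.dumps(config or {}))
    np.savez(path, **payload)
    return path


def load_checkpoint(path) -> tuple[dict, dict]:
    """Returns (state dict, config dict); loading into a model is shape-strict."""
    with np.load(path, allow_pickle=False) as z:
        state = {k[len("param::"):]: z[k] for k in z.files if k.startswith("param::")}
        config = json.loads(str(z["config_json"]))
    return state, config


def backbone_config_from_dict(d: dict) -> BackboneConfig:
    d = dict(d)
    for k in ("stage_channels", "stage_strides"):
        if k in d:
            d[k] = tuple(d[k])
    return BackboneConfig(**d)


def backbone_config_to_dict(cfg: BackboneConfig) -> dict:
    d = asdict(cfg)
    d["stage_channels"] = list(cfg.stage_channels)
    d["stage_strides"] = list(cfg.stage_strides)
    return d
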