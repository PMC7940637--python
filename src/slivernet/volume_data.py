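"""Volume data model, file I/O, preprocessing, and volume<->mosaic tiling.

An OCT acquisition is an ordered stack of B-scans (cross-sectional slices).
The standard protocol modeled here is 97 slices of 496x512 pixels covering a
6x6 mm macular region with 61 um between neighboring slices. Preprocessing
resamples every slice to a square network input (224x224 by default),
clips intensities to the slice's 2nd/98th percentiles and rescales to
integers in [0, 255].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
from skimage.transform import resize as _skimage_resize
from skimage.transform import resize_local_mean as _skimage_resize_local_mean

STANDARD_SLICE_COUNT = 97
STANDARD_SLICE_SHAPE = (496, 512)
STANDARD_SPACING_UM = 61.0
STANDARD_EXTENT_MM = (6.0, 6.0)
NETWORK_INPUT_SIZE = 224
BIOMARKERS = ("ihrf", "hdc", "sdd", "high_cdv", "rpd")


@dataclass
class RawVolume:
    """Ordered stack of 2D non-negative intensity slices plus acquisition metadata.

    The slice axis is the first array axis; within a slice, rows are axial
    depth and columns lateral position (top-left origin, 0-based).
    """

    slices: np.ndarray  # (S, H, W) float or integer, finite, >= 0
    inter_slice_spacing_um: float = STANDARD_SPACING_UM
    in_plane_extent_mm: tuple[float, float] = STANDARD_EXTENT_MM
    subject_id: str = ""
    eye: str = "unknown"
    quality_ok: bool = True

    def __post_init__(self):
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 3 or self.slices.shape[0] < 1:
            raise ValueError("a volume needs >= 1 slice of identical 2D shape")
        if not np.all(np.isfinite(self.slices)):
            raise ValueError("volume intensities must be finite")
        if self.slices.min() < 0:
            raise ValueError("volume intensities must be non-negative")
        if self.inter_slice_spacing_um <= 0:
            raise ValueError("inter-slice spacing must be positive")
        if self.eye not in ("left", "right", "unknown"):
            raise ValueError(f"unknown eye designation: {self.eye!r}")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.slices.shape[1:3]


@dataclass
class PreprocessedVolume:
    """S x H x W integer intensities in [0, 255], ready for tiling / the backbone."""

    data: np.ndarray
    provenance: RawVolume | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("preprocessed volume must be a 3D stack")
        if self.data.min() < 0 or self.data.max() > 255:
            raise ValueError("preprocessed intensities must lie in [0, 255]")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


@dataclass
class TiledImage:
    """All slices concatenated vertically into one (S*H) x W mosaic."""

    data: np.ndarray
    slice_count: int

    def __post_init__(self):
        if self.data.ndim != 2:
            raise ValueError("tiled image must be 2D")
        if self.data.shape[0] % self.slice_count != 0:
            raise ValueError("mosaic height must be an exact multiple of slice height")


@dataclass
class BiomarkerLabels:
    """Presence/absence flags for the five progression-risk biomarkers."""

    ihrf: int = 0
    hdc: int = 0
    sdd: int = 0
    high_cdv: int = 0
    rpd: int = 0

    def __post_init__(self):
        for name in BIOMARKERS:
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValueError(f"label {name} must be 0 or 1, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in BIOMARKERS], dtype=np.int64)

    @classmethod
    def from_array(cls, arr) -> "BiomarkerLabels":
        return cls(**{n: int(v) for n, v in zip(BIOMARKERS, arr)})


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _read_sidecar(path: Path) -> dict:
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        return json.loads(sidecar.read_text())
    return {}


def load_volume(path, fmt: str | None = None) -> RawVolume:
    """Load a multi-page TIFF or NIfTI file as a RawVolume.

    TIFF page order (or the NIfTI third axis) is the slice order. Spacing and
    extent come from a JSON sidecar ``<file>.json`` (keys
    ``inter_slice_spacing_um``, ``in_plane_extent_mm``) or the NIfTI header,
    defaulting to the standard protocol values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "nifti" if path.suffix in (".nii", ".gz") else "tiff_stack"
    meta = _read_sidecar(path)
    if fmt == "tiff_stack":
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D grayscale stack, got shape {arr.shape}")
        spacing = float(meta.get("inter_slice_spacing_um", STANDARD_SPACING_UM))
    elif fmt == "nifti":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D NIfTI volume, got shape {data.shape}")
        # slice axis is stored third; reorder to slice-first
        arr = np.moveaxis(data, 2, 0)
        zoom = img.header.get_zooms()
        spacing = float(meta.get("inter_slice_spacing_um", zoom[2] * 1000.0))
        if spacing <= 0:
            spacing = STANDARD_SPACING_UM
    else:
        raise ValueError(f"unknown format {fmt!r}")
    extent = tuple(meta.get("in_plane_extent_mm", STANDARD_EXTENT_MM))
    return RawVolume(
        slices=arr,
        inter_slice_spacing_um=spacing,
        in_plane_extent_mm=extent,
        subject_id=str(meta.get("subject_id", "")),
        eye=str(meta.get("eye", "unknown")),
        quality_ok=bool(meta.get("quality_ok", True)),
    )


def write_volume(v: RawVolume | PreprocessedVolume, path, fmt: str | None = None) -> Path:
    """Write a volume; ``load_volume(write_volume(v))`` reproduces intensities exactly."""
    path = Path(path)
    data = v.slices if isinstance(v, RawVolume) else v.data
    if fmt is None:
        fmt = "nifti" if path.suffix in (".nii", ".gz") else "tiff_stack"
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "tiff_stack":
        tifffile.imwrite(path, np.asarray(data))
    elif fmt == "nifti":
        spacing_mm = (
            v.inter_slice_spacing_um / 1000.0
            if isinstance(v, RawVolume)
            else STANDARD_SPACING_UM / 1000.0
        )
        img = nib.Nifti1Image(np.moveaxis(np.asarray(data), 0, 2), affine=np.eye(4))
        img.header.set_zooms((1.0, 1.0, spacing_mm))
        nib.save(img, str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if isinstance(v, RawVolume):
        sidecar = {
            "inter_slice_spacing_um": v.inter_slice_spacing_um,
            "in_plane_extent_mm": list(v.in_plane_extent_mm),
            "subject_id": v.subject_id,
            "eye": v.eye,
            "quality_ok": v.quality_ok,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))
    return path


def read_labels_csv(path) -> pd.DataFrame:
    """Read the label table (columns volume_id, ihrf, hdc, sdd, high_cdv, rpd)."""
    df = pd.read_csv(path, dtype={"volume_id": str})
    missing = {"volume_id", *BIOMARKERS} - set(df.columns)
    if missing:
        raise ValueError(f"labels CSV missing columns: {sorted(missing)}")
    for c in BIOMARKERS:
        bad = ~df[c].isin([0, 1])
        if bad.any():
            raise ValueError(f"labels column {c} contains non-binary values")
    return df


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def resample_slice(slice_2d: np.ndarray, target: tuple[int, int] = (224, 224)) -> np.ndarray:
    """Resample one slice to ``target``.

    Downscaling uses local-mean (pixel-area) resampling, so integer-ratio
    downsampling of a piecewise-constant image reproduces exact block means;
    upscaling is bilinear. Neither expands the intensity range beyond
    rounding.
    """
    slice_2d = np.asarray(slice_2d, dtype=np.float64)
    if slice_2d.size == 0:
        raise ValueError("cannot resample an empty slice")
    if target[0] <= 0 or target[1] <= 0:
        raise ValueError("target dimensions must be positive")
    if slice_2d.shape == tuple(target):
        return slice_2d.copy()
    if target[0] <= slice_2d.shape[0] and target[1] <= slice_2d.shape[1]:
        return _skimage_resize_local_mean(slice_2d, target, preserve_range=True)
    return _skimage_resize(
        slice_2d, target, order=1, mode="edge", anti_aliasing=False, preserve_range=True
    )


def enhance_contrast(slice_2d: np.ndarray) -> np.ndarray:
    """Clip to the slice's 2nd/98th percentiles, rescale to integers in [0, 255].

    Percentiles use linear interpolation between order statistics. A constant
    (or fully clipped-degenerate) slice maps to all zeros. Rounding is half
    away from zero.
    """
    x = np.asarray(slice_2d, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot enhance an empty slice")
    if not np.all(np.isfinite(x)):
        raise ValueError("slice intensities must be finite")
    p2, p98 = np.percentile(x, [2.0, 98.0])
    if p98 <= p2:
        return np.zeros_like(x, dtype=np.uint8)
    y = 255.0 * (np.clip(x, p2, p98) - p2) / (p98 - p2)
    # round half away from zero (values are >= 0 here, so floor(y + 0.5))
    return np.floor(y + 0.5).astype(np.uint8)


def preprocess_volume(
    v: RawVolume,
    target: tuple[int, int] = (NETWORK_INPUT_SIZE, NETWORK_INPUT_SIZE),
    force: bool = False,
) -> PreprocessedVolume:
    """Resample then contrast-enhance every slice, preserving slice order.

    Volumes failing the quality gate are rejected unless ``force=True``
    (inference on poor-quality scans remains possible; they are simply
    excluded from training by default).
    """
    if not v.quality_ok and not force:
        raise ValueError("volume failed quality review; pass force=True to override")
    out = np.empty((v.n_slices, *target), dtype=np.uint8)
    for i in range(v.n_slices):
        try:
            out[i] = enhance_contrast(resample_slice(v.slices[i], target))
        except ValueError as exc:  # pragma: no cover - propagated with context
            raise ValueError(f"slice {i}: {exc}") from exc
    return PreprocessedVolume(data=out, provenance=v)


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------

def tile_volume(v: PreprocessedVolume) -> TiledImage:
    """Concatenate slices vertically into an (S*H) x W mosaic (slice order kept)."""
    s, h, w = v.data.shape
    return TiledImage(data=v.data.reshape(s * h, w), slice_count=s)


def untile_volume(t: TiledImage, slice_count: int) -> PreprocessedVolume:
    """Exact inverse of :func:`tile_volume`."""
    if slice_count < 1 or t.data.shape[0] % slice_count != 0:
        raise ValueError(
            f"mosaic height {t.data.shape[0]} not divisible by slice count {slice_count}"
        )
    h = t.data.shape[0] // slice_count
    return PreprocessedVolume(data=t.data.reshape(slice_count, h, t.data.shape[1]))


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------

@dataclass
class VolumeDataset:
    """In-memory labeled cohort: volumes + per-volume labels + identities."""

    volumes: list  # list of (S,H,W) arrays (raw or preprocessed)
    labels: np.ndarray  # (N, 5) binary, column order BIOMARKERS
    volume_ids: list = field(default_factory=list)
    subject_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        n = len(self.volumes)
        if self.labels.shape != (n, len(BIOMARKERS)):
            raise ValueError("labels must be (n_volumes, 5)")
        if not self.volume_ids:
            self.volume_ids = [f"V{i:05d}" for i in range(n)]
        if not self.subject_ids:
            self.subject_ids = list(self.volume_ids)
        if len(set(self.volume_ids)) != n:
            raise ValueError("volume ids must be unique")

    def __len__(self) -> int:
        return len(self.volumes)

    def subset(self, indices) -> "VolumeDataset":
        indices = list(indices)
        return VolumeDataset(
            volumes=[self.volumes[i] for i in indices],
            labels=self.labels[indices],
            volume_ids=[self.volume_ids[i] for i in indices],
            subject_ids=[self.subject_ids[i] for i in indices],
        )

    def map_volumes(self, fn) -> "VolumeDataset":
        return VolumeDataset(
            volumes=[fn(v) for v in self.volumes],
            labels=self.labels.copy(),
            volume_ids=list(self.volume_ids),
            subject_ids=list(self.subject_ids),
        )

    def labels_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.labels, columns=list(BIOMARKERS))
        df.insert(0, "volume_id", self.volume_ids)
        return df


def load_dataset(root) -> VolumeDataset:
    """Load the on-disk layout ``volumes/<id>.tiff`` + ``labels.csv`` (+ manifest)."""
    root = Path(root)
    df = read_labels_csv(root / "labels.csv")
    manifest_path = root / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    subj = manifest.get("subjects", {})
    volumes, vol_ids, subj_ids = [], [], []
    for vid in df["volume_id"]:
        v = load_volume(root / "volumes" / f"{vid}.tiff")
        volumes.append(v.slices)
        vol_ids.append(vid)
        subj_ids.append(subj.get(vid, v.subject_id or vid))
    return VolumeDataset(
        volumes=volumes,
        labels=df[list(BIOMARKERS)].to_numpy(),
        volume_ids=vol_ids,
        subject_ids=subj_ids,
    )
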