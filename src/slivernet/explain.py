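"""Explainability maps: channel-averaged per-slice feature images.

Each slice's h x w x C backbone feature grid is averaged across channels,
bilinearly interpolated back to the input size, and min-max normalized over
the whole volume to [0, 1]; a constant-feature volume maps to all zeros.
Overlays blend the grayscale slice with a color-mapped heat map.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from matplotlib import colormaps
from skimage.transform import resize as _resize

from .sliver_model import BackboneModel, extract_slice_features
from .volume_data import PreprocessedVolume


@dataclass
class HeatmapVolume:
    """S per-slice heat maps matching the source volume's slice size."""

    maps: np.ndarray  # (S, H, W) in [0, 1]
    source: PreprocessedVolume | None = None

    def __post_init__(self):
        if self.maps.ndim != 3:
            raise ValueError("heat maps must be (S, H, W)")
        if self.maps.min() < 0 or self.maps.max() > 1:
            raise ValueError("heat maps must be normalized to [0, 1]")


def explain_volume(model, v) -> HeatmapVolume:
    """Class-agnostic heat maps from a backbone (or full model with .backbone)."""
    backbone: BackboneModel = model.backbone if hasattr(model, "backbone") else model
    if not isinstance(v, PreprocessedVolume):
        v = PreprocessedVolume(data=np.asarray(v))
    feats = extract_slice_features(backbone, v, mode="per_slice").maps  # (S,h,w,C)
    mean_maps = feats.mean(axis=3)  # (S, h, w)
    s, H, W = v.data.shape
    out = np.empty((s, H, W), dtype=np.float64)
    for i in range(s):
        out[i] = _resize(mean_maps[i], (H, W), order=1, mode="edge",
                         anti_aliasing=False, preserve_range=True)
    lo, hi = out.min(), out.max()
    if hi > lo:
        out = (out - lo) / (hi - lo)
    else:
        out = np.zeros_like(out)
    return HeatmapVolume(maps=out, source=v)


def render_overlay(heatmap_slice, source_slice, out_path, alpha: float = 0.4,
                   cmap: str = "inferno") -> Path:
    """Write a PNG blending the grayscale source with the color-mapped heat map."""
    hm = np.asarray(heatmap_slice, dtype=float)
    src = np.asarray(source_slice, dtype=float)
    if hm.shape != src.shape:
        raise ValueError(f"heatmap {hm.shape} and source {src.shape} dims differ")
    gray = np.repeat((src / max(src.max(), 1.0))[..., None], 3, axis=2)
    colored = colormaps[cmap](hm)[..., :3]
    blended = (1 - alpha * hm[..., None]) * gray + (alpha * hm[..., None]) * colored
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out_path, (np.clip(blended, 0, 1) * 255).astype(np.uint8))
    return out_path


def render_contact_sheet(hv: HeatmapVolume, out_path, cols: int = 8) -> Path:
    """Optional mosaic contact sheet of all slice overlays."""
    s, h, w = hv.maps.shape
    rows = -(-s // cols)
    sheet = np.zeros((rows * h, cols * w, 3), dtype=np.uint8)
    src = hv.source.data if hv.source is not None else np.zeros_like(hv.maps)
    for i in range(s):
        r, c = divmod(i, cols)
        gray = np.repeat((src[i] / 255.0)[..., None], 3, axis=2)
        colored = colormaps["inferno"](hv.maps[i])[..., :3]
        a = 0.4 * hv.maps[i][..., None]
        tile = (1 - a) * gray + a * colored
        sheet[r * h : (r + 1) * h, c * w : (c + 1) * w] = (tile * 255).astype(np.uint8)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out_path, sheet)
    return out_path
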