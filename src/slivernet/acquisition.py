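"""Acquisition-parameter simulation: field-of-view cropping around the
central slice, slice-axis downsampling, and train/evaluate sweeps.

These transforms emulate non-standard scan protocols: a clinic acquiring
fewer B-scans around the macula (smaller field of view) or spacing them
further apart (lower slice-axis resolution). Under the standard protocol
(97 slices, 61 um apart) 9 central slices span 488 um and all 97 span
5856 um; downsampling to 549 um spacing keeps 11 slices. Transforms never
modify pixel values — only slice membership and spacing metadata.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import ScoredSet, SingleClassError, pr_auc, roc_auc
from .volume_data import BIOMARKERS, RawVolume, VolumeDataset


@dataclass
class AcquisitionTransform:
    kind: str  # {central_crop, stride_downsample, identity}
    k: float = 0  # crop slice count, or target spacing in um

    def __post_init__(self):
        if self.kind not in ("central_crop", "stride_downsample", "identity"):
            raise ValueError(f"unknown transform kind {self.kind!r}")

    def apply_array(self, slices: np.ndarray, native_spacing_um: float = 61.0):
        if self.kind == "identity":
            return slices, native_spacing_um
        if self.kind == "central_crop":
            idx = central_crop_indices(slices.shape[0], int(self.k))
            return slices[idx], native_spacing_um
        idx = downsample_indices(slices.shape[0], native_spacing_um, float(self.k))
        stride = idx[1] - idx[0] if len(idx) > 1 else 1
        return slices[idx], native_spacing_um * stride


def central_crop_indices(s: int, k: int) -> np.ndarray:
    """Indices of the k slices around the center c = floor(S/2).

    Odd k on odd S is symmetric ([c - k//2, c + k//2]); an even k biases the
    extra slice toward the lower index.
    """
    if not 1 <= k <= s:
        raise ValueError(f"crop count k={k} outside [1, {s}]")
    c = s // 2
    if k % 2 == 1:
        lo = c - k // 2
    else:
        lo = c - k // 2
    lo = max(0, min(lo, s - k))
    return np.arange(lo, lo + k)


def crop_central_slices(v: RawVolume, k: int) -> tuple[RawVolume, float]:
    """Keep k central slices; returns (cropped volume, field of view in um).

    fov = (k - 1) * spacing: 9 slices at 61 um spacing span 488 um.
    """
    idx = central_crop_indices(v.n_slices, k)
    fov_um = (k - 1) * v.inter_slice_spacing_um
    cropped = RawVolume(
        slices=v.slices[idx],
        inter_slice_spacing_um=v.inter_slice_spacing_um,
        in_plane_extent_mm=v.in_plane_extent_mm,
        subject_id=v.subject_id,
        eye=v.eye,
        quality_ok=v.quality_ok,
    )
    return cropped, float(fov_um)


def downsample_indices(s: int, native_um: float, target_um: float) -> np.ndarray:
    """Kept indices 0, stride, 2*stride, ... with stride = round(target/native)."""
    if target_um < native_um:
        raise ValueError("target spacing must be >= native spacing")
    stride = max(int(round(target_um / native_um)), 1)
    return np.arange(0, s, stride)


def downsample_slices(v: RawVolume, target_spacing_um: float) -> RawVolume:
    """Keep every stride-th slice (anchored at index 0); spacing scales by stride."""
    idx = downsample_indices(v.n_slices, v.inter_slice_spacing_um, target_spacing_um)
    stride = idx[1] - idx[0] if len(idx) > 1 else 1
    return RawVolume(
        slices=v.slices[idx],
        inter_slice_spacing_um=v.inter_slice_spacing_um * stride,
        in_plane_extent_mm=v.in_plane_extent_mm,
        subject_id=v.subject_id,
        eye=v.eye,
        quality_ok=v.quality_ok,
    )


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

def _transform_dataset(ds: VolumeDataset, tr: AcquisitionTransform,
                       native_um: float) -> VolumeDataset:
    return ds.map_volumes(lambda v: tr.apply_array(np.asarray(v), native_um)[0])


def _stratified_subsample(ds: VolumeDataset, n: int, rng) -> VolumeDataset:
    """Uniform subsample of n volumes, retaining >=1 positive per biomarker
    when the full set has one."""
    order = rng.permutation(len(ds))
    chosen = list(order[:n])
    chosen_set = set(chosen)
    for k in range(ds.labels.shape[1]):
        if ds.labels[chosen, k].sum() == 0 and ds.labels[:, k].sum() > 0:
            donors = [i for i in order if ds.labels[i, k] == 1]
            swap_out = next(
                i for i in reversed(chosen)
                if ds.labels[i].sum() == 0 or ds.labels[i, k] == 0
            )
            chosen_set.discard(swap_out)
            chosen_set.add(donors[0])
            chosen = [i for i in chosen if i in chosen_set] + [donors[0]]
    return ds.subset(sorted(chosen_set))


def run_sweep(
    train_ds: VolumeDataset,
    test_ds: VolumeDataset,
    axis: str,
    grid,
    protocol,
    seeds=(0,),
    native_spacing_um: float = 61.0,
) -> pd.DataFrame:
    """Train/evaluate over a grid of acquisition or sample-size settings.

    ``axis`` is one of ``fov`` (central-crop slice counts), ``resolution``
    (target spacings in um) or ``sample_size`` (training-set sizes). For the
    acquisition axes the transform is applied identically to train and test
    volumes; the sample-size axis subsamples training volumes (stratified to
    keep a positive per biomarker when possible). ``protocol`` is a callable
    ``(train_ds, test_ds, seed) -> ScoredSet``. Returns a long-format table
    (grid_value, seed, biomarker, auroc, auprc) plus ``status``; grid points
    whose training set is untrainable are recorded as failed, not fatal.
    """
    if axis not in ("fov", "resolution", "sample_size"):
        raise ValueError(f"unknown sweep axis {axis!r}")
    grid = list(grid)
    if not grid:
        raise ValueError("empty sweep grid")
    rows = []
    for g in grid:
        for seed in seeds:
            grid_tag = zlib.crc32(str(g).encode())  # stable across processes
            rng = np.random.default_rng(np.random.SeedSequence((int(seed), grid_tag)))
            try:
                if axis == "fov":
                    tr = AcquisitionTransform("central_crop", g)
                    tr_train = _transform_dataset(train_ds, tr, native_spacing_um)
                    tr_test = _transform_dataset(test_ds, tr, native_spacing_um)
                elif axis == "resolution":
                    tr = AcquisitionTransform("stride_downsample", g)
                    tr_train = _transform_dataset(train_ds, tr, native_spacing_um)
                    tr_test = _transform_dataset(test_ds, tr, native_spacing_um)
                else:
                    tr_train = _stratified_subsample(train_ds, int(g), rng)
                    tr_test = test_ds
                scored = protocol(tr_train, tr_test, seed)
                for k, name in enumerate(BIOMARKERS):
                    try:
                        a = roc_auc(scored.scores[:, k], scored.labels[:, k])
                        p = pr_auc(scored.scores[:, k], scored.labels[:, k])
                    except SingleClassError:
                        a = p = np.nan
                    rows.append(
                        dict(grid_value=g, seed=seed, biomarker=name,
                             auroc=a, auprc=p, status="ok")
                    )
            except (ValueError, RuntimeError) as exc:
                rows.append(
                    dict(grid_value=g, seed=seed, biomarker="", auroc=np.nan,
                         auprc=np.nan, status=f"failed: {exc}")
                )
    return pd.DataFrame(rows)
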