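"""Synthetic OCT-like volumes with planted biomarker analogs.

Real macular OCT volumes cannot be redistributed, so every stage of the
pipeline is exercised on a layered phantom: a smooth stack of horizontal
bands (the retina-layer analog) whose top surface undulates gently across
columns and slices, plus additive Gaussian noise. Conditional on the five
binary labels, focal features are planted:

- ``ihrf``   bright dots inside the band stack (hyperreflective foci analog)
- ``hdc``    dome elevations of the top surface containing a dark core
- ``sdd``    small bright caps sitting on top of the surface (drusenoid
             deposit analog), anywhere in the volume
- ``high_cdv`` one broad central mound, a large total elevation volume
- ``rpd``    sdd-like caps planted only in peripheral slices (the analog of
             reticular pseudodrusen lying outside the macular field); the
             fraction of rpd features restricted to the periphery is
             ``peripheral_fraction`` (1.0 by default)

Default prevalences mirror the cohort the method was developed on
(ihrf 7.1%, hdc 2.4%, sdd 1.9%, high central drusen volume 3.0%, rpd 3.1%).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volume_data import (
    BIOMARKERS,
    BiomarkerLabels,
    RawVolume,
    VolumeDataset,
    write_volume,
)

DEFAULT_PREVALENCE = {
    "ihrf": 0.071,
    "hdc": 0.024,
    "sdd": 0.019,
    "high_cdv": 0.030,
    "rpd": 0.031,
}

#: intensity levels of the phantom (0-255 scale, before noise)
_VITREOUS = 25.0
_TOP_LINE = 205.0
_BAND = 140.0
_BELOW = 55.0

AUX_CLASS_NAMES = ("normal", "cnv", "dme", "drusen")


@dataclass
class SyntheticSpec:
    """Generation parameters; defaults are the study conditions at test scale."""

    shape: tuple[int, int, int] = (16, 64, 64)  # (S, H, W)
    prevalence: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    difficulty: float = 1.0  # scales feature contrast and size; 1.0 = most salient
    noise_sd: float = 6.0
    peripheral_fraction: float = 1.0
    correlation: float = 0.0  # optional label co-occurrence knob

    def __post_init__(self):
        s, h, w = self.shape
        if s < 1 or h < 16 or w < 16:
            raise ValueError("volume shape too small to host planted features")
        if not 0 < self.difficulty <= 1:
            raise ValueError("difficulty must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for k, p in self.prevalence.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence[{k}] outside [0, 1]")


def _smooth_surface(rng, s, w, base_row, amp):
    """Smooth top-surface rows t[s, w] via a few random low-frequency sinusoids."""
    cols = np.arange(w) / w
    sl = np.arange(s) / max(s - 1, 1)
    t = np.full((s, w), float(base_row))
    for _ in range(3):
        fc, fs = rng.uniform(0.5, 2.0, size=2)
        pc, ps = rng.uniform(0, 2 * np.pi, size=2)
        a = rng.uniform(0.3, 1.0) * amp
        t += a * np.sin(2 * np.pi * fc * cols + pc)[None, :] * np.cos(
            2 * np.pi * fs * sl + ps
        )[:, None]
    return t


def _gaussian_bump(s_axis, c_axis, center_s, center_c, sig_s, sig_c, amp):
    g_s = np.exp(-0.5 * ((s_axis - center_s) / sig_s) ** 2)
    g_c = np.exp(-0.5 * ((c_axis - center_c) / sig_c) ** 2)
    return amp * g_s[:, None] * g_c[None, :]


def _peripheral_slices(s: int) -> np.ndarray:
    """Slice indices outside the central 50% of the stack.

    Stacks too short to have a central region (< 4 slices) fall back to the
    outermost indices.
    """
    lo, hi = s // 4, s - s // 4
    out = np.array([i for i in range(s) if i < lo or i >= hi])
    if out.size == 0:
        out = np.unique([0, s - 1])
    return out


def generate_volume(
    spec: SyntheticSpec,
    labels: BiomarkerLabels | None = None,
    seed: int | np.random.SeedSequence = 0,
):
    """Generate one volume; returns (RawVolume, BiomarkerLabels, ground-truth coords).

    Ground truth maps each biomarker to a list of (slice, row, col) feature
    centers; it is non-empty exactly when the label is set. Deterministic
    under ``seed``.
    """
    rng = np.random.default_rng(seed)
    s, h, w = spec.shape
    d = spec.difficulty

    if labels is None:
        flags = {}
        shared = rng.uniform()  # optional co-occurrence driver
        for name in BIOMARKERS:
            p = spec.prevalence.get(name, 0.0)
            u = rng.uniform()
            if spec.correlation > 0:
                u = (1 - spec.correlation) * u + spec.correlation * shared
            flags[name] = int(u < p)
        labels = BiomarkerLabels(**flags)

    base_row = int(h * 0.45)
    thickness = max(int(h * 0.2), 6)
    surface = _smooth_surface(rng, s, w, base_row, amp=1.5)

    truth: dict[str, list] = {name: [] for name in BIOMARKERS}
    s_axis = np.arange(s, dtype=float)
    c_axis = np.arange(w, dtype=float)
    caps = []  # bright caps sitting on the surface: (slice, col, radius)

    if labels.high_cdv:
        cs = s / 2 + rng.uniform(-1, 1)
        cc = w / 2 + rng.uniform(-w * 0.1, w * 0.1)
        amp = (0.10 + 0.04 * rng.uniform()) * h * d
        surface -= _gaussian_bump(s_axis, c_axis, cs, cc, s * 0.18, w * 0.14, amp)
        truth["high_cdv"].append((int(round(cs)), int(base_row - amp), int(round(cc))))

    hdc_domes = []
    if labels.hdc:
        for _ in range(rng.integers(2, 4)):
            cs = rng.uniform(s * 0.2, s * 0.8)
            cc = rng.uniform(w * 0.15, w * 0.85)
            amp = (0.08 + 0.03 * rng.uniform()) * h * d
            surface -= _gaussian_bump(s_axis, c_axis, cs, cc, s * 0.08, w * 0.05, amp)
            hdc_domes.append((cs, cc, amp))
            truth["hdc"].append((int(round(cs)), int(base_row - amp / 2), int(round(cc))))

    if labels.sdd:
        for _ in range(rng.integers(4, 8)):
            si = int(rng.integers(0, max(s - 1, 1)))
            ci = int(rng.integers(4, w - 4))
            for sj in (si, min(si + 1, s - 1)):  # deposits span adjacent slices
                caps.append((sj, ci, max(3.0 * d, 1.0)))
            truth["sdd"].append((si, int(surface[si, ci]) - 2, ci))

    if labels.rpd:
        periph = _peripheral_slices(s)
        extendable = periph[periph < s - 1]
        if extendable.size == 0:
            extendable = periph
        for _ in range(rng.integers(4, 8)):
            if rng.uniform() < spec.peripheral_fraction:
                si = int(rng.choice(extendable))
            else:
                si = int(rng.integers(0, s - 1))
            ci = int(rng.integers(4, w - 4))
            for ds_ in (0, 1):
                sj = si + ds_
                if sj >= s or (spec.peripheral_fraction >= 1.0 and sj not in periph):
                    continue
                caps.append((sj, ci, max(3.0 * d, 1.0)))
            truth["rpd"].append((si, int(surface[si, ci]) - 2, ci))

    # render bands from the (possibly elevated) surface
    rows = np.arange(h, dtype=float)[None, None, :]  # broadcast over (s, w)
    top = surface[:, :, None]
    vol = np.full((s, w, h), _VITREOUS)
    line = (rows >= top) & (rows < top + 2)
    band = (rows >= top + 2) & (rows < top + thickness)
    below = rows >= top + thickness
    vol[line] = _TOP_LINE
    vol[band] = _BAND
    vol[below] = _BELOW
    vol = vol.transpose(0, 2, 1)  # -> (s, h, w)

    yy, xx = np.mgrid[0:h, 0:w]

    # bright caps on top of the surface (sdd / rpd analogs)
    for si, ci, rad in caps:
        cy = surface[si, ci] - rad
        mask = (yy - cy) ** 2 + (xx - ci) ** 2 <= (rad + 1.2) ** 2
        vol[si][mask] = _VITREOUS + (195.0 - _VITREOUS) * d + 35.0

    # dark cores inside hdc domes
    for cs, cc, amp in hdc_domes:
        for si in range(max(0, int(cs - 2)), min(s, int(cs + 3))):
            cy = surface[si, int(cc)] + amp * 0.45 + 2
            rad = max(amp * 0.5, 3.0)
            mask = (yy - cy) ** 2 + ((xx - cc) / 1.6) ** 2 <= rad**2
            vol[si][mask] = _BAND - (110.0 * d)

    # bright intraretinal dots (ihrf analog); each focus spans adjacent slices
    if labels.ihrf:
        for _ in range(rng.integers(5, 10)):
            si = int(rng.integers(0, max(s - 1, 1)))
            ci = int(rng.integers(4, w - 4))
            cy = surface[si, ci] + rng.uniform(4, thickness - 2)
            rad = 1.2 + 2.3 * d
            mask = (yy - cy) ** 2 + (xx - ci) ** 2 <= rad**2
            for sj in (si, min(si + 1, s - 1)):  # foci span adjacent slices
                vol[sj][mask] = _BAND + (115.0 * d)
            truth["ihrf"].append((si, int(round(cy)), ci))

    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, size=vol.shape)
    vol = np.clip(vol, 0.0, 255.0).astype(np.float32)

    raw = RawVolume(slices=vol)
    return raw, labels, truth


def generate_dataset(
    spec: SyntheticSpec,
    n: int,
    seed: int | np.random.SeedSequence = 0,
    out_dir=None,
):
    """Generate ``n`` independent volumes (two per synthetic subject).

    Returns (VolumeDataset, ground-truth list). When ``out_dir`` is given,
    also writes the on-disk layout ``volumes/<id>.tiff`` + ``labels.csv`` +
    ``manifest.json``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(
        seed if isinstance(seed, int) else seed.entropy
    ) if not isinstance(seed, np.random.SeedSequence) else seed
    children = ss.spawn(n)
    volumes, labels, truths, vol_ids, subj_ids = [], [], [], [], []
    for i in range(n):
        raw, lab, truth = generate_volume(spec, labels=None, seed=children[i])
        sid = f"S{i // 2:05d}"
        raw.subject_id = sid
        raw.eye = "right" if i % 2 == 0 else "left"
        volumes.append(raw.slices)
        labels.append(lab.as_array())
        truths.append(truth)
        vol_ids.append(f"V{i:05d}")
        subj_ids.append(sid)
    ds = VolumeDataset(
        volumes=volumes,
        labels=np.array(labels),
        volume_ids=vol_ids,
        subject_ids=subj_ids,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "volumes").mkdir(parents=True, exist_ok=True)
        for vid, vol, sid, i in zip(vol_ids, volumes, subj_ids, range(n)):
            rv = RawVolume(
                slices=vol, subject_id=sid, eye="right" if i % 2 == 0 else "left"
            )
            write_volume(rv, out_dir / "volumes" / f"{vid}.tiff")
        ds.labels_frame().to_csv(out_dir / "labels.csv", index=False)
        manifest = {
            "spec": {
                "shape": list(spec.shape),
                "prevalence": spec.prevalence,
                "difficulty": spec.difficulty,
                "noise_sd": spec.noise_sd,
                "peripheral_fraction": spec.peripheral_fraction,
            },
            "seed": int(ss.entropy) if isinstance(ss.entropy, int) else str(ss.entropy),
            "n": n,
            "subjects": dict(zip(vol_ids, subj_ids)),
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return ds, truths


def generate_auxiliary_2d(
    spec: SyntheticSpec,
    n: int,
    classes: int = 4,
    seed: int | np.random.SeedSequence = 0,
):
    """Generate a balanced labeled 2D image set for backbone pretraining.

    Single slices from the same band phantom with class-conditional patterns
    emulating a 4-way retinal diagnosis task (normal / neovascular blob below
    the band / cystic dark cavities inside the band / surface bumps). Returns
    (images (n, H, W) float32, labels (n,) int).
    """
    if n < classes:
        raise ValueError("need at least one image per class")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rng = np.random.default_rng(ss)
    _, h, w = spec.shape
    d = spec.difficulty
    base_row = int(h * 0.45)
    thickness = max(int(h * 0.2), 6)
    images = np.empty((n, h, w), dtype=np.float32)
    labels = np.arange(n) % classes
    yy, xx = np.mgrid[0:h, 0:w]
    for i in range(n):
        surf = _smooth_surface(rng, 1, w, base_row, amp=1.5)[0]
        cls = labels[i]
        if cls == 3:  # drusen-like surface bumps
            for _ in range(rng.integers(2, 5)):
                cc = rng.uniform(w * 0.1, w * 0.9)
                amp = (0.06 + 0.05 * rng.uniform()) * h * d
                surf -= amp * np.exp(-0.5 * ((np.arange(w) - cc) / (w * 0.05)) ** 2)
        img = np.full((h, w), _VITREOUS)
        top = surf[None, :]
        img[(yy >= top) & (yy < top + 2)] = _TOP_LINE
        img[(yy >= top + 2) & (yy < top + thickness)] = _BAND
        img[yy >= top + thickness] = _BELOW
        if cls == 1:  # hyperreflective-material class: bright foci in/under the band
            for _ in range(rng.integers(2, 5)):
                cy = surf[int(w / 2)] + rng.uniform(4, thickness + 3)
                cx = rng.uniform(w * 0.1, w * 0.9)
                rad = 1.2 + 1.5 * d
                mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= rad**2
                img[mask] = _BAND + 115.0 * d
        elif cls == 2:  # cystic dark cavities inside the band
            for _ in range(rng.integers(2, 4)):
                cy = surf[int(w / 2)] + rng.uniform(3, thickness - 2)
                cx = rng.uniform(w * 0.15, w * 0.85)
                rad = 1.5 + 1.5 * d
                mask = (yy - cy) ** 2 + ((xx - cx) / 1.4) ** 2 <= rad**2
                img[mask] = _BAND - 110.0 * d
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        images[i] = np.clip(img, 0.0, 255.0)
    perm = rng.permutation(n)
    return images[perm], labels[perm].astype(np.int64)
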