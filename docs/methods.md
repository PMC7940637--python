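# Methods

This note documents the model, the training and evaluation protocol, the
synthetic data the package is validated on, and the numerical and design
choices a user should know before trusting (or extending) the results.

## The problem

Macular OCT volumes are ordered stacks of cross-sectional B-scans (the
standard protocol modeled here: 97 slices of 496×512 pixels covering 6×6 mm,
61 µm between slices). Five binary biomarkers of AMD progression risk are
annotated per volume: intraretinal hyperreflective foci (IHRF),
hyporeflective drusen cores (hDC), subretinal drusenoid deposits (SDD), high
central drusen volume, and reticular pseudodrusen (RPD, normally graded on
wide-field infrared imaging and often lying outside the OCT field). Annotated
volumes number in the hundreds and positives per biomarker in the dozens —
far too few to train a volumetric CNN directly.

## The model

SLIVER-net side-steps the lack of large 3D corpora by reducing the volume to
2D and then restoring the slice structure:

1. **Tiling.** All S slices are resampled to the network input size (224×224
   in the standard configuration), contrast-enhanced, and concatenated
   vertically into one (S·224)×224 mosaic so that a 2D backbone can process
   the whole volume in one forward pass. Per-slice execution is the reference
   semantics; the tiled pass must agree with it on feature rows whose
   receptive field does not cross a tile seam (a tested invariant).
2. **Backbone.** An 18-layer-style residual 2D CNN maps each slice to an
   h×w×C feature grid, C = 512 at standard width. The spatial grid is
   computed from the instantiated network — a stride-32 residual design gives
   7×7 for a 224 input — and is never assumed. Grayscale input is replicated
   to the backbone's expected channel count so image-pretrained weights load
   unchanged.
3. **Slice integration.** Within each slice's grid, average and max pooling
   per channel give an S×2C matrix (S×1024 at standard width). A small 1D
   CNN — two kernel-3, same-padded convolutions along the slice axis with
   widths 2C→C→C, each followed by a rectifier — aggregates neighboring
   slices, and global average+max pooling over the slice axis yields a
   2C-long embedding independent of S. That invariance is what lets one
   architecture handle 9–97-slice volumes in the acquisition-robustness
   experiments.
4. **Decision head.** One hidden layer (1024 units at standard width)
   feeding 5 sigmoid outputs; all biomarkers are predicted by the one
   network (multi-task).

Two baselines isolate the contributions: a 3D residual CNN with inflated
(cubic) kernels applied to the volume directly, and a tiled 2D CNN that
global-pools over the whole mosaic — i.e., SLIVER-net without slice
integration.

The network layers themselves (2D/1D/3D convolution, residual blocks, max
pooling, Adam with decoupled weight decay, explicit backpropagation) are
implemented in NumPy inside `slivernet.nn`. Residual blocks carry no
normalization layers: at the widths this package instantiates, plain
He-initialized stacks train stably, and omitting batch statistics keeps every
forward pass bit-deterministic. Gradients of every layer are verified against
central finite differences in the test suite.

## Training and transfer protocol

- Adam with default moments, decoupled weight decay 0.01, batch size 32.
- Early stopping: training ends once validation loss has not improved for 20
  consecutive epochs (configurable); the returned weights are those of the
  best-validation epoch, an invariant the tests re-verify by re-evaluating
  the restored model.
- The learning-rate finder sweeps [1e-7, 1.0] geometrically over mini-batches
  and returns the rate at the steepest decrease of the smoothed (EMA 0.98,
  bias-corrected) loss; with plain gradient steps on a convex quadratic the
  selection provably stays below the 2/curvature stability bound (tested).
- Loss: per-biomarker binary cross-entropy summed over tasks. An optional
  prevalence-based positive weight per task, capped at 25, compensates for
  the 2–7% positive rates; it is off by default and enabled in the scaled
  study below.
- Transfer protocol: (1) train backbone + temporary K-way softmax layer on an
  auxiliary labeled 2D image set (lr 1e-3, ≤50 epochs with early stopping);
  (2) discard the auxiliary decision layer; (3) attach a freshly initialized
  aggregator and head; (4) train only those with the backbone frozen —
  backbone weights are asserted bit-identical across this phase; (5) fine-tune
  the whole network at the reduced rate 1e-5.
- Data splits are subject-level (two volumes per subject exist, so
  record-level splits would leak); the evaluation CLI refuses test manifests
  sharing subjects with the training manifest.

## Evaluation statistics

ROC AUC is the Mann–Whitney pair statistic (ties get half credit); PR AUC is
step-wise average precision (no trapezoidal interpolation, which is
optimistic on PR curves). Confidence intervals are volume-level bootstrap
percentile intervals by order statistics: B resamples with replacement, CI =
(sorted[⌈0.025·B⌉], sorted[⌊0.975·B⌋]) — the 125th and 4875th of 5000.
Resamples on which a metric is undefined (a class vanished) are redrawn and
logged rather than scored. Mean metrics average the per-biomarker values
unweighted; their CIs bootstrap volumes and recompute the mean, restricted to
the biomarkers computable on the full set. Paired model comparison applies
identical resample indices to both models and compares the per-resample
metric values with a two-sided Wilcoxon signed-rank test (exact enumeration
for ≤25 tie-free nonzero differences, normal approximation with tie
correction otherwise). The decision rule everywhere is score ≥ threshold;
the sensitivity-matched threshold is the largest threshold achieving a target
sensitivity on a tuning set, i.e., maximal specificity under the constraint.

## Acquisition simulation

Field-of-view cropping keeps k slices around the central index ⌊S/2⌋
(symmetric for odd k on odd S; an even k biases the extra slice toward the
lower index), with field of view (k−1)·spacing: 9 slices at 61 µm span
488 µm, 97 span 5856 µm. Slice-axis downsampling keeps indices 0, stride,
2·stride, … with stride = round(target/native), anchored at the first slice;
549 µm spacing keeps 11 of 97 slices. Transforms never modify pixel values.
Sweeps retrain per grid point, applying the transform identically to train
and test volumes; the sample-size axis subsamples training volumes uniformly,
stratified to keep at least one positive per biomarker when possible.

## Synthetic data

Real volumes cannot be redistributed, so the package validates on a layered
phantom: a stack of horizontal bands whose top surface undulates smoothly
across columns and slices, plus Gaussian noise (σ = 6 on the 0–255 scale).
Conditional on the five labels it plants: bright intraretinal dots spanning
adjacent slices (IHRF analog); dome elevations with a dark core (hDC); small
bright caps on the surface (SDD); one broad central mound (high central
drusen volume); and caps restricted to the slices outside the central 50% of
the stack (RPD analog — by default every rpd feature is peripheral, so a
detector must integrate evidence from the volume ends). Default prevalences
are 7.1 / 2.4 / 1.9 / 3.0 / 3.1 percent, matching the cohort the method was
developed on. The `difficulty` parameter scales feature contrast and size;
at the default 1.0 a hand-written matched-filter detector separates forced
positives from negatives with AUROC > 0.95 (tested), which is what "easy"
means here. The auxiliary 2D set emulates a 4-way single-slice diagnosis
task (normal / bright foci / dark intraretinal cavities / surface bumps) —
classes whose textures overlap the volume biomarkers the way the public
fovea-centered OCT diagnosis sets overlap the target task.

What the phantom does **not** emulate: OCT speckle statistics, anatomically
calibrated layer thicknesses, vendor-specific contrast, inter-grader label
noise, or correlated biomarker co-occurrence (an optional correlation knob
exists but defaults to independence). Passing the synthetic studies therefore
demonstrates that the architecture, transfer protocol and statistics behave
as designed — not that the specific AUROC values would transfer to clinical
data.

## The scaled study

The transfer-benefit experiment (`slivernet.experiments`) runs at sizes one
CPU handles in minutes, chosen once as the package's study conditions:
volumes of 16 slices × 64×64 pixels, network input 48×48, the small backbone
(stride 8, C = 16, head width 32), 200 training volumes (160/40
subject-level train/validation), 300 held-out test volumes generated from a
disjoint seed stream, and a 400-image auxiliary set. Training uses lr 3e-3,
at most 45 epochs with patience 15 (close to the protocol's 20; shorter
patience reliably abandons training before the rare positives are fitted),
auxiliary pretraining 30 epochs, prevalence-based positive weighting, and
label-preserving augmentation (lateral flips, slice-order reversal,
±3-pixel lateral rolls) — at 3–12 positives per biomarker, unaugmented
networks reliably memorize training-specific cues instead of the planted
features. The whole-network fine-tune phase keeps the protocol rate 1e-5 and
is capped at 10 epochs, where it is numerically inert at this scale.

Across 5 seeds this yields mean AUROC ≈ 0.96 for the pretrained arm vs
≈ 0.88 from scratch (pretrained ≥ scratch in the majority of seeds, with the
scratch arm markedly less stable across seeds — the variance reduction, more
than the mean shift, is where pretraining pays off at this scale), and the
peripheral-only RPD analog is detected at AUROC ≈ 0.98. These numbers are
recomputed from scratch by `scripts/acceptance.py` and asserted (with
stochastic margins) by `tests/test_acceptance.py`.

## Numerical and design choices

- **Resampling.** Downscaling uses local-mean (pixel-area) resampling, so
  integer-ratio downsampling of piecewise-constant images reproduces exact
  block means; upscaling is bilinear. Gaussian-prefiltered bilinear
  downscaling was rejected because it smears focal features across block
  boundaries by double-digit intensity units.
- **Contrast.** Percentiles (2nd/98th) use linear interpolation between
  order statistics, per slice (not per volume); degenerate slices (p2 = p98)
  map to all zeros; rounding is half away from zero.
- **Axes.** The slice axis is the first array axis; within a slice, rows are
  axial depth, columns lateral position, top-left origin.
- **Quality gate.** Volumes flagged as poor quality are excluded from
  training by default but can be preprocessed for inference with
  `force=True`.
- **Determinism.** Every stochastic component (generation, splits, batch
  order, initialization, bootstrap, augmentation) derives from explicit
  seeds; identical seeds and inputs reproduce training histories to ≤1e-6 in
  the losses on the same BLAS build.
- **"10e−7"** in the published learning-rate range is read as 1e-7 (the
  convention of the learning-rate-finder implementations it references).
- **Checkpoints** are single `.npz` files holding named parameter arrays and
  a config JSON; loading is strict on names and shapes.

## Known limitations

- The NumPy backend is CPU-only and single-process; the standard-width
  configuration is exercised for contracts (shapes, pooling widths,
  embedding invariance) but full-scale training at 97×224×224 is outside its
  intended use.
- Without normalization layers, very deep or very wide variants of the
  backbone may need smaller learning rates than the defaults.
- The Wilcoxon pairing for model comparison (identical bootstrap resample
  indices for both models) is one defensible construction of a paired test on
  a single test set; analytic AUC variance (DeLong) is out of scope.
- Heat maps are class-agnostic channel means of backbone features —
  informative about *where* the network looks, silent about *which* biomarker
  drove a score.
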