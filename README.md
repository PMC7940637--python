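# slivernet

Multi-label prediction of AMD-progression biomarkers from 3D OCT volumes
with few annotated examples, via **SL**ice **I**ntegration of **V**olumetric
features **E**xtracted by pre-trained **R**esidual networks (SLIVER-net).

Annotated macular OCT volumes number in the hundreds, and positives for the
biomarkers of interest — intraretinal hyperreflective foci (IHRF),
hyporeflective drusen cores (hDC), subretinal drusenoid deposits (SDD), high
central drusen volume, reticular pseudodrusen (RPD) — in the dozens. That is
far too little to train a 3D CNN, and no large labeled 3D corpus exists to
transfer from. SLIVER-net's answer:

1. **Tile** the volume: resample every slice to the network input size, clip
   intensities to the slice's 2nd/98th percentiles, rescale to [0, 255], and
   stack the S slices vertically into one (S·224)×224 mosaic a 2D network
   digests in a single pass — which makes 2D transfer learning applicable.
2. **Extract** per-slice features with an 18-layer-style residual 2D backbone
   (C = 512 channels at standard width), pretrained on an auxiliary labeled
   2D image set.
3. **Integrate slices**: average+max pooling within each slice's feature grid
   (an S×2C matrix), then a small 1D CNN along the slice axis with global
   average+max pooling — restoring the 3D neighborhood structure that tiling
   discards, with an embedding length independent of S.
4. **Decide** with a shared multi-task head: one hidden layer into 5 sigmoid
   outputs.

The package implements the full method plus its training/transfer protocol
(Adam, weight decay 0.01, batch 32, 20-epoch-patience early stopping,
learning-rate finder, frozen-backbone head training, whole-network fine-tune
at 1e-5), the evaluation statistics (ROC/PR AUC with 5000-replicate
bootstrap order-statistic CIs, Wilcoxon signed-rank comparisons,
sensitivity-matched thresholds), class-agnostic explainability heat maps,
acquisition-parameter simulators (field-of-view crops, slice-axis
downsampling, sample-size sweeps), 3D-CNN and tiled-2D baselines, and a
synthetic volume generator so everything runs end to end without any
clinical data. The neural-network layers (2D/1D/3D convolutions, residual
blocks, Adam, backprop) are implemented in NumPy in `slivernet.nn` with
finite-difference-verified gradients.

## Worked example

```python
import numpy as np
from slivernet import (
    BackboneConfig, SyntheticSpec, TrainConfig,
    generate_dataset, preprocess_volume, RawVolume,
    split_train_val, fit, roc_auc, bootstrap_ci, ScoredSet,
)
from slivernet.experiments import (
    SmallStudyConfig, make_study_data, train_scratch, score_dataset,
)
from slivernet.evaluation import mean_auroc

study = SmallStudyConfig()            # 200 train / 300 test synthetic volumes
train, test, _ = make_study_data(study, seed=1)
tr, va = split_train_val(train, 0.8, seed=1)

model, history = train_scratch(study, tr, va, seed=1)
scored = score_dataset(model, test)

print(f"mean AUROC {mean_auroc(scored):.3f}")
ci = bootstrap_ci(mean_auroc, scored, n_boot=1000, seed=1)
print(f"95% CI [{ci.lower:.3f}, {ci.upper:.3f}]")
```

prints (seed 1, this package's defaults):

```
mean AUROC 0.761
95% CI [0.694, 0.829]
```

i.e., on held-out synthetic volumes the from-scratch network separates
positive from negative volumes with a mean area under the ROC curve of 0.76
across the five biomarker analogs on this seed (0.88 averaged over five
seeds), and the volume-level bootstrap places the 95% interval well above
chance (0.5). Pretraining the backbone on the synthetic auxiliary 2D set and
fine-tuning (`slivernet.experiments.train_pretrained`) raises this to 0.96
on the same seed and stabilizes it across seeds — see `docs/methods.md`.

The same pipeline is scriptable from the shell:

```bash
slivernet synth --out data/train --n 200 --seed 1 --preset small
slivernet synth --out data/test  --n 300 --seed 2 --preset small
slivernet pretrain --out runs/backbone --n 400 --seed 1 --preset small
slivernet train --data data/train --out runs/model --seed 1 --preset small \
    --backbone-weights runs/backbone/backbone.npz
slivernet evaluate --data data/test --model runs/model/model.npz \
    --out runs/eval --train-subjects runs/model/train_subjects.json
slivernet explain --volume data/test/volumes/V00000.tiff \
    --model runs/model/model.npz --out runs/maps
```

`evaluate` writes per-biomarker AUROC/AUPRC with bootstrap CIs to
`metrics.json` and refuses test sets that share subjects with the training
manifest. `slivernet sweep` retrains over field-of-view, slice-spacing, or
sample-size grids and writes a long-format CSV.

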