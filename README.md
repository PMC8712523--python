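# pifnet

Patch individual filter (PIF) layers for 3D convolutional networks on
spatially registered volumes, with layer-wise relevance propagation (LRP)
and a convergence benchmarking harness.

## The problem

Structural neuroimaging data is unusually homogeneous: brains share one
anatomical layout, and preprocessing registers every scan to a common
template, so a given voxel indexes the same anatomy in every subject.
Standard CNNs ignore this — weight sharing makes every filter search the
whole volume for a pattern that, after registration, can only occur in one
place. `pifnet` implements an architectural prior that exploits the
homogeneity: early layers remain ordinary convolutions (low-level features
are position-independent), while a late **PIF layer** splits the latent
feature maps into a grid of spatial patches and learns a *separate* kernel
stack per patch:

```
z_p = Σ_m̂ Σ_n̂  I(m̂, n̂) · K_p(i − m̂, j − n̂)      for every patch p ∈ P,
```

with `m̂, n̂` ranging over patch `p` only.  Weights are shared *within* a
patch (the kernel still slides when the patch is larger than the kernel)
but never across patches.  The processed patches are reassembled in the
order they were split.  Because splitting creates artificial borders, a
parallel **overlap strain** processes the same maps cut at origins shifted
by half a patch size, `(x_ov, y_ov) = (x_o + s_x/2, y_o + s_y/2)`
(border-exceeding shifts dropped); where an overlap patch covers a voxel
the layer outputs the mean of the two strains, which averages their
gradients in the backward pass.

The package provides, in pure numpy (no deep-learning framework required):

- `pifnet.patches` / `pifnet.pif` — the patch grid bookkeeping and the PIF
  layer with exact forward/backward passes;
- `pifnet.architectures` — three model families: a shallow VGG-style 3D CNN
  (variants A/B), the same network with its last conv+pool stage replaced by
  a PIF layer, and a patch-based baseline (one shared sub-network over a
  2x3x2 input split, scores averaged);
- `pifnet.lrp` — LRP with the α/β rule (`α = 1 + β`, default `β = 4`),
  including the PIF adaptation (relevance split per patch, overlap strain
  relevance averaged) and filter-/patch-level heatmap starts;
- `pifnet.synthetic` — a generator of registered-MRI-like volumes (shared
  template, localized class signal, shared texture, noise, registration
  jitter) with NIfTI I/O;
- `pifnet.training` — the validation protocol: max-intensity normalization,
  translation/sagittal-flip augmentation (translation only for PIF models),
  random hyperparameter search, repeated subject-grouped splits, early
  stopping, and test metrics (AUC ROC, balanced accuracy, sensitivity,
  specificity);
- `pifnet.cli` — the `pifnet` command with `simulate`, `describe`, `train`,
  `evaluate`, `heatmap` and `compare-convergence` subcommands.

## Worked example

Generate a synthetic dataset, inspect the PIF model, train it, and draw a
patch-specific heatmap:

```sh
pifnet simulate --seed 1 --n-per-class 20 --out data/
pifnet describe --arch A-PIF --input 32 38 32
pifnet train --data data/ --arch A-PIF --seed 1 --max-epochs 30 --out run/
pifnet heatmap --checkpoint run/checkpoint.npz --data data/ \
    --layer pif --patch 0 --filter 3 --out hm/ --png
```

`describe` prints the stage table; the PIF stage on a 32x38x32 input sits on
a 4x4x4 latent grid split into 8 patches (2x2x2) plus one central overlap
patch, each with its own 2-stage conv stack:

```
   stage     output_shape  params
   conv1  (8, 32, 38, 32)     224
   pool1  (8, 16, 19, 16)       0
   conv2 (16, 16, 19, 16)    3472
   ...
     pif    (64, 2, 2, 2)  443520
  output             (2,)      66
total trainable parameters: 477554
```

`train` prints the test metrics of the best-validation checkpoint as
percentages, e.g.

```json
{"sensitivity": 100.0, "specificity": 87.5,
 "balanced_accuracy": 93.75, "auc_roc": 100.0}
```

(the exact values depend on the seed; sensitivity/specificity are the
class-1/class-0 recalls, balanced accuracy their mean, AUC the rank
statistic of the class-1 score).

From Python the same experiment is three calls:

```python
from pifnet import SyntheticSpec, generate, build_model, train, SplitPlan, make_splits
import numpy as np

data = generate(SyntheticSpec(seed=1))
(split,) = make_splits(data.subject_ids, SplitPlan(n_repetitions=1),
                       np.random.default_rng(1))
model = build_model("A-PIF", data.shape, seed=1)
record = train(model, data.volumes, data.labels, split,
               {"learning_rate": 1e-3, "batch_size": 12, "patience": 12},
               np.random.default_rng(1))
print(record.stop_iteration, record.test_metrics)
```

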