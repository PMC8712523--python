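# Methods

## The PIF layer

A patch individual filter (PIF) layer is a convolutional stage without
global weight sharing.  Its three steps are: (i) **split** the incoming
feature maps into a regular grid of spatial patches of size
`s_x × s_y (× s_z)`; (ii) **process** each patch with its own stack of
`convs_per_patch` convolutions (kernel `k ≤ s`, cross-correlation
convention, zero "same" padding, ReLU after every stage) — weights slide
within the patch when `s > k` but are never reused in another patch;
(iii) **reassemble** the processed patches at their original positions.
Split/reassemble is exact bookkeeping: `reassemble(split(x)) == x`
bit-for-bit, patches ordered lexicographically by origin, extents half-open
`[origin, origin + s)`.

**Domain constraints.**  The grid must tile the latent domain exactly; a
shape that is not a multiple of the patch size is rejected rather than
padded or truncated, because implicit boundary patches would silently
change the domain over which the per-patch kernels are defined.

**Overlap strain.**  Per-patch zero padding creates artificial borders
inside the reassembled map.  To mitigate them, a parallel strain processes
the same input cut at origins shifted by half a patch size per dimension;
shifted patches that would cross the domain boundary are dropped (they
would need padding and sit in the least informative corner regions), which
requires even patch sizes when the strain is enabled.  On a 2×2×2 grid
exactly one central overlap patch survives.

**Strain combination.**  The two strains are combined at the reassembled
(pre-pooling) resolution: voxels covered by an overlap patch carry the
element-wise mean of the strains, all others the main strain's value.
Under the chain rule, the forward mean *is* gradient averaging between the
overlapping and non-overlapping patches in the backward pass, so no custom
backward rule is needed.  The configured max pooling is applied once to the
combined map; since pooling windows never cross patch borders (patch sizes
are multiples of the window), this is identical to per-patch pooling for
the main grid while keeping the strains spatially aligned.

## Model families

All models map a single-channel volume to two class logits (softmax
cross-entropy, ReLU activations, He initialization, seeded and exactly
reproducible).

| family | structure |
|---|---|
| baseline A | 4 × [conv 3³ "same" + maxpool 2³], filters 8→16→32→64, flatten, FC 32, FC 2 |
| baseline B | 5 conv stages (8→…→128), stage 4 unpooled so the final conv+pool sees a poolable latent |
| A-PIF / B-PIF | baseline with the *last* conv+pool stage replaced by one PIF layer: 2×2×2 latent grid, 2 convs per patch, 2³ kernels, overlap strain on, pooled 2³ |
| patch-based | one shared sub-network (conv 8,16 pooled + conv 32,64 unpooled + FC 32 + FC 2) applied to the 12 patches of a 2×3×2 *input* split; volume score = mean of patch scores |

Choices the architecture family leaves open, fixed here: filter counts
double from 8 (a `width` factor scales all of them proportionally); the
PIF kernel is 2³ because the latent patches on the default volume are 2³
and kernels may not exceed the patch; the patch-based model's fusion is the
unweighted mean of class scores (the least-structured choice given that one
classifier serves all positions), and its input split zero-pads each
dimension up to the next multiple of the patch count — input-space
splitting, unlike latent PIF splitting, must tolerate arbitrary volume
sizes.  The exact stage counts matter less than the presence/absence of the
PIF stage, which is the manipulated variable.

The PIF layer's weights are named `patch_<origin>/conv<i>/{W,b}` and
`overlap_<origin>/…`, so checkpoints carry one named group per patch per
strain.

## LRP with the α/β rule

Relevance is redistributed with positive and negative contributions
normalized separately,

```
R_i = Σ_j ( α z_ij⁺ / Σ_k z_kj⁺  −  β z_ij⁻ / Σ_k z_kj⁻ ) R_j ,   α = 1 + β,
```

with `β = 4` by default.  A stabilizer `ε = 1e-9`, sign-matched to each
denominator, guards zero denominators; with `ε → 0` and nonzero
denominators each layer conserves the relevance sum (verified against a
double-loop implementation of the rule).  Conventions where the rule is
silent: max pooling routes relevance winner-takes-all through the pooling
switches; flatten is re-indexing; ReLU passes relevance through; biases
absorb their share rather than receiving a relevance "neuron", keeping
input heatmaps comparable across models.  Heatmaps may start at the output
logit, at any filter's activation map, or — for PIF layers — at one filter
inside one patch; starting relevance is the chosen activation with all
other units zeroed.

Through a PIF layer, relevance follows the forward bookkeeping in reverse:
unpool, split per main-grid patch, redistribute through each patch's
private stack, reassemble; wherever an overlap patch covers a voxel the
overlap strain's relevance is averaged with the main strain's.

The **locality index** of a heatmap partitions the volume into a cell grid
(default 2×2×2) and reports the fraction of cells needed to hold 90% of
the total absolute relevance — 1/8 for a map concentrated in one octant,
1 for a uniform map.  It quantifies how spatially confined an attribution
is; α/β heatmaps are signed, so only finiteness, not non-negativity, is
assumed.

## Synthetic data

The generator emulates what spatial normalization leaves behind in real
structural MRI:

| ingredient | default | emulates |
|---|---|---|
| template | smoothed ellipsoidal compartments, fixed per seed | shared anatomy after registration |
| signal sites | 2 spheres, radius ≈ min(shape)/8, at fixed fractional positions, `d = 0.2` added for class 1 | localized, spatially fixed disease effect |
| texture | per-subject smooth field, sd 0.05, same law in both classes | benign anatomical variability |
| noise | i.i.d. Gaussian, σ = 0.1 | scanner noise |
| jitter | 0 (≤ 2 typical) voxels integer translation | residual registration error |
| shape | 32×38×32 | a 1/3-scale echo of the 96×114×96 grids of template-registered MRI |

`d = 2σ` makes the class signal strong at the site level (a linear readout
of the site mean reaches AUC > 0.9 at n = 50/class) yet invisible at any
single voxel — the regime in which a spatial prior should pay off.  Volumes
are max-intensity normalized last, matching the training-time convention.
A `delocalized` switch re-draws site positions per subject, destroying the
fixed spatial layout the PIF prior assumes (negative-control regime).
What the generator does *not* model — MRI physics, bias fields, multi-site
effects, nonlinear anatomical variability — means passing benchmarks here
demonstrate the mechanics and the prior's effect under ideal registration,
not clinical performance.

## Training protocol

Repeated random splits (fractions configurable; 64/16/20 by default),
grouped by subject so no subject straddles partitions; hyperparameters
drawn from a discrete grid (architecture A/B — each at least twice in five
draws — learning rate {1e-4, 5e-5}, batch {4, 6, 12}, patience {12, 16});
Adam on the softmax cross-entropy; one validation evaluation per epoch.
Early stopping: the patience counter counts evaluations since the
validation balanced accuracy last *strictly* improved; among equal-metric
epochs the lower-validation-loss checkpoint is kept; a hard cap
(200 epochs by default) terminates runs stuck in their initial basin.  The
best-validation checkpoint is restored before test evaluation.  Metrics
are reported as percentages; AUC is undefined (reported as null) on a
single-class set.  Augmentation: integer translation (≤ 2 voxels,
zero-filled) for all families plus a 50% sagittal flip for non-PIF families
— a flip would swap the content of left and right latent patches, which a
PIF layer cannot absorb.

Conventions fixed where the protocol is underdetermined: the optimizer is
Adam; "iteration" for the patience counter is one validation evaluation
(= one epoch at this data scale); "performance" is validation balanced
accuracy.

## The convergence benchmark

`pifnet.experiments.run_convergence_experiment` trains baseline A, A-PIF
and the patch-based model on matched splits (same split, same seed, same
hyperparameters per run) of one synthetic dataset and compares iterations
until early stopping plus test balanced accuracy.  Problem sizes, chosen to
keep the full benchmark at desk scale: n = 50 volumes/class at 32×38×32,
5 matched splits, half-`width` models (filters 4→32), batch 12,
patience 12, cap 40 epochs, learning rate 1e-3 — higher than the
real-data protocol grid because tiny datasets and quarter-scale models
need larger steps to traverse the loss landscape within tens of epochs.
Augmentation is off in this benchmark: the generator produces perfectly
registered volumes, so the comparison isolates the architectural prior
rather than pose robustness.  Wall-clock time is recorded in every
`TrialRecord` but never asserted (hardware-dependent); the comparison
criterion is the iteration count.

What the scaled-down benchmark can and cannot show: at one third of a
typical registered-MRI resolution the latent feature maps entering the
replaced stage are only 4×4×4, so the 2×2×2 patch grid leaves the spatial
prior very little room to act, and with a strong localized signal both
baseline and PIF saturate the validation metric within roughly ten epochs —
the stop iteration is then dominated by the patience window plus
validation noise on a 16-volume set.  In our runs the two medians sit
within a few epochs of each other, with the PIF model converging markedly
faster exactly on the splits where optimization takes long, while the
accuracy ordering (baseline ≈ PIF, both far above the patch-based model)
is robust.  A median convergence gap of the kind the prior targets at
full MRI resolution — where the latent grid is large enough for patches to
specialize — should not be expected to survive this down-scaling.

`run_heatmap_locality_experiment` compares the locality index of heatmaps
started at the most active PIF patch filter against heatmaps started at the
most active first-layer filter, over 10 synthetic inputs, using a seeded
(untrained) A-PIF model — the patch confinement is architectural, not
learned, so random weights suffice.

## Known limitations

- PIF layers require spatially standardized inputs: identical voxel grids
  and meaningful voxel-wise correspondence.  Mixed-shape datasets are
  rejected at load time.
- The overlap strain mitigates but does not remove border effects; it
  introduces secondary borders of its own.
- LRP heatmaps are used to measure *locality*, not causal importance.
- The numpy implementation is CPU-oriented; it is exact but not
  competitive with GPU frameworks at full MRI resolution.
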