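# Methods

## Problem and pipeline

`sliceclr` classifies neurodegenerative disorders (e.g. Alzheimer's-type
dementia vs. behavioral-variant frontotemporal dementia vs. cognitively
normal) from preprocessed T1-weighted brain MRI, using a feature extractor
that is trained **without diagnostic labels**. The pipeline has five
stages:

1. **Slice decomposition.** Each affinely registered, cropped 3D volume
   (canonically 169 × 208 × 179 voxels at 1 mm) is reduced to 2D coronal
   planes. Only a central window of planes is kept — for a 208-plane
   coronal extent, the 120 central planes — because the mid-coronal
   territory contains the structures most affected early in dementia
   (hippocampus, temporal lobe, insula). The window is the half-open
   index range `[⌊(extent − n)/2⌋, ⌊(extent − n)/2⌋ + n)`; when the
   discarded margin is odd, the extra discarded plane is on the
   high-index side. Each selected plane is min–max scaled to [0, 1]
   per slice (constant planes map to zero).

2. **Contrastive pretraining (NNCLR).** A ConvNeXt-style 2D encoder is
   trained on slices with the nearest-neighbor contrastive objective.
   Two stochastic views of the same slice (horizontal flip, crop-resize,
   rectangular occlusion, each applied with probability 0.5) form a
   positive pair. Projections are L2-normalized, and the anchor of each
   directed pair is replaced by its Euclidean nearest neighbor from a
   FIFO queue of recent projections (capacity 8,192) before the
   InfoNCE-style softmax over the 2N batch views at temperature τ.
   The batch objective averages both directions of every pair. Queue
   entries are constants for backpropagation; until the queue is first
   filled, the current batch seeds it.

3. **Linear probing.** The classification head — layer normalization
   followed by one fully connected layer — is trained with cross-entropy
   on slice-level labels (each slice inherits its scan's diagnosis),
   by default with the backbone frozen. An unfrozen mode fine-tunes the
   backbone at 0.1× the head's learning rate.

4. **Majority voting.** A scan's label is the modal class over its
   selected slices; ties go to the larger mean softmax score, then to
   the lower class index. Metrics are computed at scan level: balanced
   accuracy (mean of per-class recalls), MCC (binary formula for two
   classes, Gorodkin's R_K otherwise), sensitivity/specificity and
   micro recall, averaged over trials as mean ± population sd.

5. **Attribution.** Integrated gradients with a midpoint Riemann rule
   (50 steps by default) against a mean-control baseline: the
   elementwise mean of control-group slices at the matching slice
   index, computed from training controls only. Attribution targets the
   pre-softmax class score. Class-level maps average over correctly
   classified test scans of the target class; maps are
   Gaussian-smoothed (σ = 1 px) and thresholded to the top 10% of
   |score| for display.

## Model architecture

The encoder follows the ConvNeXt recipe: a 4×4/stride-4 patchify stem;
four stages of residual blocks with 2×2/stride-2 downsampling between
stages; each block is a depthwise 7×7 convolution → layer norm →
pointwise expand 4× → GELU → pointwise project → per-channel layer scale
(init 10⁻⁶) → residual add. Features are global-average-pooled and
layer-normalized; the feature width equals the last stage's channels —
768 for the tiny variant (depths (3, 3, 9, 3), channels
(96, 192, 384, 768)). Inputs are grayscale (one channel). A reduced
`test_tiny` configuration (depths (1, 1, 1, 1), channels (8, 16, 32, 64))
is first-class and used for desk-scale runs and tests.

All tensor arithmetic runs on a compact reverse-mode automatic
differentiation engine over float64 numpy arrays (`sliceclr._autodiff`),
with analytic backward passes verified against central finite
differences in the test suite. Optimization is AdamW throughout.

No natural-image pretrained weights ship with the package;
`build_backbone(pretrained=True)` requires a user-supplied checkpoint
(e.g. from an earlier SSL run) and errors otherwise.

## Parameters that matter

| Parameter | Default | Notes |
| --- | --- | --- |
| queue capacity | 8,192 | support set of the nearest-neighbor lookup |
| temperature τ | 0.1 | softmax sharpness; standard NNCLR value |
| projection head | 2-layer MLP, hidden = feature dim, out 128 | queue stores its outputs |
| augmentation probabilities | 0.5 each | fixed by the training protocol |
| crop area fraction | (0.6, 1.0) | free magnitude choice |
| occlusion area fraction | (0.05, 0.2), fill 0 | free magnitude choice |
| SSL epochs / batch | 1,000 / 180 pairs | full-scale protocol; scaled runs use 60 / 32 |
| SSL optimizer | AdamW, lr 10⁻⁴, wd 10⁻⁴, cosine decay | hotter rates (≥ 3 × 10⁻⁴) can collapse representations at desk scale |
| probe epochs / batch | 100 / 64 | cosine-annealed lr with warm restarts every 20 epochs |
| probe optimizer | AdamW, lr 10⁻², wd 0 | matches a logistic-regression cross-check on frozen features |
| IG steps | 50 | midpoint rule; completeness residual recorded per map |
| test fraction / trials | 0.1 / 3 | participant-grouped splits, stratified by diagnosis; the desk-scale demo uses 0.2 so a 24-scan cohort keeps a meaningful test set |

## Synthetic phantoms

Real dementia cohorts are access-restricted, so the pipeline is
validated on synthetic volumes that emulate the structure the method
relies on: an ellipsoidal "brain" with smooth participant-specific
low-frequency texture on an exactly zero background; a class-specific
ellipsoidal region whose intensity is multiplied by (1 − effect size);
additive Gaussian noise per scan; repeat scans per participant sharing
one diagnosis. The two default classes darken a medial/inferior region
(temporal-lobe-like) and an anterior/superior region (insular-like);
both lie inside the central coronal window, as their anatomical
counterparts do. Texture is independent of class, so two phantoms
differing only in class differ exactly in which region is darkened.
Defaults: 64 × 80 × 64 voxels (a scaled-down stand-in for the full
169 × 208 × 179 crop), effect size 0.3, noise sd 0.05, one scan per
participant. All randomness flows from explicit `SeedSequence` seeds.

Phantoms deliberately omit: anatomy, bias fields, scanner artifacts,
registration error, within-class heterogeneity of lesion location, and
age/sex covariates. Passing phantom tests therefore demonstrates that
the pipeline's machinery (losses, training, voting, metrics,
attribution) is correct and that it recovers a planted regional-atrophy
signal end to end — not that the model reaches any particular accuracy
on clinical data.

## Scaled-down study conditions

Desk-scale runs (tests and the acceptance script) use the `test_tiny`
encoder, 20 central slices of 64 × 80 × 64 phantoms, cohorts of 10
participants per class, 60 SSL epochs with batch 64, and a 100-epoch
frozen probe; evaluation uses a held-out phantom cohort of 20 scans per
class. Under these conditions the pinned end-to-end run reaches
scan-level balanced accuracy ≥ 0.9. Stochastic variability across
master seeds is real at this scale (a 40-scan test set quantizes
balanced accuracy in steps of 0.025); the loss traces and per-trial
metrics written by the pipeline make this visible rather than averaging
it away.

A negative finding worth stating: at this scale, contrastive
pretraining does **not** reliably outperform an identically probed
random-weight encoder. Randomly initialized ConvNeXt-style features are
already near ceiling for strong planted lesions (balanced accuracy
0.90–0.95), and whether pretraining helps (up to +0.15) or is neutral
depends on the cohort realization; with hot learning rates it can
actively collapse the representation. The pretraining-beats-random
comparison therefore needs larger, harder data than these phantoms —
claims about SSL's benefit on clinical cohorts cannot be read off the
phantom benchmark in either direction.

## Numerical choices and degenerate inputs

- Everything is float64; the contrastive softmax masks the anchor's own
  column with −10⁹ (exactly zero after exp in float64).
- Nearest-neighbor ties resolve to the earliest-inserted queue entry.
- Min–max of a constant slice/volume returns all zeros; z-scoring a
  constant volume is an error; NaN voxels fail at load time.
- MCC with a degenerate denominator returns 0 with a warning.
- Crops are clamped to at least 2 × 2 pixels before bilinear resize.
- Checkpoints are `.npz` archives of parameter arrays plus the
  architecture tuple; loading verifies shapes.

## Known limitations

- CPU-only float64 training: full-scale (1,000-epoch, tiny-variant)
  pretraining is far slower than a GPU implementation of the same
  architecture; the package is sized for method validation, not
  large-cohort training.
- The contrastive denominator uses batch views only (the literal
  objective); variants that also count queue entries as negatives are
  not implemented.
- At desk scale (hundreds of slices), prolonged or hot contrastive
  training overfits the pretext task and erodes linear separability of
  the pooled features; the default scaled recipe (60 epochs, lr 10⁻⁴)
  was chosen for stability across seeds, and loss traces should be
  inspected when changing it.
- One view-pair construction (both views augmented) is implemented;
  leaving one view unaugmented is not.
- Sagittal/axial slice pipelines, 3D convolutions, and transformer
  backbones are out of scope.
- Attribution slice indices are reported relative to the selected
  central window, not the full coronal extent.
- In a binary task, integrated gradients concentrate on *both* classes'
  lesion regions regardless of the attributed class — the absence of the
  other class's lesion is itself evidence — so region specificity should
  be judged against lesion-free tissue, not against the competing
  class's region.
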