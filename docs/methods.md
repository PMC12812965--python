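# Methods

This note documents the modeling choices, parameter defaults, numerical
details, and limitations of the `mdlca` package.

## Model and assumptions

The classifier assumes one T1c-like MRI volume and one gene-expression
vector per patient, paired by patient ID, with a class label per patient.
Multi-sequence MRI, bias-field correction, and registration are out of
scope; volumes are assumed to arrive with (or to tolerate a fallback for)
a binary brain mask.

### MRI path

1. **Skull-stripping** multiplies the volume elementwise with its brain
   mask. The mask is first closed morphologically (cubic kernel, default
   3×3×3) to smooth segmentation irregularities at the boundary. Masks with
   fewer than `min_brain_voxels` (default 10) foreground voxels are
   rejected as degenerate. When no mask is supplied, a fallback generator
   (Otsu threshold + largest connected component) serves synthetic and toy
   volumes; it is not a substitute for a real brain-extraction tool on
   clinical data.
2. **Intensity normalization** z-scores the within-mask voxels using the
   sample standard deviation (ddof = 1) and zeroes everything outside the
   mask. A constant brain region is an error, not a silent division by
   zero.
3. **Resampling** maps the volume to a cube (default side 128; tests use
   16) with half-pixel-center coordinate mapping, so downsampling a ramp by
   two yields pair midpoints and constants are preserved exactly.
   Trilinear and nearest interpolation are supported.

### Genomic path

1. **QC** drops genes whose missing fraction exceeds 0.2 or whose
   cross-patient variance falls below 1e-8 (population variance), then
   imputes remaining missing values with the gene-wise median. These
   thresholds are package choices; the defaults keep clean tables intact.
2. **Normalization** is log2(x + 1). Quantile normalization is deliberately
   not implemented: the log transform is the primary normalization and
   keeping a single path keeps the preprocessing contract exact.
3. **Graph construction** links genes whose absolute Pearson correlation
   across patients reaches `corr_threshold` (default 0.7); signed
   co-expression counts as interaction. An explicit two-column edge list
   can replace correlation. Zero-variance genes simply receive no
   correlation edges. No self-loops are stored; the GAT layer adds them.
   In the training pipeline the correlation graph can be estimated on the
   training split only (`graph_ids`) to keep test patients out of the
   topology.

### Volumetric encoder

A 3D DenseNet: stem (7×7×7 conv stride 2, BN, ReLU, 3×3×3 max-pool stride
2, 64 channels), dense blocks of 6/12/24/16 composite layers
(BN → ReLU → 3×3×3 conv) with growth rate 32, transitions
(BN → ReLU → 1×1×1 conv at 0.5 compression → 2×2×2 average pool), dropout
0.2 after each block, He-normal initialization. Stem and transition designs
follow the standard DenseNet-121 convention. Standard downsampling of a
128³ input ends at a 4³ grid while the fused representation is 7³ per the
architecture's stated output; the final stage therefore applies adaptive
average pooling to `pooled_side` (default 7) and a 1×1×1 projection to
`out_channels` (default 256), which reconciles the two shapes for any input
side ≥ 32. A `tiny` preset (side-16 inputs, blocks [2,2], growth 8, pooled
side 2, 32 channels) is the desk-scale configuration used throughout the
tests. `trace_shapes` walks the real layer objects to report per-stage
(channels, side) without allocating activations.

### Genomic encoder

Two GAT layers: 8 heads × 32 hidden units concatenated (256 entering layer
2), then 1 head producing the 256-d node embeddings. Attention logits are
LeakyReLU (slope 0.2) applied to `a·[W h_i ‖ W h_j]`, normalized per
destination neighborhood; dropout 0.3 on attention coefficients and
intermediate features. Self-loops are added before attention so every
neighborhood is non-empty; with self-loops disabled an isolated node is an
error. The layer-1 nonlinearity is ELU and the output layer is linear —
the usual GAT convention; both the hidden width and these nonlinearities
are package choices since only the end-point dimensions are fixed.
"Adjacency normalization" is interpreted as structural cleanup
(deduplication, canonical ordering, self-loops): degree renormalization is
redundant when attention itself computes a per-neighborhood convex
weighting. The patient embedding is a mean (optionally max) pool over
nodes; the pre-pooling node matrix feeds the cross-modal layer.

### Fusion

Composition order: spatial cross-modal attention on the feature map →
global average pool → modality-attention mixing of pooled vectors. This is
the one composition that uses both mechanisms and keeps the fused map at
the encoder's printed shape.

- **Cross-modal graph attention**: per cell `s` and gene `i`,
  `e_{s,i} = LeakyReLU(a_m·(W_m f_s) + a_g·(W_a g_i))`, `β_{s,i}`
  softmax-normalized over genes, message `Σ_i β_{s,i} W_msg g_i` added
  residually (a `residual=False` toggle returns the pure message). The
  attention-space projections (`d′ = 128`) are separate from the message
  projection `W_msg` into channel space. With `W_msg = 0` the residual
  layer is exactly the identity.
- **Modality attention**: `e_mod = vᵀ tanh(W_a z_mod)` (no bias inside the
  tanh), two-way softmax over the two scores, convex mixture of the
  projected vectors (`d = 256`, `h = 128`). The per-patient report (JSON
  lines) records `α_MRI`, `α_Genomic`, and the top genes by
  spatially-averaged `β` as the interpretability surface.

### Classifier

Dense layers 512 → 128 (BN + ReLU; dropout 0.3 after the first), a linear
logit layer with no activation (so negative logits are reachable), Xavier
initialization, and entmax-α output with α = 1.5. The entmax solver uses
exact branches at α = 1 (softmax) and α = 2 (sort-based sparsemax) and
50-iteration bisection on the normalization threshold for interior α — the
bracket `[max(s) − 1, max(s)]` always contains the threshold. The backward
pass uses the closed-form Jacobian `diag(d) − d dᵀ/Σd`, `d_i = p_i^{2−α}`
on the support.

**Loss.** Training minimizes class-weighted negative log-likelihood on
entmax probabilities clamped at 1e-8. Because entmax emits exact zeros, a
confidently-wrong sample contributes a flat-gradient `−log(1e-8)` term;
this is a known sharp edge, accepted for contract simplicity, and the
dedicated α-entmax loss from the sparse-activations literature is left as
future work. Class weights are `n / (C · n_c)`.

## Training protocol

Adam (lr 1e-4, weight decay 1e-5), cosine annealing, batch size 8 with
optional gradient accumulation, early stopping after 15 epochs without
validation improvement, 150 epochs — these published-protocol defaults
appear in `TrainConfig()`. The protocol's source describes both a
150-epoch/batch-8 and a 50-epoch/batch-32 regime; the more detailed
sentence wins the defaults and `TrainConfig.alternate()` provides the
other. `TrainConfig.smoke()` (30 epochs, lr 3e-3, no early stop) is the
package's desk-scale calibration: at tiny-preset capacity and 50-patient
training sets, the larger step size is what makes the planted signal
recoverable within a one-CPU-minute budget. Splits are patient-disjoint,
stratified by label with largest-remainder allocation (15% test; 15% of
the remaining training pool as validation), and a leakage guard asserts
disjointness on every run. Augmentation (random rotation ≤ 10°, gamma
contrast 0.8–1.2 on min–max-rescaled intensities, Gaussian-smoothed elastic
deformation) is applied as extra copies of minority-class training samples
up to class balance when enabled.

## Ablation harness

Four variants train on identical splits and seeds: the full model; a
genomic-only variant whose MRI encoder becomes an adaptive mean-pool plus
1×1×1 projection; an MRI-only variant whose GAT becomes a shared per-gene
linear map; and a concatenation variant that replaces both attention fusion
stages with a linear layer on the concatenated pooled vectors. The stubs
deliberately retain the input plumbing (so tensor shapes and the head are
unchanged) while removing the component's learning capacity.

## Synthetic cohorts

The generator emulates the statistical skeleton of a paired
imaging-genomics cohort: three classes with mildly imbalanced proportions
(0.45/0.30/0.25, largest first), volumes containing an ellipsoidal brain
(intensity 1 + Gaussian noise, sd 0.3) and one ellipsoidal lesion whose
mean intensity rises by `class_id × effect_size` (radius growing mildly
with the shift), and block-correlated log-normal expression (modules share
a latent factor with loading √0.6; module 0's log2 mean shifts by
`class_id × effect_size`). Class counts come from largest-remainder
allocation, so they are exact, and all randomness flows through one seeded
PCG64 generator — cohorts are bit-reproducible. The `xor` mode plants a
purely cross-modal signal: independent image and gene latents whose XOR is
the label, leaving each modality marginally uninformative. Defaults
(60 patients, side-16 volumes, 50 genes, 4 modules) run in minutes on one
core.

What the generator does **not** emulate: MRI physics (bias fields, partial
volume, acquisition heterogeneity), real pathway topologies, sequencing
depth effects, batch effects, or label noise. Passing tests on these
cohorts demonstrates that the architecture can extract planted
cross-modal signal at small scale — not clinical-grade accuracy on real
imaging-genomics cohorts, which would require the full-size configuration,
GPU-scale training, and external validation.

## Numerical choices

- All tensor arithmetic is float64 on a package-internal reverse-mode
  autograd; eval-mode forward passes are bitwise deterministic.
- Batch-norm uses batch statistics in train mode and running statistics
  (momentum 0.1) in eval mode.
- Log-loss uses the natural logarithm with probabilities clamped at 1e-8 —
  required because entmax produces exact zeros (tested explicitly).
- Multiclass metrics are macro-averaged one-vs-rest; binary metrics treat
  class 1 as positive. A class absent from the truth has undefined recall
  and is excluded from macro means with a warning.
- AUC is the Mann-Whitney rank statistic with midranks for ties,
  macro-averaged one-vs-rest for multiclass.
- Adaptive pooling uses the floor/ceil window convention and doubles as the
  (overlapping-window) upsampler when the target side exceeds the input.
- Checkpoints are single-file `.npz` containers with a JSON header carrying
  a format version.

## Known limitations

- The numpy autograd is single-threaded and allocation-heavy; the default
  (DenseNet-121-scale) configuration is constructible and traceable but
  not practical to *train* without an accelerator framework.
- Entmax NLL gradients vanish for samples whose true-class probability is
  exactly zero (see Loss above).
- The genomic branch models one scalar feature per gene (F0 = 1); mutation
  or methylation channels would need a wider input projection.
- The correlation graph is cohort-dependent; transferring a trained model
  to a new cohort requires carrying the training graph topology along (the
  checkpoint stores weights, not the graph).
- XOR-type interaction signals are recoverable only marginally at the
  desk-scale training budget; the ablation comparison is therefore framed
  as "full ≥ single-modality stubs" under majority-of-seeds, not as a
  large separation.
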