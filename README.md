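# mdlca

Multimodal brain-tumor classification from paired MRI and gene-expression
data: a 3D DenseNet volumetric encoder, a graph attention network (GAT) over
a gene-interaction graph, cross-modal attention fusion, and a sparse
entmax-α classification head — with a seeded synthetic paired-cohort
generator so the whole pipeline is testable on one CPU with no downloads.

## The problem

Glioma subtyping (e.g. GBM vs. lower-grade glioma vs. oligodendroglioma)
benefits from combining anatomy (MRI) with molecular state (gene
expression), but the two modalities live in incompatible representations: a
volume `I(x, y, z)` and an expression vector `G = (g_1, …, g_n)`. This
package implements a cross-attention fusion architecture that lets every
spatial cell of the MRI feature map attend over gene-node embeddings, then
convexly mixes the pooled modality vectors.

## The model

**Preprocessing.** MRI: skull-strip by `I_brain = I ⊙ M` with a
morphologically closed binary brain mask `M` (3×3×3 kernel), z-score the
within-mask intensities, resample to `S×S×S`. Genomics: QC filtering
(missingness/variance thresholds, median imputation), `G_norm = log2(G+1)`,
and a gene graph `G = (V, E)` whose edges come from co-expression
(`|Pearson r| ≥ 0.7`) or an explicit interaction list.

**Encoders.** The volumetric encoder is a 3D DenseNet (blocks of
6/12/24/16 layers, growth rate `k = 32`, BN→ReLU→conv composite layers,
`X_l = H_l([X_0, …, X_{l−1}])`), ending in an adaptive pool and 1×1×1
projection to a 256×7×7×7 feature map. The genomic encoder is a two-layer
GAT (8 heads then 1, LeakyReLU slope 0.2 in the attention logits,
per-neighborhood softmax `α_ij`) producing 256-d node embeddings and a
mean-pooled patient vector.

**Fusion.** (1) Cross-modal graph attention: per spatial cell `s`, logits
`e_{s,i} = LeakyReLU(a·[W_m f_s ‖ W_a g_i])` normalize to `β_{s,i}` over
genes, and the message `Σ_i β_{s,i} W_g g_i` is added residually to the
cell. (2) Modality attention: scores `e = vᵀ tanh(W_a z)` for each projected
modality vector feed a two-way softmax `(α_MRI, α_Genomic)`, and
`F_fused = α_MRI Z_MRI + α_Genomic Z_Genomic`.

**Classifier.** Dense layers of 512 and 128 units (BN + ReLU, dropout 0.3
after the first), then `p̂ = entmax_α(z)` with `α = 1.5` — softmax at
`α = 1`, sparsemax at `α = 2`, exact zeros for unlikely classes in between.

All neural components run on a small numpy reverse-mode autograd
(`mdlca._autograd`) written for this package; no GPU frameworks required.

## Worked example

Train the desk-scale preset on a synthetic 60-patient cohort with a planted
class signal in both modalities (lesion intensity and one gene module shift
with the class label):

```python
import numpy as np
from mdlca import SyntheticCohortSpec, generate_cohort_arrays, PreprocessConfig
from mdlca.pipeline import prepare_cohort, TrainConfig, train
from mdlca.model import ModelConfig

spec = SyntheticCohortSpec(n_patients=60, volume_side=16, n_genes=50,
                           n_modules=4, effect_size=3.0, seed=1)
raw = generate_cohort_arrays(spec)
cohort = prepare_cohort(raw["volumes"], raw["masks"], raw["profiles"],
                        raw["labels"], raw["patient_ids"],
                        pre_cfg=PreprocessConfig(target_side=16))
result = train(TrainConfig.smoke(seed=1),
               ModelConfig.tiny(num_classes=3, seed=1), cohort)
m = result.test_metrics
print(f"held-out accuracy: {m.accuracy:.3f}  macro F1: {m.f1:.3f}")
```

Output (about a minute on one CPU core):

```
cohort: 60 patients, 50 genes, 88 co-expression edges
best epoch: 11
held-out accuracy:  0.667
macro F1:           0.730
macro AUC:          0.675
log-loss:           0.981
majority-class rate: 0.450
```

The held-out accuracy (0.667) clearly exceeds the majority-class rate
(0.450): the tiny model recovers the planted cross-modal signal. The
`ablate` entry point retrains four variants (full, genomic-only stub,
MRI-only stub, plain concatenation) on identical splits for
component-attribution tables.

There is also a CLI:

```bash
mdlca simulate --seed 1 --out cohort/
mdlca train    --data-dir cohort/ --config cfg.yaml --seed 1 --out run/
mdlca evaluate --data-dir cohort/ --checkpoint run/model.npz --seed 1 --out eval/
mdlca ablate   --data-dir cohort/ --seed 1 --out ablation/
```

## Layout

| module | contents |
| --- | --- |
| `mdlca.preprocess` | volume/mask/expression types, skull-strip, z-score, resample, QC, gene graph |
| `mdlca.mri_encoder` | 3D DenseNet encoder, shape tracing, checkpoints |
| `mdlca.genomic_encoder` | GAT layers and patient-level genomic embedding |
| `mdlca.fusion` | cross-modal graph attention + modality-attention fusion |
| `mdlca.classifier` | dense head, entmax family (softmax/sparsemax/bisection), losses |
| `mdlca.evaluation` | confusion matrices, rate metrics, log-loss, rank-statistic AUC |
| `mdlca.synthetic_data` | seeded paired-cohort generator (additive and interaction signals) |
| `mdlca.pipeline` / `mdlca.cli` | splits, augmentation, training, ablation, CLI |

See `docs/methods.md` for modeling assumptions, parameter defaults, and
known limitations.
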