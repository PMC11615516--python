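# gcsurv

Multi-omics integration for cancer outcome prediction and biomarker
discovery. `gcsurv` fuses mRNA expression, miRNA expression and gene-level
DNA methylation into one feature-by-sample matrix, learns a low-dimensional
patient representation with a pathway-graph-informed convolutional encoder
trained by self-supervised contrastive learning, scores survival risk with an
elastic-net Cox model, and extracts informative molecular features with an
interpretable boosted-tree stage combined with differential expression
between predicted risk groups.

It is aimed at computational biologists who have per-patient omics matrices,
a clinical survival table and a gene–gene pathway network (e.g. KEGG
connections), and who want both a risk model evaluated by concordance and a
ranked, modality-aware set of candidate biomarkers. A synthetic-cohort
generator with known ground truth makes the entire pipeline testable without
any external data.

## The model

**Fusion.** Modality matrices `X1, X2, X3` (features × samples) are
row-bound: `X = rowbind(X1, X2, X3)`.

**Graph-contrastive encoder.** The gene network `G` is mapped onto fused
features (same-gene features across modalities are tied; network edges link
features of connected genes) and symmetric-normalized with self-loops,
`S = D̃^{-1/2}(A + I)D̃^{-1/2}`. Each sample's fused vector `h` is a
one-channel signal over this graph; a graph convolution `σ(S h w)` followed
by a multilayer perceptron yields the embedding `z ∈ R^d`. Training minimizes
the temperature-scaled contrastive loss over corrupted view pairs
(Gaussian noise, dropout, value swaps, feature masking),

    L_{i,j} = −log [ exp(x_i·x_j / τ) / Σ_{k≠i} exp(x_i·x_k / τ) ],

plus an L2 activity penalty `γ Σ_l ‖F_l‖²`. A fast query encoder `θ_q` is
updated by backpropagation, a slow key encoder by the momentum rule
`θ_k ← λ θ_k + (1−λ) θ_q`.

**Risk model.** An elastic-net Cox model on the embeddings minimizes the
Breslow negative log partial likelihood plus
`λ_EN Σ_j [α|β_j| + (1−α)/2 β_j²]`, with `λ_EN` chosen by cross-validated
partial likelihood. Risk is the linear predictor `r = βᵀz`; patients are
stratified at the median risk.

**Evaluation.** Harrell's concordance index (fraction of correctly ordered
comparable patient pairs), the two-sample log-rank test between risk groups
reported as `|log10 p|`, and Kaplan–Meier curves.

**Feature selection.** A gradient-boosted tree classifier predicts the
high/low risk label from the fused features (tree depth selected from 2–8);
the top 200 features by total-gain importance form `F_XGB`. Welch's t-test
with Benjamini–Hochberg correction between risk groups gives `F_DE`
(|log2 fold change| > 1.6, adjusted p < 0.05). `IFM = F_DE ∪ F_XGB` are the
global informative molecules, `key-IFM = F_DE ∩ F_XGB` the key ones.

## Worked example

```python
from gcsurv import SynthConfig, generate_cohort, PipelineConfig, run_pipeline

mats, surv, graph, truth = generate_cohort(SynthConfig())
result = run_pipeline(mats, surv, graph, PipelineConfig(seed=0))
print(f"held-out C-index : {result.report.c_index:.3f}")
print(f"log-rank |log10 p|: {result.report.abs_log10_p:.2f}")
```

prints

```
held-out C-index : 0.733
log-rank |log10 p|: 3.92
```

The default synthetic cohort has 300 patients, 60 mRNA + 20 miRNA + 60
methylation features, 10 signal genes carrying a latent risk factor with
unit effect size, and ~30% censoring. A held-out C-index of 0.733 means the
model correctly orders 73% of comparable test-patient pairs (0.5 is chance;
the cohort's oracle — the true latent risk — reaches ≈0.75 on the same
split), and `|log10 p| = 3.92` says the two predicted risk groups' survival
curves differ at p ≈ 1.2e-4. The same run reports the feature sets, e.g.
`|key-IFM| = 3`, all of them planted signal mRNAs.

The command-line interface mirrors the library:

```sh
gcsurv simulate --set output.dir=cohort
gcsurv evaluate --config run.yaml      # data paths + stage settings
gcsurv cv --config run.yaml
gcsurv select-features --config run.yaml
```

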