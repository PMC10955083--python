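# mpfusion

Multi-parametric paired-image fusion classification: a dual-branch
convolutional pipeline that fuses two imaging modalities of the same
anatomy — e.g. T2-weighted and dynamic contrast-enhanced MRI slices of
bladder tumors — to predict a binary, patient-level tumor grade
(high- vs low-grade urothelial carcinoma). It is aimed at researchers who
want to study *how* to fuse complementary modalities rather than at
clinical deployment: every component is a configuration switch, and a
bundled synthetic cohort generator with a computable Bayes bound makes the
whole pipeline testable end-to-end without clinical data.

## The model

Each modality is encoded by its own backbone (DenseNet121 topology by
default, producing a `[B, 7, 7, 1024]` map from `[B, 224, 224, 3]`), then
refined by a **Multiscale Attention (MA)** block — 1×1 channel reduction to
512, two parallel Inception+CBAM paths, and an additive jump connection.
The branch maps are pooled to tokens and fused by **Self-Attention Feature
Fusion (SAFF)**: with the two modality tokens and a learnable class token
stacked as X ∈ R^{3×d},

    Q = X·Wq,  K = X·Wk,  V = X·Wv
    g = softmax(Q·Kᵀ / √d)        — modality-specificity matrix
    f = g·V                        — common (attended) features
    h = θ·V + f                    — commonality with residual, θ ≥ 0
    p = splice(g, h)               — fused representation

and p feeds a two-layer softmax classifier. Input-level, feature-level and
decision-level fusion baselines share the same branches and training loop,
so strategy comparisons are one config away. See `docs/methods.md` for
assumptions, defaults and design rationale.

## Worked example

```python
from mpfusion.synthdata import SynthConfig, generate_cohort, bayes_auc
from mpfusion.workbench import synthetic_fusion_benchmark

# three-arm comparison (modality A only, B only, SAFF fusion) on synthetic
# cohorts whose class signal is split across the modalities
table, bounds = synthetic_fusion_benchmark(effect_a=1.0, effect_b=1.0,
                                           seeds=(1, 2, 3))
print(table.groupby("arm")[["accuracy", "auc"]].mean().round(4))
print("joint Bayes AUC bound:", round(bounds["saff"]["bayes_auc"], 4))
```

which prints (seeds 1–3, ~185 test slices per seed):

```
          accuracy     auc
arm
saff        0.8670  0.9330
single_a    0.7889  0.8837
single_b    0.7733  0.8747
```

    joint Bayes AUC bound: 0.9772

Each single-modality arm can exploit only its own cue (texture for A,
rim contrast for B); the SAFF arm sees both and lands between the best
single-modality result and the joint Bayes bound — fusion recovered signal
that neither branch alone could.

The same experiment from the shell:

```bash
cat > config.yaml <<'YAML'
synth: {n_patients_per_class: 20, image_size: 32, seed: 1}
preprocess: {target: 32}
model: {arch: compact-test, use_ma: true, hidden: 64}
train: {epochs: 15, seed: 1}
YAML
mpfusion simulate --config config.yaml --out cohort/
mpfusion prep --manifest cohort/manifest.csv --seed 1 --out split.csv
mpfusion experiment --config config.yaml --manifest split.csv \
    --arms single_a,single_b,saff --out arms.csv
```

`mpfusion train`, `eval`, `cv` (patient-level k-fold with mean/variance
summary) and `tsne` cover the remaining workflows.

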