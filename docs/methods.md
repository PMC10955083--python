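# Methods

## Problem and model

`mpfusion` classifies paired two-modality 2-D image slices (the motivating
setting is multi-parametric MRI of bladder tumors: a T2-weighted and a
dynamic contrast-enhanced sequence per slice) into two patient-level grade
classes. The architecture is a dual-branch fusion network:

1. **Feature extraction.** Each modality passes through its own
   convolutional backbone with no weight sharing. The default is the
   DenseNet121 topology truncated before global pooling, which maps a
   `[B, 224, 224, 3]` batch to a `[B, 7, 7, 1024]` feature map (stride
   product 32). ResNet50 and a simplified depthwise-separable
   ("xception-like") tower are alternative registry entries; a
   `compact-test` backbone (three conv/pool stages, 64 channels, global
   average pool) exists so the full graph trains in seconds on a CPU.
2. **Multiscale Attention (MA).** A plug-and-play block appended to each
   branch: a 1×1 convolution halves the channel count (1024 → 512), two
   parallel IC blocks — an InceptionV1-style stage (1×1 / 3×3 / 5×5
   branches plus a pooled branch, 'same' padding, each convolution followed
   by batch norm and ReLU) followed by CBAM (channel gate then spatial
   gate, both sigmoids in (0, 1)) — extract multiscale, attention-weighted
   features, and a second 1×1 convolution re-projects their concatenation
   before an additive jump connection from the reduced features. Channel
   widths are configuration, not constants, so the same block attaches to
   the compact backbone at 64 → 32.
3. **Self-Attention Feature Fusion (SAFF).** Each branch map is globally
   average-pooled to a d-token (`d` = MA output channels), stacked with a
   learnable class token into `[B, 3, d]`, and passed through single-head
   scaled dot-product attention:
   g = softmax(QKᵀ/√d) (specificity), f = gV (commonality),
   h = θ·V + f (residual-enriched commonality) with θ ≥ 0. The specific
   and common features are spliced into the fused vector p and classified
   by two fully connected layers with softmax output.
4. **Baselines.** Input-level (sample pooling), feature-level
   (concat/add of pooled branch vectors) and decision-level
   (validation-accuracy-weighted soft averaging of two single-modality
   networks) fusion share the same branches and training loop.

## Design choices where the design was open

* **Splicing g with h.** g is `[3, 3]` and h is `[3, d]`, so "fusing" them
  by addition is dimensionally impossible; we read the splice as
  concatenation. The default readout flattens both (`3d + 9` features);
  a `cls` readout (class-token rows only, `d + 3` features) is available.
  Neither is claimed canonical.
* **θ** is a scalar hyperparameter, default 1.0, optionally learnable.
* **Attention scaling** uses 1/√d, the standard scaled dot-product form.
* **One shared class token** is used (not per-modality class codes),
  initialised from N(0, 0.02²).
* **MA internals.** Inception branch widths default to a quarter of the
  reduced width each; the two IC paths are combined by channel
  concatenation then re-projection (an `add` mode is available); the jump
  connection is additive; CBAM uses reduction ratio 16 and a 7×7 spatial
  kernel. Convolutions are 'same'-padded with batch norm + ReLU.
* **Split rounding.** The 8:1:1 stratified split takes
  val = test = round(n/10) per class and train as the remainder — the only
  simple rule that yields 60/8/8 and 50/6/6 from 76 + 62 patients.
* **Fold aggregation** reports the arithmetic mean and the *population*
  variance (÷k) rounded half-even to 4 decimals; population variance is
  the convention that reproduces the reference 10-fold summary
  (0.9375 / 0.0001) from its printed per-fold accuracies, where the sample
  variance would give 0.0002.
* **Evaluation level.** Metrics are slice-level by default (accuracy, F1
  with the high-grade class positive, AUC from the high-grade
  probability); patient-level aggregation by mean probability is an
  option.

## Numerical implementation

The network stack is written on `autograd`/numpy: convolutions are im2col
patch extraction plus a BLAS tensor contraction, and gradients come from
reverse-mode autodiff, verified against central finite differences in the
test suite. Batch normalisation always uses current-batch statistics —
forward passes are pure functions with no running-average state, which
buys exact reproducibility and simple differentiation at the cost of
batch-composition-dependent inference; evaluation batches are processed in
one pass, so reported metrics are deterministic. All computation is
float64 except the 224-input backbone demonstrations (float32 inputs).

Training follows the reference recipe: SGD with learning rate 0.01, batch
size 8, up to 50 epochs, cross-entropy loss plus an L1 penalty
(λ = 10⁻⁵ by default) on weight kernels only, early stopping on validation
loss with patience 10 and best-weight restoration. Pretrained backbone
weights are accepted from a user-supplied file and are never downloaded;
transfer learning and the MA block are independent ablation switches.

## The synthetic cohort and what it shows

The generator emulates a reference-scale clinical cohort: 138 patients by default
(76 high-grade / 62 low-grade, the 55.1 % imbalance), 1–5 paired slices per
patient, grayscale slices replicated to 3 channels. Each slice shows a
lesion disk (radius 0.22–0.30 of the image side, jittered center) on a
constant background with i.i.d. Gaussian pixel noise (σ = 0.05 on a [0, 1]
gray scale). The class signal is split complementarily:

* modality A adds an oriented sinusoid (period 4 px) inside the lesion with
  amplitude 0.12·u_A;
* modality B offsets an annulus (0.8–1.1 lesion radii) by 0.12·u_B;

with latent cue strengths u_m | y ~ N(effect_m·y, cue_noise²), independent
between modalities given the class, cue_noise = 0.5, and 80 % of the cue
variance shared between slices of a patient (so slices are correlated
within patients, which is exactly why patient-level splitting matters).
The latent cue strengths carry Gaussian within-class spread, rather than
being fixed per class, for two reasons: the class overlap is then governed
by the latent model — giving a closed-form Bayes bound that does not
saturate at 1 — while the rendered per-pixel signal stays strong enough
for small networks to learn from small cohorts.

Because an image depends on its class only through (u_A, u_B), the Bayes
accuracy of the 2-D Gaussian cue model upper-bounds every classifier
trained on the images. With equal-covariance Gaussian classes the
log-likelihood ratio is itself Gaussian, giving closed forms (cross-checked
by direct numerical integration in the tests): at effect 1 and the default
prior, a single modality is bounded by accuracy 0.843 / AUC 0.921 and the
joint cue by 0.922 / 0.977 — strictly better, so fusion is provably
beneficial under these conditions.

What the generator does **not** emulate: MRI physics, 3-D anatomy,
acquisition artefacts, inter-scanner variation, or realistic lesion
morphology. Passing the synthetic benchmark shows that the implementation
can discover and fuse complementary cross-modality signal; it says nothing
about clinical performance.

### Benchmark problem sizes

The packaged fusion benchmark trains the compact backbone (optionally with
MA) on 32×32 images: per seed, a 40-patient training cohort split 9:1
train/val at the patient level, evaluated on an independent 60-patient
test cohort (~185 slices) from the same conditions; 15 epochs with early
stopping (patience 4), three seeds. These sizes give Monte-Carlo error
around 0.02–0.03 on an AUC while keeping a full three-arm comparison in a
few CPU-minutes; they are the package's test-scale defaults, and all of
them are overridable.

## Known limitations

* Batch-norm inference uses batch statistics (see above); single-sample
  prediction is therefore not meaningful without a reference batch.
* The attention head is single-head with exactly three tokens; more than
  two modalities would need a generalised token axis.
* The reference manifest copies its per-split slice counts
  verbatim; the augmentation multiplicities behind them (e.g. 155 → 743)
  are non-integer and unexplained in the source, so no multiplicity is
  inferred. Its records are one row per paired slice (wide format), so
  record counts equal slice counts.
* `pretrained=True` requires user-supplied weights; no weight files ship
  with the package, so transfer-learning ablations are only meaningful in
  an ecosystem that provides them.
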