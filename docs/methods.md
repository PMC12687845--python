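# Methods

`latentaug` implements and evaluates two latent-space strategies for
expanding a scarce labeled image cohort — the setting of inherited retinal
disease imaging, where annotated datasets rarely exceed a few hundred
photographs — and ships a synthetic cohort generator so the entire
pipeline is testable end to end without any clinical data.

## The expansion methods

Both strategies rely on a *latent codec*: an encoder mapping an image `x`
to a Gaussian posterior `q(z|x) = N(mu(x), diag(exp(logvar(x))))` and a
decoder mapping a latent vector back to pixel space. Expansion always
operates on the posterior **mean**, never on a sampled `z`. The sampling
path exists only inside VAE training; using the mean makes every synthetic
image a deterministic function of its parents and the seed, which keeps
the augmentation controllable and auditable.

**Random-noise expansion (Gen 1).** Each real training image yields
exactly one synthetic image — a two-fold expansion. A noise scheme is
drawn uniformly from {constant, Gaussian, uniform, sinusoidal} and a
strength `s ~ Uniform(0.05, 1)`; the perturbed latent `mu + eps` is
decoded. Noise is scaled per dimension by `sigma_ref`, the empirical SD of
the training latents (floored at 1e-6), so a given strength displaces the
latent by a comparable fraction of the cohort's spread under every scheme:

| scheme     | eps_i                                                          |
|------------|----------------------------------------------------------------|
| constant   | `s * c * sigma_i`, one `c ~ U(-1, 1)` shared by all dimensions |
| Gaussian   | `N(0, (s * sigma_i)^2)` independently                          |
| uniform    | `U(-s * sigma_i, +s * sigma_i)` independently                  |
| sinusoidal | `s * sigma_i * sin(2 pi f i / d + phi)`, one `(f, phi)` draw   |

The scheme names are fixed by the method; their exact functional forms are
this package's parameterization (the sinusoid runs over the latent index,
the constant offset is symmetric around zero). Each is isolated behind
`sample_noise` so alternatives can be swapped in.

**Pairwise combinatorial expansion (Gen 2).** For every unordered pair of
same-label training images, the latent means are linearly combined,
`z = r * z_a + (1 - r) * z_b`, at ratios from {0.1, 0.3, 0.5, 0.7, 0.9},
and decoded. Two modes exist because the method's published description is
ambiguous about the per-pair count: the default `single` mode emits one
synthetic per pair at a ratio drawn uniformly from the set — exactly
C(n, 2) synthetics per class of size n — while `all` mode emits every
ratio, 5·C(n, 2). Self-pairs are excluded (they reconstruct the parent),
and unordered enumeration avoids the double counting implied by the
symmetry `mix(a, b, r) = mix(b, a, 1 - r)`. Cross-class mixing is never
performed; a class with fewer than two members is skipped with a warning.

## The reference codec

The default codec is a small dense VAE (4096-pixel input → 384 hidden →
64-dimensional latent, mirrored decoder), trained by Adam for 80 epochs on
the loss

    L = mean_pixels (x_hat - x)^2 + beta * KL(q(z|x) || N(0, I)),

with `beta = 1e-3`. The decoder's output layer is **linear** by default
(values clipped to [0, 1] only when an image is emitted); a sigmoid output
is available but optimizes the pixel-MSE objective markedly slower at
cohort scale — its saturation suppresses exactly the fine texture the
class signal lives in. With the linear output and these sizes, cohort-
scale reconstructions retain enough mid-peripheral texture energy that
decoded latent mixtures still carry an (attenuated) class-dependent
texture difference; with the sigmoid decoder that difference vanished
entirely. Latent dimensionality and loss weights are package choices — the
method's description leaves them open. Log-variances are clipped to ±10
for numerical safety, and training aborts with a diagnostic on any
non-finite loss.

The expanders depend only on a minimal codec contract (`encode`,
`decode`, `latent_dim`, `input_side`, both directions deterministic), so a
pretrained image VAE — including one with a spatial latent grid, flattened
to a vector — can be plugged in unchanged. A trivial block-mean
`DownsampleCodec` ships as the contract's reference implementation and
lets structural tests run without any training.

## Evaluation protocol

Splits are made at the **patient** level, stratified by class, so fellow
eyes never straddle a train/test boundary. Two modes: `GROUPED_KFOLD`
(default; each patient appears in exactly one test fold) and
`REPEATED_8020` (independent stratified 80/20 draws — the resampling
reading of the protocol). Per fold, the codec is fitted on that fold's
training records only, expansion is applied to training records only, and
a hard `LeakageError` aborts the run if any synthetic's parent sits
outside the fold's training set. Seeds cascade from one global seed via
tagged derivation, so switching the expansion mode never reshuffles fold
assignment — comparisons across modes are paired.

Metrics: per-fold ROC-AUC (Mann–Whitney form, ties counted half, verified
against an exhaustive pairwise oracle), accuracy / recall / specificity at
a 0.5 threshold on the positive-class score (X_LINKED is the positive
class), and the **pooled AUC** over the concatenation of all folds'
(label, score) pairs. Pooling and averaging genuinely differ when fold
score ranges are miscalibrated; both are always reported. Fold summaries
are mean ± sample SD, with the interval reported as mean ± SD (the
`interval_method` field names the construction).

## The reference classifier

Fine-tuning a pretrained vision transformer is supported only through the
PLUGIN contract (`fit` / `predict_scores`); the built-in reference model
is a deliberately small from-scratch CNN: per-image intensity
standardization, a stride-2 3×3 convolution (8 filters), ReLU, a 3×3
convolution (8 filters), ReLU, and global average pooling, trained with
AdamW-style decoupled weight decay (learning rate 1e-3, 30 epochs, batch
size 8) and in-training augmentation (random resized crop with area scale
in [0.8, 1.0], then random horizontal flip). Global average pooling of
rectified filter responses makes the model essentially a learned
texture-energy detector; per-image standardization removes global
brightness/contrast nuisances such as the shared patient-level offset
between fellow eyes, which would otherwise correlate fellow-eye scores
and inflate the variance of pooled statistics.

Two post-training steps make scores from independently trained fold
models poolable:

1. **Head refit** (default). The SGD-trained sigmoid head of so small a
   network is a noisy, underfit estimator on cohorts of tens of images;
   the decision layer is therefore refit as a regularized logistic
   regression on the real training members' pooled features — a convex
   problem that extracts the learned representation's signal far more
   efficiently. The raw SGD head remains available (`head="sgd"`).
2. **Score calibration.** Each model's scores are mapped through the
   empirical CDF of its real training members' scores. The mapping is
   monotone per fold (fold AUC untouched) and gives every fold model the
   same near-uniform score distribution, so pooled AUC compares like with
   like; without it, fold-specific score offsets of order 0.1 dominated
   the within-fold signal and made pooled AUC nearly uninterpretable.

All numerics (VAE and CNN) run in float32 with manual backpropagation;
convolutions are im2col GEMMs. Training is deterministic given the seed
on a fixed platform.

## The synthetic cohort generator

Fixtures emulate the *statistical structure* of a two-class retinal
cohort, not its appearance: 1–2 eyes per patient (P(two eyes) = 0.95,
matching a cohort of ~105 eyes from ~53 patients), left/right laterality
with the bright optic-disc surrogate on the nasal side (OD images are
exact mirrors of the OS geometry until harmonization flips them), a
darker macula surrogate, curvilinear dark vessel strokes, i.i.d. pixel
noise (SD 0.02), and a per-patient brightness offset (SD 0.05) shared by
fellow eyes — the source of fellow-eye correlation.

The class signal is a **speckle-density difference** in a mid-peripheral
annulus (a bone-spicule pigment surrogate): dark 2×2 dots at density
`0.010 * (1 + effect_size)` per band pixel for the X_LINKED class versus
`0.010` for AUTOSOMAL. At `effect_size = 0` the classes are identically
distributed, giving an exact null for calibration tests.
`fixture_signal_check` quantifies the injected signal with a permutation
test on per-image high-pass band energy.

Class labels are **independent Bernoulli(class_balance) draws per
patient** (redrawn deterministically in the rare event a class has fewer
than two patients). An earlier design that fixed the class count exactly
was abandoned: assigning labels without replacement makes chance
feature–label associations in the training partition *negatively*
dependent on those in the test partition (a finite-population effect), so
a flexible classifier systematically anti-learns under the null — pooled
null AUC showed seeds with every fold far below 0.5. With independent
labels the null is clean: pooled AUC at 40 patients stays within ±0.07 of
0.5 across seeds.

What the fixtures do **not** emulate: color, realistic retinal texture,
disease progression, image-quality artifacts, or inter-eye asymmetry of
disease stage. Passing tests on fixtures therefore demonstrate that the
pipeline's *mechanics* (counts, leakage control, null calibration, and
the direction of the expansion effect under a learnable sub-visual
signal) are correct — not that expansion improves any particular clinical
task.

## Study conditions used by the acceptance checks

Problem sizes are chosen so the full suite runs in minutes on one CPU:
64 px images, five grouped folds, 40 patients for null calibration and
leakage checks, and 20 patients for the scarce-cohort benefit comparison
(the smallest size at which five patient-grouped folds are reliable under
Bernoulli labels). The benefit cohort's `effect_size = 0.4` was fixed by a
calibration rule applied to the baseline only: it is the signal level at
which the unexpanded classifier's mean pooled AUC lands partway between
chance and ceiling (~0.7), emulating a hard-but-learnable sub-visual
signal. The directional comparison (Gen 2 ≥ Gen 1 ≥ base within
tolerance, Gen 2 above base) is averaged over five seeds; it is a
stochastic check and single-seed inversions are expected.

Two caveats on interpreting the benefit comparison. First, synthetic
images are deterministic functions of the real training images, so no
fixed-dimension, well-regularized decision layer can extract *more*
information from them; the benefit flows through the interaction of the
expanded training set with the conv-stack representation and through
manifold densification by latent mixing, and its desk-scale magnitude
(a few AUC points) is far smaller than what fine-tuning a large
pretrained backbone on faithful synthetics can show. Second, the decoded
synthetics are visibly smoother than real images; the head refit on real
members keeps this domain shift out of the decision layer.

## Known limitations

- The dense VAE reconstructs small cohorts with visible smoothing; a
  stronger pretrained codec can be substituted through the codec
  contract and should widen the expansion benefit.
- Per-fold VAE retraining (the default, chosen to rule out codec-level
  leakage) differs from workflows built on externally pretrained codecs;
  `shared_codec` reproduces those.
- Grayscale only by default; 3-channel inputs are averaged to one plane
  by the built-in models (the expansion algorithms themselves are
  channel-agnostic).
- Accuracy/recall/specificity use a fixed 0.5 threshold on calibrated
  scores; no further threshold tuning is performed.
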