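# Methods

`dermforge` implements a three-stage pipeline for studying medical deepfakes
in dermoscopy: (1) a label-conditioned GAN that synthesizes six-class
skin-lesion images, (2) a representation similarity analysis (RSA)
quantifying how closely the fakes resemble real images, and (3) a family of
Vision-Transformer (ViT) binary classifiers that detect the fakes. All
neural models run on a small reverse-mode autodiff engine written in numpy
(`dermforge.nn`); no deep-learning framework is required, which keeps the
whole pipeline runnable and testable on a single CPU.

## Fixture world

Real dermoscopic corpora (public skin-lesion archives) cannot ship with a
package, so `dermforge.fixtures` procedurally generates stand-ins:

- **Lesion images.** A uniform skin-tone background (RGB ≈ (0.87, 0.72,
  0.62), ±0.03 jitter) carries one rotated elliptical lesion whose color is
  drawn from one of six fixed RGB centroids (one per class: AKIEC, BKL,
  NEVI, VASC, BCC, MEL) with ±0.05 per-channel jitter, a soft feathered rim
  confined strictly inside the ellipse, a mild radial darkening texture,
  and 0–3 dark Bezier "hair" strokes. Centroids are pairwise separated by
  ≥ 0.15 in at least one channel so a nearest-centroid classifier on mean
  lesion color exceeds 80% accuracy at 20 images per class — the classes
  are learnably conditioned, which is all the GAN conditioning pathway
  needs at desk scale.
- **Fake fingerprint.** Generative models leave periodic spatial artifacts
  ("checkerboard" traces). The fixture stand-in is an additive 2-D
  sinusoidal grid, `a·sin(2πx/8)·sin(2πy/8)` with default amplitude
  a = 0.05 and period 8 px, identical in all channels and clipped to
  [0, 1]. It is invisible casually (peak-to-peak 0.1) yet concentrates
  spectral power at the 1/8 cycles-per-pixel band, giving the detector a
  learnable, quantifiable real-vs-fake signal. Amplitude is capped at 0.2.
- **Corpora.** `build_corpus` writes PNGs plus a CSV manifest
  (`path,class_id,provenance,split`), stratifies a 75:25 train:test split
  within each (class, provenance) group, and is bit-reproducible under a
  fixed seed.

What a green test on fixtures does *not* establish: photorealism, the
statistics of real dermoscopy (hair density, color calibration, lesion
morphology diversity), or detector performance against real GAN
fingerprints, which are subtler and less stationary than a fixed sinusoid.

## Conditioned GAN

**Generator.** Latent z ∈ R²⁵⁶ ~ N(0, I) → dense layer to 128·8·8 = 8192
units → LeakyReLU(0.2) → reshape to 8×8×128. Class label c ∈ {0..5} →
64-dim embedding → reshape to 8×8×1. Concatenation gives 8×8×129, upsampled
by DCGAN-style transposed convolutions (kernel 4, stride 2, pad 1,
LeakyReLU 0.2) through 8→16→32→64→128, then a 3×3 convolution to RGB with a
sigmoid output. The sigmoid keeps pixels on the normalized [0, 1] scale the
post-processing threshold assumes. No batch normalization: at desk batch
sizes its statistics are noisy, and the plain DCGAN stack trains stably
here (a deliberate design choice where the architecture description was
silent).

**Discriminator.** The label is embedded (64-dim), linearly upscaled to a
full-resolution plane, and concatenated with the image as a fourth channel.
Four stride-2 convolutions (kernel 4, LeakyReLU 0.2) downsample 128→8,
followed by flatten, 40% dropout, and a single sigmoid unit. The conv
stack uses a constant filter width (`base_filters` per stage): with a
half-width discriminator the desk-scale adversarial game was unstable (the
generator overran the discriminator in a fraction of seeds), while a
doubling schedule made the discriminator saturate and the generator never
improve; constant width keeps the game near equilibrium with the
discriminator above chance — the qualitative regime the full-scale
training curves show.

**Losses.** Binary cross-entropy on the sigmoid output, probabilities
clamped to [1e-7, 1−1e-7] before logs. The discriminator objective is
reported split into its real half (target 1) and fake half (target 0); the
generator uses the non-saturating reversed-label form (generated images
scored against target 1 through the frozen discriminator).

**Training loop.** Per epoch: (1) one Adam update of D on a half batch of
real images, (2) one separate Adam update of D on a half batch of freshly
generated images, (3) one Adam update of G through the combined module with
D's weights excluded from the optimizer (frozen). Adam lr 2e-4, β₁ 0.5 for
both networks (DCGAN convention). Dropout stays active in all three
forward passes, mirroring framework training-mode semantics; the
half-batch accuracies are measured on those same passes. Parameter
bookkeeping mirrors the combined-module convention in which the
discriminator is counted twice (one weight set per real/fake pass):
total = params(G) + 2·params(D), with exactly params(D) non-trainable
during a generator update.

**Scale config.** `GanConfig.desk(32)` shrinks the geometry proportionally
(32×32 output, two upsampling stages, latent 64, base filters 32) so a
200-epoch, batch-32 run takes ~1.5 min of CPU; the default config
reproduces the full 128×128 geometry.

**Post-processing.** `interpolate_black_pixels` removes the isolated
near-black dropouts that generated dermoscopy exhibits (hair occlusions in
the training data): any pixel with all channels ≤ 0.1 is replaced by the
per-channel median of the non-black pixels in its 3×3 window, iterating
until convergence. Pixels above threshold are never altered; the operation
is idempotent once converged; a fully black image is returned unchanged
with a warning.

## Representation similarity analysis

Each image is converted to luminance grayscale (Rec. 709 weights via
scikit-image), bilinearly resized to 200×200 and flattened row-major to a
40,000-dim vector. Grayscale is forced by the 40,000 = 200·200 dimension
(three channels would give 120,000); luminance is the conventional
reduction. Pearson correlation uses population covariances
(C_xy = Σ(xᵢ−x̄)(yᵢ−ȳ)/D, divide by D not D−1); a zero-variance vector
yields NaN rather than an arbitrary 0. The RSM samples 30 images per pool
(real, fake) without replacement under a seed, uniformly over each pool
(not stratified by lesion class), and reports the 60×60 matrix with the
real block first, plus mean off-diagonal block correlations as a soft
realism readout.

## ViT detector

`ViT<a>/<b>` tiles an a×a image into non-overlapping b×b patches
(row-major; re-assembly is bit-exact), flattens each to 3b² elements,
projects linearly to a 64-dim embedding, prepends a learnable class token,
adds learnable positional embeddings, and applies 8 pre-norm encoder blocks
(4-head scaled dot-product self-attention + 2× MLP with GELU, residual
connections). Variants tiling to ≤ 4 patches (ViT64/32, ViT32/16) are
rejected — four tokens give attention nothing to work with.

**Classifier head.** Two conventions exist. The head can read the class
token's encoder output alone (`head_mode="token"`), or flatten the entire
encoded sequence before the dense layers (`head_mode="flatten"`, the
convention of the widely-copied Keras reference implementation). The
published per-variant parameter counts scale almost purely with token count
(4.4 M at N=16 whatever the patch pixel count, 10.7 M at N=64, 35.1 M at
N=256), which only the flatten head produces, so flatten is the default
with head widths (2048, 1024); this also makes parameter count grow
monotonically as the patch size halves. Both modes are implemented and
tested; attention permutation-invariance (zeroed positional embeddings)
holds for the token head only, by construction. Counts are *reported*
(`derm-forge vit-report`), never asserted, since encoder width/depth are
free parameters.

**Training.** 75:25 train:test from the manifest; 30% of train redrawn
every epoch as validation; batch 10; Adam at defaults (lr 1e-3);
categorical cross-entropy on the 2-way softmax. Augmentations on training
batches only: random horizontal flip (p = 0.5), random rotation up to
±0.2 of a full turn (±72°), random zoom with scale in [0.8, 1.2] —
fractional factors read the conventional way — after dataset mean/std
normalization whose statistics are stored on the model and re-applied at
prediction time. Positive class is *real* throughout: a false negative is
a real image classified as fake.

One fixture-specific caveat: the geometric augmentations scramble the
fixed-orientation sinusoidal fingerprint that defines fixture fakes
(rotation/zoom resampling moves and attenuates its spectral peak), so a
desk-scale model trained with them sits at chance while the same model
without them separates the classes perfectly. Real GAN fingerprints are
broader-band and survive augmentation; the fixture artifact does not.
Desk-scale configurations therefore default to `augment=False`, while
`DetectorConfig` keeps the full protocol on by default.

## Evaluation

Confusion counts, row-normalized confusion, accuracy/precision/recall/F1
(zero denominators → NaN, flagged not silently zeroed), and macro-averaged
variants. ROC and PR curves come from a threshold sweep over the unique
scores (scikit-learn); AUC is the trapezoidal integral of TPR over FPR and
equals the Mann–Whitney pairwise-concordance statistic with ties counted
0.5, which the tests verify to 1e-10.

## Numerical choices

- float64 everywhere: desk-scale models are small enough that
  finite-difference-checkable gradients are worth more than speed.
- Probability clamp 1e-7 before logs; layer-norm ε 1e-5; Adam ε 1e-8.
- Weight init: N(0, 0.02) in both GAN networks (DCGAN convention); Glorot
  normal in the ViT.
- Every stochastic operation takes an explicit seed; derived per-image
  seeds are deterministic functions of (corpus seed, class, index).

## Known limitations

- Desk-scale adversarial training is qualitative: it demonstrates stable
  alternating optimization and an above-chance discriminator, not the
  photorealistic convergence a GPU-scale run on real dermoscopy reaches.
- The sinusoidal fingerprint is a much easier detection target than real
  GAN artifacts; detector accuracies on fixtures say nothing quantitative
  about real-world deepfake detection.
- The numpy engine is single-threaded and eager; the default 128×128 GAN
  geometry builds and runs forward passes quickly, but full 1200-epoch
  training at that size is out of desk scope.
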