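# Methods

## Pipeline

A conditional generator and a tile classifier are trained on the same
labelled tiles. For each integer seed the generator renders one image per
class by passing that class's embedding to every synthesis layer; the images
are center-cropped to the classifier's μm field of view, resampled to its
input resolution, stain normalized per the configured method, and
classified. Seed triage follows the prediction-strength rules below; the
strongly concordant seeds feed class blending (embedding interpolation) and
layer blending (per-layer embedding assignment).

## Prediction strength and seed labels

Categorical outcomes: the predicted class is the post-softmax argmax, and
the prediction is *strong* iff that value strictly exceeds 0.75. Continuous
outcomes in [−1, 1]: the predicted class is the sign, and the prediction is
*strong* iff the absolute value strictly exceeds 0.5. Boundary values
(exactly 0.75 or ±0.5) are therefore weak, an argmax tie resolves to the
lowest index with weak strength, and a continuous prediction of exactly 0
carries no sign and matches neither class (it can only produce
non-concordance). A seed is *strong* when both images are correctly and
strongly predicted, *weak* when both are correct but either is weak, *non*
when either is wrong. The three labels partition any seed set; summary
proportions are computed in rational arithmetic so they sum to 1 exactly.

## Mini models

No tensor-autograd library is used; both models are compact numpy networks
with hand-written gradients and Adam.

**Classifier.** Flattened 32×32 RGB tiles → two ReLU hidden layers of width
1024 with dropout p = 0.1 after each → softmax (cross-entropy) or a scalar
clipped to [−1, 1] (mean squared error). Mini-batches are category-balanced
(continuous targets balance on their sign). Training augmentation: a
uniform draw from the 8 dihedral states, JPEG compression with probability
0.5 at quality uniform in [50, 100], Gaussian blur with probability 0.1 at
σ uniform in [0.5, 2.0]. Defaults: batch 32, 300–600 Adam steps at 1e-3.
Dropout is disabled at inference, so prediction is deterministic and
batch-invariant; stain normalization runs inside `predict()`.

**Conditional GAN.** The generator is a 4-layer MLP (latent 64, hidden 256,
sigmoid output at 32×32×3) in which layer *l* computes
`h_l = lrelu(W_l h_{l−1} + U_l e_l + b_l)` — the embedding enters every
layer, which is what makes layer blending meaningful. One learned
32-dimensional embedding per class. The discriminator is a frozen
random-feature map (3072 → 512 leaky-ReLU projection) with one trainable
linear head per class. Because the trainable part is linear, the parameter
gradient of the R1 penalty `(γ/2)·E‖∇_x D‖²` is analytic — no second-order
autodiff — while the generator still receives the full adversarial input
gradient. Losses are the non-saturating logistic pair, R1 γ = 1.6384,
batch 32, Adam with β₁ = 0 (discriminator heads use a larger step, 5e-3
vs 1e-3, since they are linear). The output bias is initialized to the
logit of the dataset mean image so early training spends its budget on
structure and class response rather than global brightness. The integer
seed maps to a latent through a fixed Philox stream; this mapping is part
of the public contract. StyleGAN-specific machinery (mapping network,
path-length regularization, adaptive augmentation) is deliberately absent:
only the R1 objective and the per-layer conditioning contract are kept.

## Synthetic data

`gen_texture_tile` renders class A as round "follicle" blobs with a cool
tint and class B as striated bands with a warm tint on a near-white,
eosin-cast background, plus a shared per-pixel speckle field (σ = 0.18 in
[0, 1] units). A tile at class score `s` is the exact alpha blend
(α = (s+1)/2) of the two pure renderings for the same seed, so every channel
mean is linear in the score before uint8 quantization and the class axis is
recoverable from mean color. The speckle amplitude is constant so in-focus
tiles always clear the blur-QC threshold.

`gen_synthetic_slide` lays rectangular tissue patches on a 128-px lattice
with one-cell margins (the tissue mask has exactly the requested number of
connected components), renders them with a darker base color so slide-level
Otsu thresholding separates tissue from the white background, and defocuses
a chosen fraction of tissue cells with a σ = 8 Gaussian. Because geometry is
lattice-aligned, every default-preset tile window is purely tissue,
background, or blurred tissue, and the QC decision for each tile is
unambiguous — this is what lets tests compare the kept-tile set against a
brute-force oracle computed from the ground-truth masks *exactly*.

The analytic generator has L = 4 layers with fixed unit row-vectors
w_l (the standard basis, d = 4) and class response
`(1/L)·Σ_l ⟨w_l, e_l⟩`; class A's embedding is (−1,…,−1) and class B's
(+1,…,+1), so interpolation at t gives response 2t−1 exactly. The rendered
tile visualizes that response; additionally the exact float64 response is
stamped into a 4-pixel corner tag (magic pixel, 8 payload bytes, parity
byte) that the oracle classifier reads back. The tag is what makes
blend-path linearity checks *bit-exact* despite uint8 image boundaries; on
untagged images the oracle classifier falls back to a mean-color
projection. Passing tests on these fixtures demonstrates the pipeline's
arithmetic and contracts, not photorealism: the textures have none of real
histology's nuclear detail, stain variability, or scanner artifacts, and
class separability is far better than any real molecular endpoint.

## Tile extraction and QC

Tiles live on a non-overlapping grid of half-open windows addressed by
their 0-based top-left corner; the source window is `round(tile_um / mpp)`
pixels and is resampled bilinearly to `tile_px` (default presets:
302 μm → 299 px for classifiers; 400 or 302 μm → 512 px for generators).
With an ROI, a tile is emitted iff its center lies inside a polygon.
Three filters, each with config-exposed parameters:

- grayspace: pixel is gray when its channel spread is < 0.05 (on [0, 1]);
  reject when the gray fraction exceeds 0.7;
- Otsu: threshold fitted once per slide on a grayscale thumbnail (max
  dimension 1024); reject when the below-threshold (tissue) fraction of the
  tile is < 0.5;
- blur: reject when the variance of (gray − gaussian(gray, σ = 3)) is
  < 0.02.

The blur statistic (residual variance) is a declared choice: it is monotone
in defocus, cheap, and compatible with the σ = 3 / 0.02 parameterization.
The grayspace and Otsu parameters are likewise package defaults in the
spirit of standard WSI QC, not values inherited from elsewhere.

## Stain normalization

Reinhard transfer matches per-channel mean/std in CIELAB. "Brightness
standardization" is interpreted as a pre-fit luminance rescaling: scale the
RGB image so its 95th-percentile luminance maps to 0.95; the *modified*
variant removes exactly that step (and is therefore not invariant to global
brightness changes, while the full variant is). Macenko fits the two stain
vectors as the 1st/99th-percentile extreme angles of the optical-density
cloud in its top-2 principal plane (pixels with all OD channels > β = 0.15;
at least 100 required), orders hematoxylin first by red absorption, and
rescales concentrations to the target's 99th-percentile maxima. Generated
images are never normalized at generation time; normalization happens only
in front of the classifier. The default normalization target is a fixed
package fixture tile.

## FID

`FID = ‖μ_a−μ_b‖² + tr(Σ_a + Σ_b − 2(Σ_a Σ_b)^{1/2})` with unbiased (n−1)
covariances. The square root is computed symmetrically —
`S = Σ_a^{1/2}`, then `(S Σ_b S)^{1/2}` via eigendecomposition with negative
eigenvalues clipped to zero — which is exact for commuting covariances and
numerically stable otherwise; a negative total beyond 1e-6 relative is
raised as an error rather than silently clipped. The shipped embedder is a
fixed-seed two-layer random projection (leaky ReLU, 64 features at 32 px):
deterministic and dependency-free, so FID values are comparable across runs
of this package but not against published Inception-based numbers. Any
callable image-batch → features can be plugged in instead.

## Transition statistic

For a blend path with predictions p₁…p_K, the per-step change fractions are
δ_k = (p_{k+1} − p_k)/(p_K − p₁); they telescope to 1 per path, so the mean
curve across paths is a distribution of "where the transition happens" over
the blending axis. Paths with zero total change are excluded with a
warning. Across paths the module reports per-step mean, standard deviation,
a normal-approximation 95% CI (mean ± 1.96·SE), and — since it is ambiguous
whether aggregated curves should be normalized per path — the raw mean
prediction curve as well.

## Evaluation statistics

AUROC is the Mann–Whitney statistic with ties counted half. DeLong variance
uses the structural components (per-positive and per-negative placement
means with unbiased variances); CIs are normal-approximation, clipped to
[0, 1], and a zero variance collapses the CI to the point estimate with a
warning. The paired DeLong test is two-sided by default (flag-exposed). The
teaching instrument assigns boundary |prediction| = 0.5 tiles to the weak
stratum (the strong rule is a strict inequality), merges trios horizontally
with a 4-px white gutter in randomized order, and shuffles items uniformly
(not stratified — the choice is a uniform shuffle). The paired t-test is
one-sided (post > pre) with a one-sided lower confidence bound; zero
variance of the differences yields a degenerate report (p = 0.5 at zero
mean, else 0 or 1).

## Problem sizes and numerical choices

The default study conditions are miniature by design: 32×32 tiles, 400
training tiles (200 per class), 300-step classifier training, 12 kimg of
GAN training, 200 triaged seeds, 100-step blend paths (20 in the demo), and
2000-sample FID (256 during training checkpoints). These sizes are the
package's own desk-scale defaults; each module accepts larger values
through its config. Tolerances: bit-exact determinism for all generation
paths; 1e-6 for analytic R1 and closed-form FID; one intensity level for
stain round trips; 2° for Macenko recovery; stochastic bounds (accuracy
≥ 0.9, FID decrease, ≥ 70% conditioning agreement) for trained models.

## Known limitations

- The mini-GAN's frozen-feature discriminator caps achievable realism; it
  suffices for color/texture class structure, not fine morphology.
- The random-projection FID embedder makes values internally consistent but
  not comparable to Inception-based FID.
- Reinhard statistics match the target exactly only for in-gamut images;
  gamut clipping after LAB transfer can shift moments by ~1e-3.
- Synthetic fixtures are far more separable than real molecular endpoints;
  passing stochastic bounds here says the pipeline works, not that any
  particular real-data performance is attainable.
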