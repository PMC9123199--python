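# Methods

## The task and the model

Surface-coil EPI volumes are modeled as `source = A · b + ε`, where `A`
is the bias-free head image, `b` a smooth multiplicative coil sensitivity
in (0, 1], and `ε` additive Gaussian noise. The processing goal is the
map `source → A · mask`, i.e. simultaneous bias removal and brain
extraction. A conditional GAN learns this map: a 3D U-Net generator
receives the raw volume as its only input (no noise variable — the
deterministic image-to-image setting), and a 3D PatchGAN discriminator
receives the (condition, candidate) pair channel-concatenated at its
input and outputs a grid of per-receptive-field probabilities through a
sigmoid. The objective is the conditional-GAN value plus λ = 100 times
the per-voxel mean absolute error; the generator minimizes the
non-saturating form −mean log D(c, G(c)) plus λ·L1, the discriminator
minimizes −mean log D(c, x) − mean log(1 − D(c, G(c))). Probabilities
are clamped to [1e−7, 1 − 1e−7] before logs, so all losses are finite for
all inputs.

Architecture conventions follow the original image-to-image design where
the configuration is not otherwise pinned down: leaky-rectifier slope 0.2
in the encoder and discriminator, rectifiers in the decoder, tanh output,
batch normalization everywhere except the first encoder block, the
bottleneck and the output block, dropout (rate 0.5) on the leading
decoder blocks, feature maps doubling per level capped at 8× the base
width, and weight init N(0, 0.02). Dropout is applied only to non-final
decoder blocks — the output block is a bare transposed convolution with
tanh, so the effective count is min(dropout_layers, depth − 1); at full
depth 6 the default of 3 reproduces the "first half of the decoder"
convention, and the depth-3 desk-scale network uses depth // 2 = 1.

### Numerical core

No deep-learning framework is used: `ganstrip.nn` implements strided 3D
convolution via stride-tricks patch views and `tensordot`, the transposed
convolution as the exact adjoint of that convolution (so the k = 4,
s = 2, p = 1 shape algebra — halving/doubling each axis — and the
gradients are consistent by construction), batch normalization over the
spatial axes (batch size 1 throughout, so train-mode statistics are
per-volume; inference uses the running averages accumulated with
momentum 0.1), inverted dropout, and Adam with β₁ = 0.5, β₂ = 0.999.
Everything is float32; gradients of every layer and of the assembled
U-Net are checked against finite differences and directional derivatives
in the test suite.

## Training protocol

One iteration = one training pair: a discriminator update on the real
pair (label 1) and the current fake (label 0), then one generator update;
data order is reshuffled per epoch from a seeded RNG; weights are
checkpointed every epoch. Default hyperparameters: lr_G = 2·10⁻⁴,
lr_D = 1·10⁻⁶, 200 epochs, batch 1, λ = 100. The strongly asymmetric
learning rates keep the adversary from overpowering the generator; in the
desk-scale runs the discriminator terms stay near the balanced-game value
ln 2 while the L1 term falls by more than an order of magnitude. A
non-finite loss aborts training with a divergence diagnostic. Model
selection evaluates every checkpoint on held-out pairs (CAD, L2, MSSIM on
the [0, 1] display scale) and picks the highest mean MSSIM, ties to the
earliest epoch.

The learning-rate search probes candidate (lr_G, lr_D) pairs for a few
epochs and rejects a pair when (a) any loss becomes non-finite, (b) the
final-epoch mean of the generator composite exceeds R = 10 times its
first-epoch mean, (c) the adversarial term alone exceeds R·ln 2 — the
composite is λL1-dominated, so discriminator saturation (e.g. lr_D ≥ 1,
which saturates D within the first probe epoch and makes its own first
epoch useless as a baseline) is detected against the balanced-equilibrium
reference instead — or (d) the final-epoch SD of the composite exceeds
5× max(first-epoch SD, 1% of the first-epoch mean); the floor keeps a
near-constant first epoch (few iterations) from flagging a calm run as
oscillatory. Among survivors the pair with the lowest final composite
wins.

### Desk-scale configuration

Tests and the acceptance workflow run 8 training / 2 held-out phantoms on
16³ grids with a depth-3 U-Net and a 3-level PatchGAN, 30 epochs
(240 iterations), base width 32. The width matters: with Adam, each
parameter moves at most ≈ lr per step, so the total per-coordinate
displacement in 240 iterations at lr 2·10⁻⁴ is ≈ 0.05 — the network can
only reach the target amplitude if enough coordinates contribute, i.e.
convergence within a fixed iteration budget is bought with width, not
with learning rate. At base 8 the desk-scale run plateaus before the
prediction overtakes the raw source in CAD; at base 32 it converges
(CAD ≈ 0.96, MSSIM ≈ 0.9) in ~12 s on one CPU.

## Volume handling

Min–max normalization (per volume: `Â = 2(A − m)/d`, m mid-range,
d range) maps any input to exactly [−1, 1]; a constant volume has no
defined map and raises a dedicated error. Source and target of a pair
are normalized independently, each storing its own (m, d) for exact
inversion; display rescaling is the affine 0.5·x + 0.5. Stride-2
encoders need axes divisible by 2^depth, so volumes are zero-padded
symmetrically (extra voxel trailing) to the next multiple and cropped
back after prediction; padding is recorded in JSON sidecars together
with (m, d). NIfTI-1 I/O preserves data at float32 and voxel size in the
header; volumes are used in stored voxel order with no reorientation.
Non-finite voxels are rejected at read time.

## Synthetic phantoms

`make_brain_phantom` builds a labeled head: an ellipsoidal brain with a
WM core (55% of the brain axes), a GM rim, two CSF pockets at fixed
fractional offsets, a scalp/muscle shell grown from the brain surface by
Euclidean distance, and (SE only) a disjoint high-intensity sphere above
the head. A seeded smooth multiplicative texture (amplitude 0.05) gives
tissue realistic local structure, and a Gaussian blur (σ = 0.6 voxel)
softens compartment edges; intensity support is confined to labeled
voxels so that with no shell and no external object the brain mask equals
the nonzero support exactly.

Modality defaults encode what distinguishes the two protocols in real
rodent data:

| parameter | GE (mouse-like) | SE (rat-like) | why |
|---|---|---|---|
| tissue intensities WM/GM/CSF | 0.7 / 1.0 / 1.4 | 0.55 / 0.95 / 1.8 | T2\* vs T2 weighting at long TE (CSF far brighter in SE) |
| shell intensity | 0.35 | 0.9 | scalp/muscle signal much stronger in spin echo |
| external reference object | absent | present | only the SE protocol images one above the head |
| brain semi-axes (× grid) | 0.30, 0.27, 0.25 | 0.36, 0.33, 0.28 | SE data come from the larger rat brain filling more of the FOV |

The geometry/contrast separation is what makes single-modality models
measurably prefer their own modality; with a shared distribution the SE
task is strictly a superset of the GE task and an SE-trained model would
score *higher* on the easier GE scenes.

The coil field uses the normalized on-axis magnitude of a circular loop,
`b = floor + (1 − floor)·a³/(a² + d²)^{3/2}` with d the mm distance from
the coil center (default: centered over the head, 15% of the grid above
the dorsal face; radius 35% of the in-plane FOV; floor 0.15). It is
monotone along depth, equals 1 at the coil center and tends to the floor
far away; `floor = 1` gives the uniform-coil identity. The source is
`intensity × bias + N(0, σ)` clipped at 0 (σ = 0.05 by default — noise is
Gaussian on real-valued magnitude images, which keeps the noiseless limit
exact; clipping rectifies background noise, so noise-level checks are
made on head voxels where clipping never binds). The target is the
unbiased intensity restricted to the brain mask.

`make_dataset` jitters geometry, intensities and coil placement by ±10%
per phantom from a seeded stream and assigns exactly
round(n · test_fraction) pairs (at least one, at pair level, not
stratified by modality) to the test split — mirroring a
roughly-10%-held-out protocol. Every operation is a pure function of
(spec, seed): texture and noise draw from separate spawned streams of the
spec seed.

What the phantoms do **not** emulate: EPI geometric distortion,
ghosting, multiband slice leakage, motion, within-cohort anatomical
variability beyond affine jitter, partial-volume effects, or
imperfections of real training targets (e.g. residual bias in reference
corrections). Passing desk-scale tests therefore demonstrates that the
architecture, objective and selection machinery can learn and undo the
modeled corruption classes — not that a model trained here transfers to
scanner data.

## Evaluation metrics

All metrics compare display-rescaled [0, 1] volumes, whole-volume
including background. CAD is the cosine of the angle between flattened
volumes; L2 the Euclidean distance, with MSE = L2²/N and
PSNR = 10·log10(1/MSE) derived from the same quantity (peak 1 on the
display scale). MSSIM slides a 7³ window at stride 1 over all
fully-interior positions (a (64, 16, 64) grid gives 58×10×58 windows);
per window the luminance, contrast and structure factors use moments
weighted by a unit-sum circular-symmetric Gaussian of SD 1.5 samples
(population-style, no Bessel correction), stabilizers C1 = 10⁻⁴,
C2 = 9·10⁻⁴, C3 = 4.5·10⁻⁴, exponents all 1. The window size itself is a
choice — only the Gaussian SD and the window-count convention pin it
down; 7³ is consistent with both and configurable. Dice binarizes both
volumes at intensity **strictly greater than** 0.05 (boundary behavior
documented and tested; pre-binarized masks pass through unchanged) and
is an error when both masks are empty. Cohort tables report mean, sample
SD (ddof = 1), max, min; per-pair failures are recorded alongside, never
silently dropped.

## Experiments and reproducibility

`run_experiment` chains simulate → split → train → select → predict →
report for the three regimes (GE-only, SE-only, mixed), writing volumes,
checkpoints, logs, reports, the resolved config and a manifest; each
stage's seed is derived from the master seed by hashing the stage name,
so adding a stage never shifts the others. `cross_modality_eval` scores
any set of trained models on each modality subset of a mixed test set,
one row per (model, modality) cell; an incompatible cell is recorded as
missing rather than aborting the table. Between-group significance
testing of metric tables is deliberately left to standard statistics
libraries.

## Known limitations

* Batch-size-1 batch normalization means train-mode statistics are
  per-volume; inference uses running averages, which converge only after
  enough iterations.
* The numpy engine is single-threaded per operation and intended for
  desk-scale problems; full-scale 6-deep training on 64³+ grids is
  possible but slow.
* Checkpoint selection uses the same held-out pairs later reported as
  test results (no third split), so the selection is mildly optimistic —
  the random split is at pair level and can place related phantoms on
  both sides.
* MSSIM exponents other than 1 are only meaningful when the structure
  factor is non-negative.
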