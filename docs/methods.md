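# Methods

## The segmentation problem

A maize kernel imaged by micro-CT is a stack of 8-bit grayscale axial
slices. Three tissue classes matter here: background (code 0, which for
segmentation purposes also covers the pericarp and germ), starchy
endosperm (code 1) and vitreous endosperm (code 2). The two endosperm
classes image at nearby gray values with a blurred interface, so the
pipeline treats this as per-slice 3-class semantic segmentation
followed by 3D measurement on the stacked masks.

## Preprocessing

Raw batch scans hold several kernels per field of view. Splitting runs
per slice: Canny edges (high threshold = the slice's Otsu threshold,
low = half of it — a parameter-free default on bright-object scans),
5×5 morphological closing, hole filling, then 26-connected 3D
labelling across slices. Components are ranked by voxel count, the
expected number of kernels is kept, and each is cropped with a tight
half-open bounding box padded by 5 % of its longer side. Equal-size
ties break toward the smaller centroid x and crops are ordered
left-to-right, making the output deterministic.

Intensity handling: `clamp_pixels` applies the [min, max] window
(default 0–255, the identity on 8-bit data — kept because scanner
exports occasionally carry out-of-range values after format
conversion); contrast enhancement defaults to a p1–p99 percentile
stretch onto 0–255, a monotone map that is testable in closed form,
with CLAHE as a named alternative. Crops are resized
aspect-preserving so the longer side hits the model size (256 for the
full network), zero-padded square, and rescaled to [0, 1].

Label images from annotation tools arrive with arbitrary gray values;
`remap_labels` requires an explicit and exhaustive value→code mapping
and refuses unmapped values rather than guessing.

## Network

CSFTU-Net is a U-Net with `levels` resolution levels (default 5, i.e.
four 2×2 max-poolings) and channel widths doubling from `base_filters`
(default 64 → 64, 128, 256, 512, 1024; an optional cap at 512 is
provided for memory-constrained runs). Each encoder level is
[conv3×3–BN–ReLU]×2 followed by a CBAM block immediately before the
pool; the bottleneck has no pool and, by default, no CBAM (a flag
enables one). Each decoder level upsamples 2× (learned transposed
convolution by default; nearest-neighbour + 1×1 projection by flag),
concatenates the matching encoder skip, applies [conv–BN–ReLU]×2 and an
SE block. A 1×1 convolution maps to the 3 class logits.

Attention parameters: both the CBAM channel MLP and the SE gating use
reduction ratio r = 16 (the conventional default in the attention
literature; the reduced test-scale networks use r = 4 so that r divides
the channel counts). The CBAM spatial convolution is 7×7. With both
attention families disabled the network is exactly the plain U-Net
baseline, which is how the ablation variants are built.

All convolutions are stride-1 'same'-padded, so the forward pass
preserves H×W for any input divisible by 2^(levels−1); other sizes
raise immediately with the required divisor in the message.

Implementation note: the network runs on `kernelct.nn`, a small
reverse-mode autodiff engine over NumPy written for this package
(float32 throughout; convolution via im2col; max-pool gradients split
evenly among ties; `sqrt` uses subgradient 0 at the origin so the
boundary loss stays finite on flat probability maps). Parameter
initialisation is He-normal driven by a seeded generator: two builds
from the same seed are bit-identical, verified by SHA-256 checksums
over the parameter bytes.

## Loss

The objective is `L = α·(1 − T)^γ + λ·Σ(|∇I_pred| − |∇I_true|)²` with
the Tversky index in its two-set form
`T = (|X∩Y| + ε)/(β|X| + (1−β)|Y| + ε)`. Defaults: β = 0.75, γ = 2.0,
α = 1 (α only rescales the focal term; it has no separate
positive/negative-sample role in this form), ε = 1e-6. Since
|X| = TP+FP and |Y| = TP+FN on hard masks, β > 0.5 penalises false
positives more; a `variant="standard"` switch exposes the equivalent
explicit TP/FP/FN form. For the 3-class task both losses reduce
one-vs-rest over the two foreground classes on softmax probabilities
and average with equal weight; background is excluded.

The boundary term uses forward differences with edge replication (the
difference past the last row/column is zero) and the per-pixel
Euclidean magnitude; Sobel was considered and rejected as adding a
smoothing radius the formula does not call for. Because the term is a
raw pixel sum, its scale grows with slice area while the focal term is
bounded by α; the default weight λ = 1e-4 balances the two at the
128–256 px slice sizes this pipeline uses (at λ ≈ 0.1 the boundary
term dominates by two orders of magnitude and the overlap objective
cannot train, while λ = 0 measurably loses Dice on phantoms —
0.81 vs 0.86 at the reference seed). λ = 0 recovers the pure focal
Tversky loss exactly. Dice and cross-entropy losses are provided for
ablation comparisons.

Metric conventions: Dice = 2|X∩Y|/(|X|+|Y|) and IoU = |X∩Y|/|X∪Y|,
with empty-vs-empty defined as 1 (two empty sets agree). Multi-class
reports give per-foreground-class values plus their mean.

## Training

RMSprop (smoothing 0.99, eps 1e-8, no momentum — framework-default
internals), batch size 1, 50 epochs by default, initial learning rate
1e-4 with a floor of 1e-5. The decay policy is reduce-on-plateau
(factor 0.5, patience 5, monitoring validation Dice; cosine decay by
flag) — the published recipe names only the two endpoint rates, and
plateau decay is the common reading of an "initial/minimum" pair.
Identifier splitting withholds the test set first, then splits the
remainder 8:1 train:validation with rounding toward train, under a
seeded shuffle; splitting is per-kernel by default so that slices of
one kernel never straddle the split. Optional augmentation
(horizontal/vertical flips, 90° rotations) is off by default. The
best-validation-Dice parameters are restored at the end and saved with
the architecture config embedded. Runs are bit-reproducible under a
fixed seed.

## Phenotypes

Volume is voxel counting: `count × voxel_edge³`. The voxel edge is a
user parameter everywhere, defaulting to 27 μm. Seed volume V is
measured on the whole-seed mask — pericarp and germ included — so
VV/V + SV/V < 1 in general. The seed mask comes from an Otsu
foreground split refined by a second threshold at the midpoint between
the background mean and the 95th-percentile rim intensity: the plain
Otsu cut is biased low by the dominant background class and accretes
the blur halo onto the seed (≈ +3–4 % volume on default phantoms),
whereas for a symmetric blur the half-rise contour sits on the true
surface (≤ 1 % error on phantoms). The threshold is followed by
largest-26-connected-component selection and per-slice hole filling.

Class masks from a label volume split by code equality; grayscale mask
renderings split at the Otsu threshold of the nonzero histogram
(exhaustive 256-level between-class-variance maximisation, ties toward
the lower level — on a clean bimodal rendering any gap threshold is
exact, and the tie rule makes the choice deterministic). Length, width
and thickness are the sorted edge lengths of the tight axis-aligned
bounding box; no PCA orientation is applied. Mesh-based volumetry was
deliberately bypassed: voxel counting is the definition used, and a
surface mesh would differ only by discretisation. Group aggregation
reports n, mean, median, sd (ddof = 0; 0 for n = 1), min, quartiles
and max per subgroup and variable — the statistics behind box plots of
endosperm distributions.

## Phantom generator

Phantoms are nested ellipsoids: normalized radius r < `core_fraction`
is starchy core, r < `shell_fraction` vitreous shell, r ≤ 1 pericarp
(seed but background-class). Labels are defined *pre-blur* so truth
stays crisp; the image gets per-region mean intensities (background
20, starchy 150, vitreous 180, pericarp 220 — a 30-gray-level
endosperm gap chosen to mimic the faint contrast of real kernel CT
while staying learnable at desk scale), Gaussian blur (σ = 1.2 voxels)
and additive Gaussian noise (σ = 8), clamped to [0, 255]. The truth
record carries exact per-class voxel counts, centroid and bounding
box; seed counts agree with the closed-form ellipsoid volume to < 2 %
for semi-axes ≥ 20 voxels. Training samples are central equatorial
slices of thin phantoms with geometry, contrast, blur, noise and
centre jitter drawn uniformly from documented ranges under a seed.

What the phantoms do *not* emulate: germ and cavity structures,
beam-hardening and ring artifacts, non-ellipsoidal kernel shape, and
intra-class texture. Passing phantom tests therefore demonstrates that
the machinery (splitting, training, measurement) is correct and that
the network can learn a low-contrast blurred-boundary task — not that
real-data accuracy figures transfer.

## Test-scale choices

The test suite and the acceptance script run on one CPU, so the
segmentation-recovery check uses a reduced network (3 levels, 16 base
filters, r = 4) on 128×128 slices — 64 for training (8:1 split
within), 16 held out — for 10 epochs, reaching mean foreground
Dice ≥ 0.80; the ablation comparison (plain U-Net / +CBAM / +SE /
both) runs at 64×64 for 4 epochs and is reported, not asserted, since
orderings at this scale are stochastic. The exhaustive loss-oracle
check covers every pair of 3×3 binary masks against literal
double-loop implementations.

## Known limitations

- Per-slice 2D segmentation: no 3D context across slices.
- NIfTI orientation codes are ignored (arrays in stored order,
  z slowest); label and image stacks must come from the same export
  path.
- The batch splitter assumes bright kernels on a darker background and
  non-touching kernels; touching kernels merge into one component.
- The published scan resolution is ambiguous between 13.55 μm and a
  27 μm voxel edge; all measurements take the voxel edge as an
  explicit parameter (default 27 μm) so either reading is available.
- Training at full scale (5 levels, 64 base filters, 256×256) is
  functional but slow on CPU; the NumPy engine is single-threaded
  apart from BLAS matmuls.
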