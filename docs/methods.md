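# Methods

This note documents the models, procedures and numerical choices behind
`fractalseg`: what each stage computes, which parameters matter, what the
synthetic data do and do not emulate, and where genuinely open design choices
were settled.

## Fractal generation

**Model.** A category is an iterated function system (IFS)
`{(θ_i, p_i)}_{i=1..N}` of planar affine maps
`w_i(x) = [[a_i, b_i], [c_i, d_i]] x + [e_i, f_i]`. The number of maps N is
uniform on [2, 8]; all six coefficients are uniform on [−1, 1]. The chaos game
starts at (0, 0), draws map i with probability p_i at each of `n_points`
steps, and records the visited points; the first `burn_in = 100` points are
transient (they depend on the arbitrary start) and are discarded. Points are
affinely mapped from their bounding box onto the raster and each stamps a
disc of `point_radius` pixels (default 1) with value 255.

**Selection probabilities.** Negative selection probabilities are
meaningless, so p_i is taken proportional to |det[[a_i,b_i],[c_i,d_i]]| —
the standard IFS practice of weighting maps by the area they cover — with a
uniform fallback when all determinants are ≈ 0, then normalized so the sum is
exactly 1 (verified to 1e-12). The determinant-weighting keeps rarely-selected
near-singular maps from starving the attractor.

**Degeneracy and divergence.** Random coefficient draws can be expansive; a
coordinate exceeding 1e6 aborts the render as degenerate. Surviving renders
are screened by lit-pixel fraction: outside [0.002, 0.95] on a 64 × 64 probe
render (3,000 points) the candidate is rejected and the seeded sampler draws
again, up to `max_rejects`. The probe is intentionally cheap; the full render
uses far more points, which only increases fill.

**Instances.** An instance multiplies all six coefficients of every map by one
scalar weight from {0.8, 0.9, 1.0, 1.1, 1.2} and re-renders with a fresh seed;
instance counts beyond five therefore vary the rendering seed at a cycled
weight. Up-weighting can make a contractive map expansive; the dataset builder
retries with alternate seeds and backs off toward weight 1.0 before giving up.
Instance seeds derive from `SeedSequence([db_seed, category, instance])`, so
any category can be rebuilt in isolation, and two builds of the same config
are byte-identical.

**Scale profiles.** The desk-scale default is 20 categories × 50 instances at
64 px and 20,000 points per image, sized so the whole pretext stage runs in
tens of seconds on one CPU. The full-scale profile (1,000 × 1,000 at 200,000
points, 224 px) is exposed as the named config `FRACTALDB_1K` and is a
cluster-scale job; nothing in the code assumes the small profile.

## Phantom cohort

Clinical GTV datasets are private, so the pipeline runs on a generated cohort.
Each case is a star-convex blob: a voxel lies inside iff its distance from the
volume center is at most `R0 · (1 + amp · F(direction))`, where F is a seeded
band-limited angular field — one real spherical harmonic per order 2–8 with
random order m, coefficient and phase — normalized to max |F| = 1 (zero mean
by construction, since all l ≥ 1 harmonics integrate to zero). `amp = 0`
yields a sphere; `amp = 0.6` yields an intricate boundary. Star-convexity
guarantees a single connected component. Base radii (default 7–20 mm) and
amplitudes (0–0.6) are stratified across the cohort so the surface-to-volume
ratio (SVR) spans at least a twofold range, which is what makes the
simple/complex median split meaningful.

CT rendering places two HU plateaus (lung −800, tumor +20 by default), blurs
the binary boundary with a 1-voxel Gaussian for partial-volume realism, and
adds Gaussian noise (default SD 40 HU). Voxel spacing defaults to
1.074 × 1.074 × 2.0 mm. Volumes are written as NIfTI pairs with the spacing in
the affine.

**What the phantom is not.** There are no vessels, airways, chest wall or
attachment effects, and no scanner-specific texture; tumor contrast is
unrealistically clean. Passing results on the phantom therefore demonstrate
that the pipeline's mechanics (cropping, training, metrics, statistics) are
correct and that pretraining effects are measurable under controlled
conditions — not that any accuracy level transfers to clinical CT. The
phantom's SVR distribution is likewise not calibrated to clinical anatomy;
only its spread matters.

## Preprocessing

All slices intersecting the GTV are used, each cropped to a 64 × 64 window
(68.736 mm at 1.074 mm pitch) centered on the **3D** voxel-count centroid of
the GTV — one window per case, shared by all its slices, so the crop does not
jitter slice to slice. The centroid is rounded half-up and the window is
half-open, giving an exact 64-pixel extent with the centroid at pixel
(32, 32); out-of-bounds regions are padded (image with the window floor, mask
with 0). Cohort geometry guarantees the whole GTV fits the window, and a test
asserts no mask voxel is ever lost. Intensities are clamped to a
(−1000, 200) HU window and min-max scaled. Nearest-neighbour resizing is
index-exact: binary masks stay binary and integer-factor up-then-down
round-trips are identities; a model declaring a 224-px input gets the ROI
upsampled on the way in and its mask downsampled on the way out.

## Models and training

**Network engine.** Training runs on a compact NumPy convolutional engine
written in-package: 3 × 3 same-padding convolutions via im2col, ReLU, 2 × 2
max-pooling, nearest-neighbour upsampling, Adam, softmax cross-entropy, and a
Dice + binary-cross-entropy segmentation loss. Everything is float32, seeded,
and deterministic on a fixed platform; gradients are verified against finite
differences in the test suite. The default encoder has four conv levels of
widths (4, 8, 16, 32) — deliberately small so that the full comparison
experiment runs on one CPU in minutes; larger or externally pretrained
encoders load through the same NPZ checkpoint interface.

**Pretext task.** The classifier predicts the category index of each fractal
image. Its head flattens the deepest feature map rather than average-pooling
it: fractal categories differ mainly in spatial layout, and pooling discards
exactly that (measured: flatten lifts held-out toy accuracy from ~0.7–0.8 to
≳0.94). The head is discarded on export; only encoder weights transfer.
Pretext optimization is Adam at a constant 3e-3 — the pretext schedule is a
package choice, since upstream work ships checkpoints rather than recipes.

**Segmentation.** The decoder mirrors the encoder with skip connections and a
1 × 1 output head producing one foreground logit per pixel; prediction
thresholds the sigmoid at 0.5. The loss is the equal-weight sum of soft Dice
(batch-aggregated, smoothing 1.0) and BCE — the standard pairing for the
severe foreground/background imbalance of tumor ROIs. Fine-tuning trains all
weights (no freezing), batch 8, Adam, with the warm-up schedule: 2e-5 at
epoch 1, linear per-epoch ramp to 1e-4 at epoch 5, constant thereafter.
"Linear per epoch" is the minimal reading of a gradual ramp; a per-step ramp
would differ only inside the first five epochs. The epoch with the lowest
validation loss is kept (ties → earliest); validation is used for nothing
else.

**Augmentation.** Applied in order, per sample: horizontal mirror (p = 0.5);
shift/scale (scale ±50%, shift ±10%, no rotation; p = 1.0); additive Gaussian
noise (p = 0.2); perspective warp (p = 0.5); one of CLAHE / brightness-
contrast / gamma (p = 0.9); one of sharpen / box blur ≤ 3 px / motion blur
(p = 0.9); one of brightness-contrast / hue-saturation-value (p = 0.9).
Geometric transforms hit image and mask identically (mask resampled at order
0, so it stays binary); photometric transforms touch the image only. The HSV
jitter operates on the grayscale image replicated to three channels and
collapses back by mean — replication first preserves the semantics of a
color-image policy applied to CT.

**Folds.** Patient-level k-fold: the cohort is shuffled once and cut into k
equal test blocks (disjoint, exhaustive); each fold's remainder is split into
train/validation at the configured sizes (63/15/26 for 104 cases). Slices
never straddle subsets because splitting happens at case level before slice
extraction.

## Evaluation

Predictions are made per slice but scored per case in 3D: predicted slices
are stacked into a volume at the cohort spacing, because sDSC's tolerance and
HD95 are physical (mm) quantities. Surfaces are represented as exposed
voxel-face centers — a face between a foreground voxel and a background or
out-of-bounds voxel contributes one point at its center and its area to the
total. This representation is deterministic and integer-exact, and makes
sDSC/HD95 exactly checkable against a brute-force all-pairs implementation
(the acceptance suite does so on 50 randomized pairs). Conventions for
degenerate cases: vDSC is 1.0 when both volumes are empty, 0.0 when exactly
one is; an empty prediction scores vDSC = sDSC = 0 and HD95 = ∞ (excluded
from means, counted in the tables); HD95 uses the nearest-rank percentile of
the pooled bidirectional nearest-neighbour distances, avoiding interpolation
ambiguity. Note that voxel-face surface area exceeds the smooth-surface area
(≈ 3/2 for spheres), uniformly across shapes; SVR is used only to *rank*
shapes, so the representation bias cancels.

**Statistics.** The Friedman test (within-case ranks, tie-corrected,
chi-square reference with k − 1 df; implemented directly so paired k = 2
designs are accepted, and verified against scipy for k ≥ 3) gates pairwise
two-sided Wilcoxon signed-rank tests; Holm's step-down correction is applied
across the strategy pairs of each metric, α = 0.05. All-zero difference
vectors yield p = 1. The subgroup analysis splits cases at the SVR median
(ties by case id; odd n puts the median case in the simple group) and reuses
the main cross-validation inference — no per-group retraining.

## The miniature transfer experiment

The directional claim under test is an ordering — fractal-pretrained
fine-tuning should match or beat training from scratch — not any clinical
magnitude. Conditions: the desk-scale fractal DB (20 × 50, 64 px, 20k points,
fixed seed: it plays the role of a fixed public pretraining set), a 40-case
phantom cohort per seed, 15 pretext epochs, 25 fine-tuning epochs under the
default warm-up schedule, one 25/5/10 train/val/test split per seed, three
seeds. The run passes when the fractal strategy's mean test vDSC is ≥
scratch's in at least two of three seeds. One split per seed (rather than
full fourfold CV per seed) keeps the three-seed experiment near ten CPU
minutes; seed-to-seed variation already resamples cohort, split and
initialization together.

## Orchestration

`run_experiment` executes the stages with content-addressed caching: each
stage directory is keyed by a hash of its config subtree plus upstream keys,
so repeated runs are byte-identical cache hits and a statistics-only change
never retrains. Every strategy is fine-tuned and evaluated on identical folds
and test slices (the paired design the statistics require). The default
experiment touches no network resource.

## Known limitations

- The phantom's clean two-plateau contrast makes segmentation easier than
  clinical CT; absolute metric levels are not transportable.
- The desk-scale encoder (~15k parameters) is far below clinical-model
  capacity; it is sized for CPU reproducibility, and conclusions are
  restricted to orderings under matched conditions.
- Surface representation differs from mesh-based implementations by the
  voxel-face area factor; comparisons across packages should use the same
  representation.
- 3D fractal generation and 3D segmentation are out of scope; the pipeline is
  2D-slice-based with 3D evaluation.
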