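# fractalseg

Transfer learning for gross-tumor-volume (GTV) segmentation on CT, pretrained
not on natural photographs but on **mathematically generated fractal images**.
The package is for researchers who want to study formula-driven pretraining
for medical segmentation without access to clinical data: every input it needs
— the pretraining set and the tumor cohort — is generated by code.

## What it does

1. **Fractal image generation.** An iterated function system (IFS) is a family
   of planar affine maps `w_i(x) = [[a_i, b_i], [c_i, d_i]] x + [e_i, f_i]`
   with selection probabilities `p_i` (Σp_i = 1). The *chaos game* — start at
   (x₀, y₀), repeatedly apply a randomly selected map — traces the attractor;
   rasterizing the visited points yields a fractal image. A sampled parameter
   set Θ = {(θ_i, p_i)} is a *category*; scaling its parameters by a weight in
   {0.8, …, 1.2} and re-rendering gives *instances*. Parameters are drawn
   uniformly from [−1, 1]; selection probabilities are proportional to the
   |determinant| of each map's linear part.
2. **Self-supervised pretext pretraining.** A FractalDB-style dataset
   (C categories × I instances) is labelled by category index — labels come
   from the generative process, not annotation. An encoder is trained to
   classify categories; its classification head is then discarded.
3. **Phantom cohort.** A synthetic stand-in for a clinical cohort: 3D CT-like
   volumes (two HU plateaus, partial-volume blur, Gaussian noise) with binary
   tumor masks whose boundary intricacy — hence surface-to-volume ratio
   (SVR) — is controllable. Default geometry matches planning CT:
   1.074 × 1.074 mm pixels, 2.0 mm slices.
4. **Fine-tuning.** 64 × 64 ROIs centered on the 3D GTV centroid
   (68.736 × 68.736 mm), on-the-fly augmentation (mirror, shift/scale,
   noise, perspective, contrast/sharpness/color groups), Adam with batch 8,
   learning-rate warm-up 2e-5 → 1e-4 by epoch 5, lowest-validation-loss epoch
   selection, patient-level fourfold cross-validation (63/15/26 per fold for a
   104-case cohort).
5. **Evaluation.** Per-case volumetric Dice `vDSC = 2|A∩B|/(|A|+|B|)`, surface
   Dice `sDSC(τ) = (|S_A^τ|+|S_B^τ|)/(|S_A|+|S_B|)` at τ = 1 mm, 95th-percentile
   Hausdorff distance (HD95, mm), SVR; strategies are compared with a Friedman
   test gating pairwise Wilcoxon signed-rank tests under Holm correction
   (α = 0.05), plus a simple/complex subgroup analysis by SVR median split.

Training runs on a compact, fully deterministic NumPy convolutional
encoder–decoder (~15k parameters) sized for CPU desk-scale experiments;
encoders pretrained elsewhere can be plugged in as NPZ weight archives.

## Worked example

```bash
python examples/03_contour_metrics.py
```

prints, for a 10 mm-radius sphere versus the same sphere shifted 2 mm:

```
vDSC = 0.850   (1 = perfect overlap)
sDSC(1mm) = 0.492   (surface agreement within 1 mm)
HD95 = 2.00 mm  (consistent with the 2 mm shift)
SVR(truth) = 0.449 /mm
```

A 2 mm systematic shift leaves substantial volumetric overlap (0.85) but only
half the surface within the 1 mm tolerance, and HD95 recovers the shift
magnitude exactly — the three metrics are deliberately complementary.

The other examples cover fractal rendering (`01`), phantom cohorts (`02`),
pretraining + fine-tuning (`04`), and the reduced end-to-end comparison
(`05`). The full desk-scale comparison is also available from the shell:

```bash
fractalseg run --out results/experiment --seed 1
```

## Layout

- `src/fractalseg/ifs.py` — IFS sampling, chaos game, rasterization
- `src/fractalseg/fractaldb.py` — dataset assembly, manifest, batch loading
- `src/fractalseg/phantom.py` — synthetic CT cohort generator (NIfTI)
- `src/fractalseg/roi.py` — centroid cropping, resizing, HU windowing
- `src/fractalseg/nn.py` — NumPy conv-net engine (encoder, decoder, Adam)
- `src/fractalseg/training.py` — folds, schedule, augmentation, training loops
- `src/fractalseg/metrics.py` — vDSC, sDSC, HD95, SVR, Friedman/Wilcoxon-Holm
- `src/fractalseg/pipeline.py` — cached end-to-end experiment orchestration
- `docs/methods.md` — models, assumptions, parameter choices, limitations
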