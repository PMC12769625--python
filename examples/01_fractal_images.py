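"""Sample an IFS category, render instances at the five weights, save PNGs.

Each category is a random set of planar affine maps; the chaos game traces its
attractor and the raster is the pretraining image.  The printed fill fraction
is the share of lit pixels — the degeneracy filter rejects near-empty or
saturated renders.
"""

from pathlib import Path

from PIL import Image

from fractalseg import (DegenerateCategoryError, RenderConfig, WEIGHT_GRID,
                        render_category, sample_category)

out = Path("example_output/fractals")
out.mkdir(parents=True, exist_ok=True)

category = sample_category(seed=3)
print(f"category with N={category.n_transforms} maps, "
      f"probabilities={[round(p, 3) for p in category.probabilities]}")

config = RenderConfig(n_points=20_000, image_side=64)
written = 0
for weight in WEIGHT_GRID:
    try:
        img = render_category(category, config, seed=1, weight=weight)
    except DegenerateCategoryError:
        # up-weighting can make a map expansive; the dataset builder backs off
        # toward weight 1.0 when this happens
        print(f"  weight {weight:.1f}: diverged (rejected)")
        continue
    fill = (img.pixels > 0).mean()
    Image.fromarray(img.pixels).save(out / f"w{weight:.1f}.png")
    print(f"  weight {weight:.1f}: fill fraction {fill:.3f}")
    written += 1
print(f"wrote {written} instance renders to {out}")
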