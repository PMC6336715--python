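# pydefine

Artifact removal and semi-automated quantification for fluorescence
microscopy images of labeled axons — a headless, batch-capable
reimplementation of the DEFiNE method (Digital Enhancement of Fibers with
Noise Elimination).

## The problem

Quantifying sparse, thin, fluorescently labeled axonal fibers in tissue
sections is routinely defeated by fluorescent artifacts: autofluorescent
lipofuscin granules, hemosiderin, blood vessels, and miscellaneous debris
that can be as bright as — or brighter than — the axons themselves. DEFiNE
attacks this with three complementary, fully automated cleaning steps
applied to multi-channel z-stacks, followed by a background-calibrated
quantification of the cleaned images:

1. **Large particle removal** — each z-slice is thresholded at
   `mean + k·SD` for k = 1.5, 2, 2.5, 3 (four sequential passes);
   connected particles are measured for area *A* (µm²) and circularity
   `C = 4πA/P²` (P = perimeter), and any particle matching one of up to five
   (minimum-area, minimum-circularity) gates is zeroed. The default ladder —
   40/0.17, 25/0.32, 15/0.40, 10/0.70, 5/0.80 — removes compact blobs at any
   size and elongated structures only when they are much larger than axons.
2. **Autofluorescence subtraction** — an *autofluorescence channel*,
   excited at a label's wavelength but collected in an emission band where
   the label does not emit (so it captures artifacts only), is binarized per
   z-slice at `mean + 1·SD`, and the resulting mask is subtracted from every
   signal channel.
3. **Small particle removal** — after maximum intensity projection (MIP),
   particles with area ≤ 1 µm² and circularity in [0.99, 1] at a
   `mean + 1·SD` threshold are zeroed (residual speckle).

Crucially, steps 1–2 run on the z-stack, not on a projection: a fiber
passing *above or below* an artifact survives, because the artifact is
removed only from its own slices.

**Quantify Fibers** then takes ten user-chosen (or automatically proposed)
12 × 12 µm axon-free background regions, pools their pixels, sets an
image-specific threshold at `mean + 4·SD`, and reports the image area (µm²)
above it.

## Worked example

The canonical depth-occlusion scenario: a bright autofluorescent granule in
z-slices 0–2 and a labeled fiber crossing the same (y, x) location in slices
3–5.

```python
from pydefine import (CleanSettings, clean_images, figure4_scenario,
                      quantify_fibers, propose_regions)

stack, truth = figure4_scenario()
(cleaned,) = clean_images(stack, CleanSettings())

fiber = next(o for o in truth.objects if o.kind == "fiber")
granule = next(o for o in truth.objects if o.kind == "granule")
retained = (cleaned.pixels[fiber.footprint] >= fiber.intensity).mean()
residual = (cleaned.pixels[granule.footprint & ~fiber.footprint]
            >= granule.intensity).mean()
print(f"fiber pixels retained:   {100 * retained:.1f}%")
print(f"granule pixels residual: {100 * residual:.1f}%")

regions = propose_regions(cleaned, n=10)
result = quantify_fibers(cleaned, regions, k=4)
print(f"threshold:  {result.threshold:.2f}")
print(f"fiber area: {result.fiber_area_um2:.1f} um^2 "
      f"(planted fiber: {fiber.area_um2:.1f} um^2)")
```

prints

```
fiber pixels retained:   100.0%
granule pixels residual: 0.0%
threshold:  15.88
fiber area: 60.6 um^2 (planted fiber: 55.1 um^2)
```

Every fiber pixel survives cleaning and no granule signal remains; the
quantifier recovers the planted fiber area plus a small margin of
noise-brightened pixels at the 4-SD cutoff. Processing the *pre-projected*
MIP of the same scene instead loses every fiber pixel under the artifact
footprint — the reason the pipeline operates on stacks.

## Command line

```bash
define phantom  --out fixtures --seed 1            # synthetic test stack + ground truth
define clean    fixtures --out results --af-channel 1
define quantify results/DEFiNE_Processed_Images_*  --auto-regions
define optimize stack.ome.tif markings.csv         # settings recommendation
```

`clean` writes one cleaned MIP per signal channel into a dated
`DEFiNE_Processed_Images_MM-DD-YYYY` folder; `quantify` writes binary fiber
masks and a tab-delimited report into
`DEFiNE_Quantified_Fibers_MM-DD-YYYY`. Settings are YAML
(see `CleanSettings`); all defaults can be overridden.

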