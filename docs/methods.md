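# Methods

This note documents the processing model, the measurement conventions, the
synthetic-data model used for testing, and the design decisions taken where
the original method description leaves the details open.

## Processing model

The cleaning pipeline operates on an integer-valued multi-channel z-stack
`(channel, z, y, x)` with known pixel size (µm/px per axis). Three stages
run in order; each stage can only set pixels to zero, never raise them, so
the cleaned image is a pixelwise lower bound of the input and quantification
downstream is conservative.

**Thresholding convention.** Every threshold in the package is
`mean + k · SD` of the pixels being thresholded, using the *population*
standard deviation (the statistic of the whole image, not a sample
estimate; the distinction is negligible at image scale but is pinned so
tests are exact). Binarization is strictly greater-than. Together these
make a constant (e.g. blank) plane produce an empty mask, so empty z-slices
degrade nothing — though cropping them first (`crop_z`) remains the
recommended practice, and near-blank slices are logged as warnings.

**Large-particle removal** runs per (channel, z) plane, excluding the
autofluorescence channel. For each multiplier k in (1.5, 2, 2.5, 3), the
*current* plane is re-thresholded, its particles measured, and every
particle matching any (min-area, min-circularity) gate is zeroed. Statistics
are recomputed each pass because the earlier subtractions lower the mean and
SD — removing the brightest artifacts lets later passes reach structure that
was initially below threshold relative to them. Gates are OR-combined: the
default ladder (40/0.17, 25/0.32, 15/0.40, 10/0.70, 5/0.80 in µm²/unitless)
describes alternative ways of being artifact-like, trading minimum size
against compactness.

**Autofluorescence subtraction** binarizes each z-slice of the
autofluorescence (AF) channel at `mean + af_k·SD` (default af_k = 1,
per-slice statistics — depth-dependent brightness falloff makes whole-stack
statistics inappropriate) and zeroes the masked pixels in every signal
channel's same slice. The AF channel itself is never modified and is never
an output: it is a noise reference. It is likewise exempt from
large-particle removal — removing its artifacts before subtraction would
defeat its purpose. Whether the original implementation also exempts it is
unknown; this is a declared choice.

**Small-particle removal** runs once on each signal channel's maximum
intensity projection: particles with area ≤ 1 µm² and circularity in the
*closed* interval [0.99, 1] at a `mean + 1·SD` threshold are zeroed. The
interval must be closed above because single-pixel and near-square specks
clip to circularity exactly 1.

Removed pixels are set to 0 rather than to a local background estimate:
this mirrors binary AND-mask subtraction and never inflates the fiber area
measured later.

## Particle measurement

Particles are 8-connected components (the convention the surrounding
ecosystem defaults to; configurable at the labeling call). Per particle:

* **area** = pixel count × pixel area (x·y µm²). Interior holes are
  off-pixels and therefore excluded; a hole-filling variant could differ by
  sub-percent areas on rare ring-shaped artifacts.
* **perimeter** = weighted boundary-chain length: the outer boundary is
  traced pixel-centre to pixel-centre over the Moore neighbourhood; axis
  steps contribute one pixel pitch (per axis under anisotropic sampling,
  e.g. the 0.830 vs 0.208 µm/px of 20× vs 40× objectives), diagonal steps
  the diagonal pitch √(sx²+sy²). This is the standard low-bias digital
  perimeter; a rasterized disk of radius 20 px measures circularity ≈ 0.95.
* **circularity** = min(1, 4π·area/perimeter²), clipped to 1 as is
  conventional. A single-pixel particle is assigned circularity 1.0 by
  convention (it is maximally compact and must remain removable by
  high-circularity gates); its perimeter is that of its bounding rectangle.

The boundary trace terminates by revisiting a (pixel, backtrack) state; the
cycle length between the two visits is the perimeter. This is exact for any
single 8-connected component, including width-1 filaments (both sides of the
filament are walked, giving the expected ≈2L perimeter).

## Quantification

Ten 12 × 12 µm background regions (count and side configurable) are pooled
into one pixel multiset; overlapping regions are counted once with a
warning. The threshold is `pooled mean + 4·pooled SD`; the result is the
area above threshold in µm² plus the binary mask. Pooling rather than
averaging per-region statistics is the better-conditioned estimator when
individual regions are small, and matches treating the ten patches as one
background sample. Region sides convert to pixels by rounding per axis
(minimum 1 px). The region set comes from a CSV sidecar (headless batch
operation) or from the automatic proposer — the n lowest-mean disjoint
tiles — which is an extension for unattended runs and should be inspected
on real data: a dim tile is not guaranteed to be axon-free.

With roughly Gaussian background, the 4-SD cutoff admits ≈ 0.003 % of true
background pixels, so the measurement tracks planted structure to within a
few pixels on the synthetic fixtures.

## Settings recommendation

The preview/recommendation flow is deliberately isolated: the original
method promises recommendations but does not publish its heuristic, so the
rule here is this package's own design and makes no claim of equivalence.
Each marked mistake is repaired by the smallest relative change to a single
gate, with a 1 % margin past the offending particle's measurements:

* a wrongly removed fiber tightens every gate it matched — min-area to
  1.01 × its area or min-circularity to 1.01 × its circularity, whichever is
  the smaller relative change (the area route is forced when the circularity
  route would exceed 1);
* a wrongly kept artifact that matches no gate loosens the single gate
  needing the smallest relative change to capture it; one that already
  matches a gate evaded morphology (it was sub-threshold or merged), so the
  fallback is a lower AF threshold multiplier when the artifact is visible
  in the AF channel above a 0.5-SD floor — af_k is never driven below 0.5 —
  and otherwise an explicit "not separable by current features" warning.

Tightenings only ever raise bounds, so protections established by earlier
markings persist; recommendations never add gates and always satisfy the
settings invariants.

## Synthetic phantoms

The generator emulates the scene classes the pipeline is designed around,
with defaults chosen to model a 20×-objective field (0.830 µm/px, 8-bit,
2 channels × 6 slices × 192 × 192 px):

* **fibers** (6): damped-random-walk curves, width 1 px (≲1 µm — axon
  scale), length 40–65 px, intensity 140–210, spanning 1–3 adjacent
  z-slices, rendered in one signal channel. Measured circularities land
  ≤ 0.1, far below every default gate.
* **granules** (8): lipofuscin-like ellipses, 6–45 µm², aspect ≤ 1.3,
  intensity 170–235, ≤ 3 adjacent slices, rendered in *all* signal channels
  and, scaled by a bleed-through fraction (0.8), in the AF channel — broad
  emission is what defines them. Measured circularities are ≥ 0.8 in
  practice (the generator's contract is ≥ 0.7).
* **vessels** (1): wide (5–8 px), long (50–90 px), nearly straight ribbons
  with the same AF bleed-through; circularity ≈ 0.2–0.4, so they are caught
  by the large-area/low-circularity gates.
* **background**: integer-rounded Gaussian noise (mean 10, SD 3) in signal
  channels, composited under the objects by maximum. The AF channel's
  background is a flat offset (mean 2, no noise) by default: an AF channel
  with free Gaussian noise would have ~16 % of pixels above any
  `mean + 1·SD` cutoff in every artifact-free slice, which models an
  empty detector rather than the structured-artifact regime the 1-SD
  default addresses. Slices whose AF content is constant produce empty
  masks by the strict-> convention.

Objects of the same class are placed with a one-pixel exclusion margin
(full 3×3 dilation) so they never touch even diagonally, keeping
ground-truth object counts exact under 8-connected labeling. Different
classes may overlap by default — a fiber running under a granule is
precisely the hard case — and scenes that require cleanly separated classes
(e.g. measuring pure morphological discrimination) disable cross-class
overlap. Every object's footprint is measured with the package's own
particle engine at generation time and recorded in the ground truth.

What the phantoms do **not** model: PSF blur, Poisson photon statistics,
depth attenuation, spectral unmixing physics, uneven illumination, and
tissue texture. Passing tests therefore demonstrate algorithmic
correctness — thresholds, measurements, masks, bookkeeping — not robustness
to optical effects; thresholds on real data may need the settings
optimization flow.

The canonical depth-occlusion fixture (`figure4_scenario`) is a 6-slice,
2-channel, 96 × 96 px scene: a radius-6 px granule at the centre in slices
0–2 (both channels, 0.9 bleed-through), a fiber crossing the granule centre
in slices 3–5 (signal only; the path is anchored through the centre so the
occlusion overlap is structural, not seed-dependent), faint Gaussian noise
in the signal channel, and a clean AF background.

## Problem sizes and tolerances

The test suite and the acceptance script run entirely on generated data:
default phantoms (2 × 6 × 192 × 192), a single-plane 256 × 256
discrimination scene with 20 granules and 20 fibers, ten random phantom
seeds for subtraction exactness, and 1000 random ≤ 32 × 32 instances per
brute-force oracle comparison (flood-fill labeling, loop-computed
projections, pixel-enumerated background statistics). These sizes keep the
full suite in the seconds-to-a-minute range while leaving every code path
exercised at realistic object densities. Integer image math makes most
assertions exact (bit-identical reruns, zero-violation subtraction); the
quantifier calibration is asserted to 3 % against planted areas, and the
rasterized-disk circularity to the [0.9, 1.0] band appropriate for the
chosen perimeter estimator.

## Known limitations

* TIFF/OME-TIFF only (plus anything sharing those containers); no
  proprietary vendor formats, no tile stitching.
* Acquisition metadata other than pixel size is not propagated to outputs.
* The perimeter estimator matches the documented algorithm, not any
  particular legacy implementation's lookup tables bit-for-bit; circularity
  values near gate boundaries can therefore differ at the third decimal
  from other software.
* The settings-recommendation heuristic is a first-order repair rule; it
  fixes the marked mistakes minimally but does not optimize globally.
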