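# Methods

## Scope and model

`histotile` prepares whole-slide histology images for machine learning
by separating tissue from background and cutting the tissue into
fixed-size tiles. The pipeline treats a slide as a multi-resolution
pyramid: level 0 is the native raster, level *i* a pre-stored copy at
downsample factor *d<sub>i</sub>* (one stored pixel spans
*d<sub>i</sub>* × *d<sub>i</sub>* native pixels). Three downsample
factors are independent user choices — mask computation
(*d<sub>m</sub>*), tile output (*d<sub>o</sub>*), and the overview
rendering — and all geometry is kept consistent between them by defining
the tile grid purely in native coordinates: tile (r, c) starts at
(c·s, r·s) with native span s = `tile_size`·*d<sub>o</sub>*. Changing
*d<sub>m</sub>* can change which tiles are selected (mask resolution)
but never where tiles are.

## Slide reading

Pyramidal TIFF/SVS files are read with `tifffile` (SubIFD pyramids);
plain PNG/TIFF images act as single-level pyramids, with alpha
composited over white. `read_region(handle, d, x, y, w, h)` serves a
native-anchored region at any factor d ≥ 1 by cropping the finest
stored level with downsample ≤ d and box (area-average) resampling the
residual. Box filtering was chosen over bilinear/Lanczos because it is
the exact block mean for integer residuals — directly checkable against
a reshape-and-mean oracle — and alias-resistant for the large factors
typical of mask computation. Levels are held in memory; at the slide
sizes this package targets in practice (tests run 4096² slides, tens of
MB) this is far below any relevant budget, and the per-region API would
be unchanged by a lazily tiled backend.

## Tissue masking

**Graph method (default).** The mask region is converted to grayscale
(BT.601 weights 0.299/0.587/0.114), edges are found with a from-scratch
Canny detector, and the binary edge image is segmented with the
efficient graph-based (Felzenszwalb–Huttenlocher) algorithm:

* Canny: separable Gaussian smoothing (σ = 1.4 at mask resolution,
  kernel truncated at 4σ, reflective borders), 3×3 Sobel gradients,
  non-maximum suppression quantized to four directions, hysteresis with
  thresholds low/high = 0.1/0.2 **of the per-image maximum gradient
  magnitude**. Relative thresholds make one default usable across
  slides of very different stain intensity; the cost is that a
  structure-free image normalizes its own noise, which the border
  classification and minimum component size absorb downstream.
  NMS breaks magnitude plateaus by requiring a strict maximum against
  only the second neighbor along the gradient, so an ideal step edge
  yields a one-pixel line. Magnitude maxima below 1e-6 are treated as
  flat (convolution round-off, not gradients).
* Segmentation: 8-connected grid graph, weight = |intensity
  difference|, edges processed in non-decreasing (weight, a, b) order;
  components merge iff w ≤ min(Int(C₁)+k/|C₁|, Int(C₂)+k/|C₂|) with
  Int(C) the largest weight that previously merged inside C; a second
  pass in the same order merges components below `min_size`; labels are
  compacted by first-pixel order. The explicit (weight, a, b) tie order
  makes the procedure fully deterministic, which is what allows an
  exact partition-level comparison against a literal set-based
  implementation of the same criterion (the suite and the acceptance
  script both run that comparison). The two merge passes are compiled
  with numba; the oracle is pure Python.
* Defaults k = 10000 and `min_size` = half a tile footprint at mask
  resolution: with weights in {0, 255} on the edge render, a uniform
  region must exceed k/255 ≈ 39 pixels before boundary edges stop
  merging into it, and the `min_size` choice removes speckle components
  that could never dominate a tile.
* The one-pixel NMS skeleton is dilated by one pixel (3×3) before
  segmentation. On an 8-connected grid a one-pixel *diagonal* curve can
  be hopped by a weight-0 diagonal edge between the two flanking
  pixels, flooding enclosed tissue with background; thickening the
  curve to ≥ 2 px closes that route for every orientation.
  `segment_image` itself takes the raw {0, 255} edge render.
* Background classification: every component with a pixel inside an
  active border strip or corner square (width/side = `margin`, default
  1 mask pixel, all four borders active by default) is background; the
  rest is tissue. With no active region the largest component is
  background. This is what makes the method robust on slides whose
  tissue is darker *or* lighter than its surround: polarity never
  enters.

**Otsu.** Global threshold t maximizing the between-class variance
ω₀ω₁(μ₀−μ₁)² of the 256-bin histogram, smallest maximizer on ties,
tissue = values < t (dark-on-light polarity, as for H&E on glass). A
guard rejects the split when the class means are closer than 10 gray
levels: below stain-scale contrast the optimum is splitting sensor
noise or quantization, and the slide is reported as tissue-free. (An
alternative guard on Otsu's separability measure η = σ²_b/σ²_T was
tried and discarded: block-averaging to mask resolution quantizes noise
to a couple of gray bins, which drives η above 0.8 with no tissue
present.) The threshold function itself stays the pure argmax; the
guard lives only in `make_mask`.

**Adaptive.** Foreground where value < (local mean over an odd
`block_size` window, reflective borders) − `offset`; defaults 51 px and
8 gray levels at mask resolution. Robust to uneven illumination, but
large homogeneous tissue regions hollow out (their local mean equals
their own intensity) — the known trade-off of local thresholding, left
as-is.

## Tiling and extraction

Each tile's mask-level footprint side is s/*d<sub>m</sub>*; footprints
are rounded per boundary (⌊c·side+0.5⌋), counted over an integral
image, and divided by the **full** footprint area, so partial edge
tiles score low rather than being silently dropped — the manifest's
`fg_fraction` column lets users apply their own edge policy. Selection
is `fg_fraction ≥ content_threshold` (boundary inclusive), with
`keep_all` overriding. Extraction reads at *d<sub>o</sub>* and pads
beyond the slide with white; files are named by grid position so
coordinates are recoverable from names. Random mode draws tile origins
uniformly from the valid native rectangle with a seeded generator and
records the seed in its manifest.

## Synthetic slides and what they show

The fixture generator emulates the salient structure of a stained
section scan: `n_blobs` tissue pieces, each a union of
`lobes_per_blob` randomly perturbed ellipses around a center, filled
with an eosin-like pink (mean (200, 120, 160), per-blob shade sd 12) on
a near-white background (242), i.i.d. Gaussian pixel noise (sd 6)
everywhere, written as a tiled pyramidal TIFF (levels 1/4/16 by box
downsampling, matching the reader's resampler) with a pixel-exact
ground-truth mask. Defaults are 4096² native with five blobs of radius
250–500 px, i.e. pieces spanning 1/8–1/4 of the slide so a 256-px grid
sees interior, boundary, and empty tiles. Blob placement keeps the
worst-case lobe extent off the slide border (offsets clamped at 2 sd),
because tissue reaching the border is — correctly — classified as
background by the exclusion rule, which is a property of real
edge-touching artifacts the fixtures deliberately do not model. Setting
`perturbation = 0` collapses every lobe to an exact circle, giving the
analytic-area oracle used in tests.

What the fixtures do *not* model: scanner blur bands, pen marks,
coverslip edges, stain gradients within a piece, and texture inside
tissue. Passing tests therefore demonstrate the pipeline's geometric
and algorithmic correctness (mask recovery under noise, grid
consistency, determinism), not robustness to every scanner artifact;
the tunables exist precisely for such slides (k, Canny thresholds,
content threshold, exclusion regions).

## Numerical and design notes

* Grayscale rounds half-up; smoothing is done in float and quantized
  once at the end of each public operation.
* Otsu's degenerate case (zero variance everywhere) returns the
  constant itself, under which everything is background. For a
  two-delta histogram every interior threshold induces the same
  partition; the smallest maximizer is returned.
* `best_level_for_downsample` picks the largest stored level with
  downsample ≤ requested, never upsampling.
* Exit codes: 0 success, 1 usage/configuration error, 2 runtime error;
  a failed run removes the files it had written.
* Problem sizes in the verification suite — 50 random 8×8 images for
  the segmentation oracle, 200 random images for Otsu, ten 4096²
  slides at three mask factors for tile recovery, 10,000 draws for the
  uniformity check — are chosen so the whole suite and the acceptance
  script each complete in about a minute on one CPU while keeping
  every check at full strength (the oracle comparisons are exact, not
  sampled approximations of a larger condition).

## Known limitations

* Vendor formats beyond SVS-style pyramidal TIFF (MRXS, NDPI,
  JPEG2000) are out of scope, as are ICC color management, overlapping
  or strided tiles, and stain normalization.
* Border-exclusion background classification applies to the graph
  method only; the thresholding methods return their raw masks.
* The Canny and segmentation defaults are calibrated at mask
  resolution; running the graph method at native resolution on a large
  slide is memory- and time-intensive and rarely useful.
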