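# histotile

Whole-slide histology images (WSIs) are multi-gigapixel pyramidal scans in
which most of the area is empty glass. Machine-learning pipelines consume
them as fixed-size square tiles, and preparing those tiles — separating
tissue from background, laying a grid, keeping only cells with enough
tissue, extracting them at a chosen resolution — is a preprocessing chore
that otherwise gets re-scripted per project. `histotile` is a library and
command-line tool that does exactly this step.

## Method

Given a slide, the pipeline:

1. **Masks the tissue** at a mask downsample factor *d<sub>m</sub>*.
   The default *graph* method converts the region to grayscale, runs a
   Canny edge detector (Gaussian smoothing, Sobel gradients, non-maximum
   suppression, two-threshold hysteresis), and segments the binary edge
   image with efficient graph-based segmentation: edges of an
   8-connected grid graph are processed in non-decreasing weight order
   and components *C₁, C₂* merge iff

   *w ≤ min( Int(C₁) + k/|C₁|, Int(C₂) + k/|C₂| )*

   where *Int(C)* is the largest weight that previously merged pixels of
   *C* and τ(C) = *k*/|C| is the scale-dependent tolerance. Components
   reaching the slide border (or user-chosen border/corner exclusion
   regions) are classified as background; everything else is tissue.
   Global Otsu thresholding and local adaptive (mean − offset)
   thresholding are available as alternatives, and a *random* mode skips
   masking entirely.
2. **Grids and scores.** A grid of `tile_size` tiles (defined at the
   output downsample *d<sub>o</sub>*) covers the slide; each tile's
   foreground fraction is the share of mask-foreground pixels in its
   footprint, with off-slide padding counted as background. Grid
   geometry depends only on `tile_size`·*d<sub>o</sub>*, so mask and
   overview factors can be chosen independently without changing tile
   coordinates.
3. **Selects and extracts.** Tiles with fraction ≥ `content_threshold`
   (default 0.05) are written as PNGs named `<slide>_<row>_<col>.png`,
   white-padded at slide edges, together with a TSV manifest of every
   grid tile and a JSON run log. An overview image (red grid lines, blue
   crosses on selected tiles) shows the segmentation at a glance; test
   mode produces mask, overview, and manifest without writing tiles.

Everything is deterministic: identical configuration and seed reproduce
the output tree byte for byte.

## Worked example

```sh
python -c "
from histotile import SyntheticSlideSpec, generate_synthetic_slide
spec = SyntheticSlideSpec(width=2048, height=2048, n_blobs=3,
                          blob_radius_range=(150, 300), levels=(1, 4, 16), seed=1)
generate_synthetic_slide(spec, '.', stem='demo')"
histotile --input demo.tiff --output tiles --mask-downsample 8 --overview-downsample 8
```

prints

```
... INFO histotile.pipeline: opened demo.tiff: 2048 x 2048 px, 3 levels
... INFO histotile.pipeline: mask foreground fraction: 0.1903
... INFO histotile.pipeline: grid 8 x 8: 19 / 64 tiles selected
19/64 tiles selected, 19 written
```

i.e. 19 % of the mask is tissue, and 19 of the 64 grid tiles meet the 5 %
content threshold. `tiles/` then holds the 19 tile PNGs,
`demo_overview.png`, `demo_log.json`, and `demo_manifest.tsv`, whose rows
give each tile's grid position, native coordinates, foreground fraction
and selection flag:

```
slide	row	col	x	y	width	height	fg_fraction	selected
demo	0	0	0	0	256	256	0.000000	0
...
```

The library surface mirrors the CLI: `open_slide`, `make_mask`,
`compute_tile_grid` / `score_tiles` / `select_tiles`, `extract_tiles`,
`sample_random_tiles`, `render_overview`, or `run_pipeline` for the whole
thing. See `docs/methods.md` for the model, parameters, and limitations.

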