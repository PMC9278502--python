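# Methods

`mplexview` renders a cohort of multiplexed tissue images — Vectra, CyCIF,
t-CyCIF, or CODEX multichannel TIFF-family files — as an "image t-SNE":
a static canvas on which each image appears as a cleaned thumbnail placed
at its 2D embedding position, paired with an interactive scatterplot in
which each image is a dot carrying its metadata. This note records the
models, parameter choices, and numerical decisions behind each stage, and
what the synthetic test data do and do not establish.

## Image ingestion

Three container dialects are normalized to one in-memory type (a
channel × row × col stack with ordered marker names): plain multi-page
TIFF, OME-TIFF, and QPTIFF-style pyramidal TIFF. Channel names follow a
fixed precedence — embedded OME-XML channel metadata, then a user-supplied
list, then autogenerated `ch00..chNN` — because embedded names, when
present, are authoritative. For pyramidal files the default policy loads
the highest-resolution level whose longer edge is at most 4,096 px; real
whole-slide multiplexed files reach tens of gigabytes at full resolution
and the gallery use case never needs more than thumbnail-scale detail. A
`None` policy loads full resolution. Pixel dtype is preserved on read;
conversion to unsigned byte is a cleaning-stage concern.

Image identifiers are file basenames without extension (``a.ome.tif`` →
``a``); they key every downstream table, and the hover tool reports them
verbatim. Metadata arrives as one delimited table per annotation category
(comma or tab, sniffed, header row), plus an optional ``colors`` table
mapping annotation values to display colors. Duplicate rows keep the last
value with a warning; rows naming unknown images are skipped with a
warning rather than failing a whole run.

## Channel cleaning

Each selected marker channel is cleaned independently in five steps:

1. **Median filter** (window 3 px by default) — edge-preserving denoising.
2. **Otsu threshold** — the 256-bin histogram threshold minimizing total
   within-class intensity variance. The implementation is a vectorized
   exhaustive search over all candidate thresholds with ties broken
   toward the smaller threshold, so it agrees exactly with a brute-force
   minimizer; a constant channel is flagged degenerate and treated as all
   background.
3. **Morphological closing** of the foreground mask with a disk of radius
   1 px, filling small gaps in stained regions.
4. **Border clearing** — connected foreground components touching the
   raster border are removed; partial cells at the field-of-view edge
   otherwise smear the thumbnail boundary.
5. **Upweighting** — surviving foreground keeps its median-filtered
   intensities multiplied by 1.5, clipped to 255, preserving morphology
   rather than binarizing.

The mask produced by steps 2–4 is applied multiplicatively to the
median-filtered image, so foreground texture survives; background pixels
are exactly 0. Channels stored in wider dtypes are min–max scaled per
channel to [0, 255] first; all cleaned output is unsigned byte. Cleaned
channels blend additively into RGB: each contributes
``intensity/255 × color``, clipped at 255, with a fixed 10-color
categorical palette assigned in marker order when the user supplies none.
Optional per-marker weights scale each cleaned channel before blending
(weight 0 removes a marker, weights must be nonnegative).

Chosen where the procedure leaves room: the median window (3), closing
radius (1), multiplicative upweighting with factor 1.5, and mask-based
(rather than binarized) cleaning are package defaults; each is exposed in
`CleanParams`.

## Thumbnails and borders

Thumbnails downscale the cleaned composite with an area-averaging (box)
resampler so the longer edge equals `max_edge` (default 222 px; at that
size a cleaned Vectra-scale field of view compresses to well under 100 kB
of PNG). Aspect ratio is preserved with half-up rounding on the shorter
edge; images already smaller are left untouched. A metadata border pastes
the tile onto a rectangle larger by `border_px` (default 4 px) per side,
filled with the color assigned to that image's annotation value; interior
pixels are never modified.

## Layout

Positions are top-left tile corners; the canvas origin is top-left with y
downward, and embedding y is flipped so canvas and scatterplot agree
visually. Default canvas 4,000 × 3,000 px with a 50 px margin.

* **Coordinate mode** affinely maps each embedding axis onto the drawable
  span (canvas − margins − tile). The map is monotone per axis; a
  degenerate axis (all images equal) centers the tiles. Overlap is
  allowed by design — the shuffle option re-randomizes the front-to-back
  render order (seeded uniform permutation) as the only mitigation.
* **Grid mode** places tiles row-major with a fixed gap
  (``per_row = floor((width − gap)/(tile + gap))``), growing the canvas
  vertically; tiles never overlap.
* **Random mode** uses Bridson's grid-accelerated Poisson-disc sampler:
  a background grid of cell size r/√2 holds at most one point per cell,
  each active point spawns up to k = 30 candidates in the annulus
  [r, 2r], and candidates within r of an existing point are rejected.
  The sampler is modified to stop at exactly the requested point count
  and to tolerate an under-filled domain (returning fewer points with a
  warning) instead of failing; the layout driver then halves r once and,
  as a last resort, tops up with uniform points so every image is placed.
  Minimum separation defaults to half the tile edge. Deterministic for a
  given seed.

## Inbuilt embedding and clustering

When the user supplies no coordinates, each image is abstracted to a
vector of length 6 — the arithmetic means of its initial six channels in
stored plane order, computed on raw (pre-cleaning) intensities. Images
with fewer than six channels are zero-padded with a warning to keep the
cohort matrix rectangular. The stacked matrix feeds scikit-learn's t-SNE
(perplexity ``min(30, (n−1)/3)``, auto-reduced with a warning when a
requested value is infeasible; PCA initialization; seeded) and a
variational Bayesian Gaussian mixture (10 components by default, full
covariances, Dirichlet-process stick-breaking weight prior so unused
components self-prune; seeded).

One numerical choice matters on small cohorts: the mixture's covariance
floor (`reg_covar`) is set adaptively to half the mean per-feature cohort
variance. With the scikit-learn default floor (1e-6), tight well-separated
groups of a few dozen 6-vectors are shredded into micro-components; a
floor on the scale of the within-group variance removes that failure mode
while leaving between-group structure — which dominates the total
variance — intact. Generated coordinates and cluster labels are written
back in the same delimited dialect the readers consume, so a fallback run
is replayable as a pure coordinate-mode run, and the cluster labels
populate a `cluster` metadata category on the live canvas automatically.

## Rendering

The static canvas is a theme-colored background (black `#000000`, gray
`#404040`, dark blue `#0B0B45`) onto which tiles are pasted in render
order, later over earlier; rendering is byte-deterministic given the same
inputs and seed. The stack-montage view cleans every channel of a single
image, colors it with its palette entry, and arranges the tiles row-major
in channel order with the marker name drawn in a fixed bitmap font
beneath each tile.

The live canvas is emitted as a single self-contained HTML document:
an inline SVG scatter plus plain JavaScript implementing hover records
(image name, thumbnail filename, embedding coordinates, and every
metadata key–value pair), one button-switched view per metadata category
with a per-value legend, drag-pan, wheel-zoom, reset, and save-to-PNG.
The contract is the document's interactive behavior, not any particular
plotting framework, and a file that opens anywhere was preferred over a
served application.

## Synthetic data

The generator emulates immunofluorescence fields of view: per channel, a
dark background (8 intensity units), compact Gaussian blobs standing in
for stained cells (12 per channel, σ = 6 px at the default 336 × 252
frame — a Vectra-style field at quarter linear scale, kept small so test
suites run in seconds; acceptance checks that need full 1,344 × 1,008
frames scale σ accordingly), additive Gaussian noise (SD 3), and clipping
to unsigned byte. Blob centers stay at least 3σ from the border so no
signal mass is clipped away, which makes the per-image channel mean track
blob amplitude linearly.

Group structure enters through per-group, per-channel blob amplitudes; a
per-image amplitude jitter (relative SD 0.05) is the sole source of
within-group channel-mean spread, so the expected between-group
separation on a contrast channel is ``Δamp / (mean_amp · jitter)`` pooled
standard deviations and recovery experiments can state their effect size
exactly. The default two-group recipe makes group A brighter on channel 1
and group B on channel 2 by the amount matching the requested separation
(5 SD by default). Cohorts are written balanced across groups with
`group` and `patient` metadata tables and, optionally, random embedding
coordinates.

What the synthetic data do **not** contain: real staining chemistry,
spectral bleed-through, cell-scale texture, segmentation ground truth, or
spatially structured backgrounds. Passing tests therefore establish the
pipeline's arithmetic and contracts (cleaning steps compose correctly,
layouts respect their invariants, clustering recovers groups whose
channel means genuinely differ), not performance on real tissue, where
channel means are noisier summaries and group differences are rarely this
clean.

## Problem sizes and determinism

Routine tests use 6–30 images at 96 × 72 to 336 × 252 px; the
thumbnail-footprint check uses one full 7 × 1,344 × 1,008 frame; grid
stress goes to 210 tiles (a full tissue-microarray cohort) and
Poisson-disc validation to 92 points × 50 seeds. A single config-level
seed governs blob synthesis, sampling, shuffling, t-SNE and the mixture
fit; identical configs produce byte-identical canvas PNGs.

## Known limitations

No vendor formats beyond the TIFF family (no MIBI/IMC containers), no
lazy tile streaming, no de-overlapping or packing optimization in
coordinate mode, no per-tile zoom on the static canvas, no brightness /
sharpness adjustment or segmentation (the tool is a preview layer, not an
image-analysis suite), and UMAP coordinates are consumed but never
computed internally.
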