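# mplexview

A cohort-scale gallery viewer for multiplexed tissue images.

Multiplexed imaging platforms (PerkinElmer Vectra, CyCIF/t-CyCIF, CODEX /
PhenoCycler) produce multichannel images — one plane per protein marker —
and a study quickly accumulates dozens to hundreds of them. Most viewers
open one image at a time. `mplexview` instead renders the *whole cohort at
once* as an **image t-SNE**: every image is reduced to a cleaned, composited
thumbnail and placed on a large static canvas at its 2D embedding position
(t-SNE/UMAP coordinates computed by you, a vertical grid, or blue-noise
random positions), paired with an interactive scatterplot in which every
image is a dot carrying its metadata (response group, treatment phase,
cluster, patient) in a hover record. It is a preview layer for spotting
marker-expression patterns across a cohort before committing to per-image
analysis, for tumor-immune imaging studies and similar work.

## What it computes

* **Channel cleaning** — each selected marker channel passes through median
  filtering, Otsu thresholding (the exact within-class-variance minimizer
  σ²_w(t) = w₀(t)σ₀²(t) + w₁(t)σ₁²(t) over all 8-bit thresholds t),
  morphological closing, border-component clearing, and foreground
  upweighting, then the channels blend additively into an RGB composite in
  unsigned-byte range.
* **Layouts** — a monotone per-axis affine map of embedding coordinates onto
  the canvas; a non-overlapping row-major grid; or Bridson Poisson-disc
  sampling (all pairwise distances ≥ r, grid-accelerated dart throwing,
  capped at one point per image). A seeded shuffle controls the z-order of
  overlapping tiles.
* **Inbuilt fallback embedding/clustering** — with no user coordinates, each
  image is abstracted to the 6-vector of its initial six channel means, the
  stacked matrix is embedded with t-SNE, and a variational Bayesian Gaussian
  mixture (Dirichlet-process prior, self-pruning components) assigns cluster
  labels that feed the live canvas automatically.
* **Renderings** — a deterministic static canvas PNG, per-image PNG tiles
  (optionally framed by metadata-colored borders), a per-channel stack
  montage for single images, and a self-contained interactive HTML
  scatterplot with hover, pan, zoom, save, and reset.

Supported inputs: plain multi-page TIFF, OME-TIFF (channel names read from
OME-XML), and QPTIFF-style pyramidal TIFF; delimited text for metadata and
coordinates. A synthetic-cohort generator (`mplexview.synthetic`) fabricates
realistic blob-structured test images in all three dialects.

## Worked example

```python
from pathlib import Path
from mplexview import synthetic
from mplexview.cli import RunConfig, run

# 12 synthetic 7-channel Vectra-style images in two groups whose channel
# means differ by 5 pooled SD, plus group/patient metadata tables
recipe = synthetic.two_group_recipe(separation_sd=5.0, n_images=12, seed=0)
manifest = synthetic.generate_cohort(recipe, Path("demo_cohort"))

config = RunConfig(
    input_dir=str(manifest["images_dir"]),
    output_dir="demo_out",
    layout="coords",          # no coordinate file -> inbuilt t-SNE + clustering
    metadata_dir=str(manifest["metadata_dir"]),
    border=True, border_category="group",
    theme="black", seed=42,
)
for name, path in run(config).items():
    print(f"{name}: {path}")
```

prints

```
canvas: demo_out/static/images_coords_42.png
live: demo_out/images_live.html
tiles_dir: demo_out/output_tiles
positions: demo_out/positions.csv
config: demo_out/run_config.yaml
log: demo_out/run.log
```

`images_coords_42.png` is the image t-SNE: all 12 thumbnails, cleaned and
bordered by group color, placed at the coordinates the fallback t-SNE
generated (also written to `demo_out/generated/generated_coordinates.csv`,
with the mixture's cluster labels in `demo_out/generated/cluster.csv`, e.g.
`img000,c2`). `images_live.html` opens in any browser: one dot per image,
one tab per metadata category (`group`, `patient`, and the auto-generated
`cluster`), with the full hover record per dot. `positions.csv` holds the
pixel position of every tile, and re-running from `run_config.yaml`
reproduces the canvas byte-for-byte.

The same run works from the shell:

```sh
mplexview --input-dir demo_cohort/images --output-dir demo_out \
          --layout coords --metadata-dir demo_cohort/metadata \
          --border --border-category group --seed 42
```

For a single image, `--mode stack_montage` renders every channel as its own
labelled tile.

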