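"""Static canvas and live-canvas rendering.

The static canvas is a large PNG onto which all cohort thumbnails are
pasted at their layout positions, in render order (later tiles draw over
earlier ones), over a user-chosen background theme.  The live canvas is
its interactive counterpart: a standalone HTML scatterplot in which every
image is a dot carrying a hover record (image name, thumbnail name,
coordinates, all metadata), with one view per metadata category and pan /
wheel-zoom / save / reset tools.  A stack-montage view renders every
channel of a single image as its own labelled tile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from PIL import Image, ImageDraw, ImageFont

from .io_formats import CohortMetadata, CoordinateTable, MultiplexImage, save_png
from .layout import LayoutResult, grid_layout
from .preprocess import (
    CleanParams,
    PALETTE_CYCLE,
    clean_channel,
    default_palette,
)
from .thumbnail import Thumbnail, _scaled_dims

__all__ = [
    "CanvasSpec",
    "HoverRecord",
    "THEMES",
    "render_static_canvas",
    "stack_montage",
    "build_live_scatter",
    "make_hover_records",
]

#: Canvas color themes: background fill only, thumbnails are never recolored.
THEMES: dict[str, tuple[int, int, int]] = {
    "black": (0, 0, 0),
    "gray": (64, 64, 64),
    "dark_blue": (11, 11, 69),
}

LABEL_STRIP_PX = 14  # text strip under each montage tile


@dataclass
class CanvasSpec:
    """Everything needed to draw one static canvas."""

    theme: str
    layout: LayoutResult
    thumbnails: list[Thumbnail]

    def __post_init__(self) -> None:
        if self.theme not in THEMES:
            raise ValueError(f"theme must be one of {sorted(THEMES)}")
        tile_ids = {t.source_id for t in self.thumbnails}
        if tile_ids != set(self.layout.positions):
            raise ValueError("layout and thumbnails must cover the same image ids")


@dataclass
class HoverRecord:
    """Fields exposed when hovering a scatter point."""

    image_id: str
    thumbnail_name: str
    x: float
    y: float
    metadata: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "image": self.image_id,
            "thumbnail": self.thumbnail_name,
            "x": self.x,
            "y": self.y,
            **self.metadata,
        }


def render_static_canvas(
    spec: CanvasSpec,
    out_path: str | Path | None = None,
) -> np.ndarray:
    """Paste thumbnails onto a theme-colored background in render order."""
    width, height = spec.layout.canvas_dims
    canvas = np.empty((height, width, 3), dtype=np.uint8)
    canvas[:] = THEMES[spec.theme]
    tiles = {t.source_id: t for t in spec.thumbnails}
    for image_id in spec.layout.render_order:
        tile = tiles[image_id].rgb_tile
        x, y = spec.layout.positions[image_id]
        h, w = tile.shape[:2]
        if x < 0 or y < 0 or x + w > width or y + h > height:
            raise ValueError(
                f"tile {image_id!r} at ({x},{y}) size ({w}x{h}) exceeds canvas"
            )
        canvas[y : y + h, x : x + w] = tile
    if out_path is not None:
        save_png(canvas, out_path)
    return canvas


def _labelled_tile(
    tile: np.ndarray, label: str, background: tuple[int, int, int]
) -> np.ndarray:
    """Append a text strip naming the marker beneath a tile."""
    h, w = tile.shape[:2]
    out = Image.new("RGB", (w, h + LABEL_STRIP_PX), background)
    out.paste(Image.fromarray(tile), (0, 0))
    draw = ImageDraw.Draw(out)
    draw.text((2, h + 1), label[:32], fill=(255, 255, 255), font=ImageFont.load_default())
    return np.asarray(out)


def stack_montage(
    image: MultiplexImage,
    params: CleanParams | None = None,
    palette: Mapping[str, tuple[int, int, int]] | None = None,
    tile_edge: int = 222,
    grid_cols: int | None = None,
    theme: str = "black",
    gap_px: int = 10,
) -> CanvasSpec:
    """One cleaned, palette-colored tile per channel of a single image.

    Tiles are arranged row-major in channel order and labelled with their
    marker names; the result renders through :func:`render_static_canvas`.
    """
    params = params or CleanParams()
    full_palette = default_palette(image.marker_names)
    if palette:
        full_palette.update(palette)
    if grid_cols is None:
        grid_cols = max(1, int(np.ceil(np.sqrt(image.n_channels))))

    rows, cols = image.pixel_dims
    t_rows, t_cols = _scaled_dims(rows, cols, tile_edge)
    thumbs: list[Thumbnail] = []
    for i, marker in enumerate(image.marker_names):
        cleaned = clean_channel(image.channels[i], params).astype(np.float64)
        color = np.asarray(full_palette[marker], dtype=np.float64)
        colored = np.clip(
            np.rint(cleaned[:, :, np.newaxis] / 255.0 * color), 0, 255
        ).astype(np.uint8)
        tile = np.asarray(
            Image.fromarray(colored).resize((t_cols, t_rows), Image.Resampling.BOX)
        )
        tile_id = f"{image.image_id}_{i:02d}_{marker}"
        thumbs.append(
            Thumbnail(
                rgb_tile=_labelled_tile(tile, marker, THEMES[theme]),
                source_id=tile_id,
                out_name=f"{tile_id}.png",
            )
        )

    tile_dims = (t_rows + LABEL_STRIP_PX, t_cols)
    canvas_width = gap_px + grid_cols * (tile_dims[1] + gap_px)
    positions, dims = grid_layout(
        [t.source_id for t in thumbs], canvas_width, tile_dims, gap_px
    )
    layout = LayoutResult(
        mode="grid",
        positions=positions,
        render_order=[t.source_id for t in thumbs],
        canvas_dims=dims,
    )
    return CanvasSpec(theme=theme, layout=layout, thumbnails=thumbs)


def make_hover_records(
    coords: CoordinateTable,
    metadata: CohortMetadata | None = None,
    thumbnail_names: Mapping[str, str] | None = None,
) -> list[HoverRecord]:
    """One hover record per plotted point, in coordinate-table order."""
    metadata = metadata or CohortMetadata()
    records = []
    for image_id, (x, y) in coords.coords.items():
        thumb = (
            thumbnail_names.get(image_id, f"{image_id}.png")
            if thumbnail_names
            else f"{image_id}.png"
        )
        records.append(
            HoverRecord(
                image_id=image_id,
                thumbnail_name=thumb,
                x=x,
                y=y,
                metadata=metadata.annotations_for(image_id),
            )
        )
    return records


def _hex(color: tuple[int, int, int]) -> str:
    return "#{:02x}{:02x}{:02x}".format(*color)


def _category_colors(
    metadata: CohortMetadata, category: str
) -> dict[str, str]:
    """Stable value -> hex color map: user colors first, then palette cycle."""
    values = sorted(set(metadata.categories.get(category, {}).values()))
    out = {}
    cycle = 0
    for v in values:
        if v in metadata.colors:
            out[v] = _hex(metadata.colors[v])
        else:
            out[v] = _hex(PALETTE_CYCLE[cycle % len(PALETTE_CYCLE)])
            cycle += 1
    return out


_HTML_TEMPLATE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>__TITLE__</title>
<style>
 body { font-family: sans-serif; background: #fafafa; margin: 1em; }
 #tabs button, #tools button { margin: 0 4px 8px 0; padding: 4px 10px; cursor: pointer; }
 #tabs button.active { background: #1f77b4; color: #fff; }
 #plot { border: 1px solid #999; background: #fff; cursor: grab; }
 #tooltip { position: absolute; display: none; background: #fff; border: 1px solid #555;
            padding: 6px 8px; font-size: 12px; pointer-events: none; box-shadow: 2px 2px 4px #0003; }
 #legend span.swatch { display: inline-block; width: 12px; height: 12px; margin-right: 4px; }
 #legend .entry { margin-right: 14px; font-size: 13px; }
</style>
</head>
<body>
<h2>__TITLE__</h2>
<div id="tabs"></div>
<div id="tools">
 <button id="reset">Reset view</button>
 <button id="save">Save PNG</button>
 <span style="font-size:12px;color:#555">drag to pan &middot; wheel to zoom &middot; hover a dot for its record</span>
</div>
<svg id="plot" width="__W__" height="__H__" viewBox="0 0 __W__ __H__"
     xmlns="http://www.w3.org/2000/svg"></svg>
<div id="legend"></div>
<div id="tooltip"></div>
<script>
const DATA = __DATA__;
const W = __W__, H = __H__, HOME = [0, 0, W, H];
let view = HOME.slice();
const svg = document.getElementById("plot");
const tooltip = document.getElementById("tooltip");
const NS = "http://www.w3.org/2000/svg";
let activeCategory = DATA.categories.length ? DATA.categories[0] : null;

function pointColor(p) {
  if (!activeCategory) return "#1f77b4";
  const v = p.meta[activeCategory];
  if (v === undefined) return "#aaaaaa";
  return DATA.colors[activeCategory][v] || "#aaaaaa";
}
function draw() {
  svg.innerHTML = "";
  for (const p of DATA.points) {
    const c = document.createElementNS(NS, "circle");
    c.setAttribute("cx", p.px); c.setAttribute("cy", p.py);
    c.setAttribute("r", 6); c.setAttribute("fill", pointColor(p));
    c.setAttribute("stroke", "#333"); c.setAttribute("stroke-width", "0.5");
    c.setAttribute("class", "dot");
    c.addEventListener("mousemove", (e) => showTip(e, p));
    c.addEventListener("mouseleave", hideTip);
    svg.appendChild(c);
  }
  drawLegend();
  drawTabs();
}
function recordHtml(p) {
  let rows = `<b>image</b>: ${p.image}<br><b>thumbnail</b>: ${p.thumbnail}<br>` +
             `<b>x</b>: ${p.x}<br><b>y</b>: ${p.y}`;
  for (const [k, v] of Object.entries(p.meta)) rows += `<br><b>${k}</b>: ${v}`;
  return rows;
}
function showTip(e, p) {
  tooltip.innerHTML = recordHtml(p);
  tooltip.style.left = (e.pageX + 12) + "px";
  tooltip.style.top = (e.pageY + 12) + "px";
  tooltip.style.display = "block";
}
function hideTip() { tooltip.style.display = "none"; }
function drawLegend() {
  const legend = document.getElementById("legend");
  legend.innerHTML = "";
  if (!activeCategory) return;
  for (const [value, color] of Object.entries(DATA.colors[activeCategory])) {
    const e = document.createElement("span");
    e.className = "entry";
    e.innerHTML = `<span class="swatch" style="background:${color}"></span>${value}`;
    legend.appendChild(e);
  }
}
function drawTabs() {
  const tabs = document.getElementById("tabs");
  tabs.innerHTML = "";
  for (const cat of DATA.categories) {
    const b = document.createElement("button");
    b.textContent = cat;
    if (cat === activeCategory) b.className = "active";
    b.addEventListener("click", () => { activeCategory = cat; draw(); });
    tabs.appendChild(b);
  }
}
function setView() { svg.setAttribute("viewBox", view.join(" ")); }
svg.addEventListener("wheel", (e) => {
  e.preventDefault();
  const f = e.deltaY > 0 ? 1.15 : 1 / 1.15;
  const r = svg.getBoundingClientRect();
  const mx = view[0] + (e.clientX - r.left) / r.width * view[2];
  const my = view[1] + (e.clientY - r.top) / r.height * view[3];
  view = [mx - (mx - view[0]) * f, my - (my - view[1]) * f, view[2] * f, view[3] * f];
  setView();
});
let drag = null;
svg.addEventListener("mousedown", (e) => { drag = [e.clientX, e.clientY, view.slice()]; });
window.addEventListener("mouseup", () => { drag = null; });
window.addEventListener("mousemove", (e) => {
  if (!drag) return;
  const r = svg.getBoundingClientRect();
  view[0] = drag[2][0] - (e.clientX - drag[0]) / r.width * view[2];
  view[1] = drag[2][1] - (e.clientY - drag[1]) / r.height * view[3];
  setView();
});
document.getElementById("reset").addEventListener("click", () => { view = HOME.slice(); setView(); });
document.getElementById("save").addEventListener("click", () => {
  const xml = new XMLSerializer().serializeToString(svg);
  const img = new Image();
  img.onload = () => {
    const canvas = document.createElement("canvas");
    canvas.width = W; canvas.height = H;
    const ctx = canvas.getContext("2d");
    ctx.fillStyle = "#ffffff"; ctx.fillRect(0, 0, W, H);
    ctx.drawImage(img, 0, 0);
    const a = document.createElement("a");
    a.href = canvas.toDataURL("image/png");
    a.download = "live_canvas.png";
    a.click();
  };
  img.src = "data:image/svg+xml;base64," + btoa(unescape(encodeURIComponent(xml)));
});
draw();
</script>
</body>
</html>
"""


def build_live_scatter(
    coords: CoordinateTable,
    metadata: CohortMetadata | None = None,
    thumbnail_names: Mapping[str, str] | None = None,
    out_path: str | Path | None = None,
    title: str = "Cohort live canvas",
    plot_size: tuple[int, int] = (800, 600),
) -> str:
    """Standalone interactive HTML scatter of the cohort embedding.

    One view (tab) per metadata category, points colored by that
    category's value map; without metadata a single uncolored scatter is
    rendered.  Hovering a point exposes its full record; pan, wheel zoom,
    save-to-PNG and reset tools are built in.  Returns the HTML text and
    optionally writes it to ``out_path``.
    """
    metadata = metadata or CohortMetadata()
    records = make_hover_records(coords, metadata, thumbnail_names)
    width, height = plot_size
    margin = 40

    xy = coords.as_arrays([r.image_id for r in records]) if records else np.zeros((0, 2))
    if len(xy):
        lo, hi = xy.min(axis=0), xy.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        px = margin + (xy[:, 0] - lo[0]) / span[0] * (width - 2 * margin)
        py = margin + (hi[1] - xy[:, 1]) / span[1] * (height - 2 * margin)
    else:
        px = py = np.zeros(0)

    categories = metadata.category_names()
    data = {
        "points": [
            {
                "image": r.image_id,
                "thumbnail": r.thumbnail_name,
                "x": r.x,
                "y": r.y,
                "px": round(float(px[i]), 2),
                "py": round(float(py[i]), 2),
                "meta": r.metadata,
            }
            for i, r in enumerate(records)
        ],
        "categories": categories,
        "colors": {cat: _category_colors(metadata, cat) for cat in categories},
    }
    html = (
        _HTML_TEMPLATE.replace("__TITLE__", title)
        .replace("__W__", str(width))
        .replace("__H__", str(height))
        .replace("__DATA__", json.dumps(data, sort_keys=True))
    )
    if out_path is not None:
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        out_path.write_text(html)
    return html
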