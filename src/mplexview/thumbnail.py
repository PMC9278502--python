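"""Downscaled RGB tiles and metadata-colored borders.

A thumbnail is a concise stand-in for one multiplexed image: its cleaned
composite, downscaled so the longer edge matches a configured maximum
(aspect preserved, area-averaging resampler).  An optional uniform border
frames the tile in a color carried by cohort metadata, e.g. one color per
response group.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from PIL import Image

from .io_formats import MultiplexImage, save_png
from .preprocess import CleanParams, CleanedComposite, composite_channels

__all__ = [
    "Thumbnail",
    "make_thumbnail",
    "make_weighted_thumbnail",
    "add_border",
    "DEFAULT_MAX_EDGE",
]

#: Default longer-edge size of a tile, px.
DEFAULT_MAX_EDGE = 222


@dataclass
class Thumbnail:
    """A small RGB tile standing in for one cohort image."""

    rgb_tile: np.ndarray  # (rows, cols, 3) uint8
    source_id: str
    border_color: tuple[int, int, int] | None = None
    border_px: int = 0
    out_name: str = ""

    def __post_init__(self) -> None:
        if not self.out_name:
            self.out_name = f"{self.source_id}.png"

    @property
    def tile_dims(self) -> tuple[int, int]:
        return self.rgb_tile.shape[0], self.rgb_tile.shape[1]

    def save(self, out_dir: str | Path) -> Path:
        return save_png(self.rgb_tile, Path(out_dir) / self.out_name)


def _scaled_dims(rows: int, cols: int, max_edge: int) -> tuple[int, int]:
    """Aspect-preserving target dims; rounding half-up on the shorter edge."""
    longer = max(rows, cols)
    if longer <= max_edge:
        return rows, cols
    scale = max_edge / longer
    if rows >= cols:
        return max_edge, int(np.floor(cols * scale + 0.5))
    return int(np.floor(rows * scale + 0.5)), max_edge


def make_thumbnail(
    composite: CleanedComposite,
    max_edge: int = DEFAULT_MAX_EDGE,
    out_dir: str | Path | None = None,
) -> Thumbnail:
    """Downscale a cleaned composite so its longer edge equals ``max_edge``.

    Images already smaller than ``max_edge`` are left at native size.  The
    tile is written to ``out_dir`` as ``<image_id>.png`` when given.
    """
    if max_edge < 16:
        raise ValueError("max_edge must be >= 16 px")
    rows, cols = composite.rgb.shape[:2]
    new_rows, new_cols = _scaled_dims(rows, cols, max_edge)
    if (new_rows, new_cols) == (rows, cols):
        tile = composite.rgb.copy()
    else:
        img = Image.fromarray(composite.rgb)
        tile = np.asarray(img.resize((new_cols, new_rows), Image.Resampling.BOX))
    thumb = Thumbnail(rgb_tile=tile, source_id=composite.source_id)
    if out_dir is not None:
        thumb.save(out_dir)
    return thumb


def make_weighted_thumbnail(
    image: MultiplexImage,
    selection: Sequence[str],
    weights: Mapping[str, float],
    params: CleanParams | None = None,
    palette: Mapping[str, tuple[int, int, int]] | None = None,
    max_edge: int = DEFAULT_MAX_EDGE,
    out_dir: str | Path | None = None,
) -> Thumbnail:
    """Thumbnail with each cleaned channel scaled by a nonnegative weight.

    With all weights 1 this is identical to the unweighted thumbnail; a
    zero weight removes that marker's color from the tile entirely.
    """
    composite = composite_channels(
        image, selection, params=params, palette=palette, weights=weights
    )
    return make_thumbnail(composite, max_edge=max_edge, out_dir=out_dir)


def add_border(
    thumb: Thumbnail,
    color: tuple[int, int, int],
    border_px: int = 4,
) -> Thumbnail:
    """Paste the tile onto a slightly larger rectangle filled with ``color``.

    Output dims grow by ``2 * border_px`` per axis; interior pixels are the
    original tile exactly.
    """
    if border_px < 1:
        raise ValueError("border_px must be >= 1")
    tile = thumb.rgb_tile
    framed = np.empty(
        (tile.shape[0] + 2 * border_px, tile.shape[1] + 2 * border_px, 3),
        dtype=np.uint8,
    )
    framed[:] = np.asarray(color, dtype=np.uint8)
    framed[border_px:-border_px, border_px:-border_px] = tile
    return replace(thumb, rgb_tile=framed, border_color=tuple(color), border_px=border_px)
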