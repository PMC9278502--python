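"""Canvas placement of thumbnails.

Three layout modes position tiles on the static canvas: an affine mapping
of user-supplied embedding coordinates (t-SNE/UMAP), a row-major vertical
grid, and blue-noise random positions from a grid-accelerated Poisson-disc
sampler.  A seeded shuffle controls the front-to-back render order, which
matters when coordinate-mode tiles overlap.

Canvas convention: origin at top-left, x rightward, y downward; embedding
y is flipped so the scatterplot and the canvas agree visually.  Positions
are the top-left corner of each tile, and every tile lies fully inside the
canvas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import CoordinateTable

logger = logging.getLogger(__name__)

__all__ = [
    "LayoutResult",
    "scale_coords_to_canvas",
    "grid_layout",
    "poisson_disc_sample",
    "shuffle_order",
    "build_layout",
    "DEFAULT_CANVAS",
    "DEFAULT_MARGIN",
]

DEFAULT_CANVAS: tuple[int, int] = (4000, 3000)  # (width, height) px
DEFAULT_MARGIN: int = 50


@dataclass
class LayoutResult:
    """Positions, z-order and canvas size for one rendering."""

    mode: str  # "coords" | "grid" | "random"
    positions: dict[str, tuple[int, int]]  # image_id -> top-left (x, y) px
    render_order: list[str]
    canvas_dims: tuple[int, int]  # (width, height) px

    def __post_init__(self) -> None:
        if sorted(self.render_order) != sorted(self.positions):
            raise ValueError("render_order must be a permutation of the image ids")


def scale_coords_to_canvas(
    table: CoordinateTable,
    canvas_dims: tuple[int, int] = DEFAULT_CANVAS,
    tile_dims: tuple[int, int] = (222, 222),
    margin_px: int = DEFAULT_MARGIN,
) -> dict[str, tuple[int, int]]:
    """Affinely map embedding coordinates onto the drawable canvas span.

    Per axis, [min, max] of the embedding maps onto
    ``canvas − 2·margin − tile``; relative order is preserved, embedding y
    is flipped (larger y plots higher).  When all images share a
    coordinate on an axis the tiles are centered on that axis; tile
    overlap is allowed — the shuffle governs stacking.
    """
    if len(table) == 0:
        return {}
    if margin_px < 0:
        raise ValueError("margin_px must be >= 0")
    width, height = canvas_dims
    tile_h, tile_w = tile_dims
    span_x = width - 2 * margin_px - tile_w
    span_y = height - 2 * margin_px - tile_h
    if span_x < 0 or span_y < 0:
        raise ValueError("tile plus margins exceed canvas dims")

    ids = table.image_ids
    xy = table.as_arrays(ids)
    positions: dict[str, tuple[int, int]] = {}
    for axis, span, flip in ((0, span_x, False), (1, span_y, True)):
        lo, hi = xy[:, axis].min(), xy[:, axis].max()
        if hi > lo:
            frac = (xy[:, axis] - lo) / (hi - lo)
            if flip:
                frac = 1.0 - frac
            pix = margin_px + frac * span
        else:
            center = ((width - tile_w) if axis == 0 else (height - tile_h)) / 2.0
            pix = np.full(len(ids), center)
        if axis == 0:
            px_x = pix
        else:
            px_y = pix
    for i, image_id in enumerate(ids):
        positions[image_id] = (int(round(px_x[i])), int(round(px_y[i])))
    return positions


def grid_layout(
    image_ids: Sequence[str],
    canvas_width: int,
    tile_dims: tuple[int, int],
    gap_px: int = 10,
) -> tuple[dict[str, tuple[int, int]], tuple[int, int]]:
    """Row-major vertical grid; returns positions and the canvas dims used.

    ``per_row = floor((canvas_width − gap) / (tile_w + gap))``; rows are
    added as needed, so no two tiles overlap.  Canvas height grows to fit
    the last row.
    """
    tile_h, tile_w = tile_dims
    per_row = int((canvas_width - gap_px) // (tile_w + gap_px))
    if per_row < 1:
        raise ValueError(
            f"tile width {tile_w}+gap exceeds canvas width {canvas_width}"
        )
    positions: dict[str, tuple[int, int]] = {}
    for i, image_id in enumerate(image_ids):
        row, col = divmod(i, per_row)
        positions[image_id] = (
            gap_px + col * (tile_w + gap_px),
            gap_px + row * (tile_h + gap_px),
        )
    n_rows = (len(image_ids) + per_row - 1) // per_row
    height = gap_px + n_rows * (tile_h + gap_px)
    return positions, (canvas_width, max(height, gap_px))


def poisson_disc_sample(
    canvas_dims: tuple[int, int],
    r: float,
    k: int = 30,
    n_points: int | None = None,
    seed: int = 42,
) -> list[tuple[float, float]]:
    """Blue-noise points with pairwise distance >= r (Bridson dart throwing).

    A background grid of cell size ``r/sqrt(2)`` (at most one point per
    cell) accelerates the neighbor test; each active point spawns up to
    ``k`` candidates uniformly in the annulus [r, 2r] and candidates
    closer than ``r`` to any existing point are rejected.  Sampling stops
    at ``n_points`` when given — a capacity modification that tolerates
    under-filling: when the domain cannot hold ``n_points`` at distance
    ``r`` the shorter list is returned with a logged warning rather than
    failing.  Deterministic for a given seed.
    """
    if r <= 0:
        raise ValueError("r must be > 0")
    if k < 1:
        raise ValueError("k must be >= 1")
    width, height = canvas_dims
    if n_points is not None and n_points <= 0:
        return []
    rng = np.random.default_rng(seed)
    cell = r / np.sqrt(2)
    nx, ny = int(np.ceil(width / cell)), int(np.ceil(height / cell))
    grid: dict[tuple[int, int], int] = {}
    points: list[tuple[float, float]] = []

    def cell_coords(pt: tuple[float, float]) -> tuple[int, int]:
        return int(pt[0] // cell), int(pt[1] // cell)

    def point_valid(pt: tuple[float, float]) -> bool:
        cx, cy = cell_coords(pt)
        for ix in range(max(cx - 2, 0), min(cx + 3, nx)):
            for iy in range(max(cy - 2, 0), min(cy + 3, ny)):
                j = grid.get((ix, iy))
                if j is not None:
                    dx = points[j][0] - pt[0]
                    dy = points[j][1] - pt[1]
                    if dx * dx + dy * dy < r * r:
                        return False
        return True

    def accept(pt: tuple[float, float]) -> None:
        grid[cell_coords(pt)] = len(points)
        points.append(pt)

    accept((float(rng.uniform(0, width)), float(rng.uniform(0, height))))
    active = [0]
    while active and (n_points is None or len(points) < n_points):
        idx = int(rng.integers(len(active)))
        base = points[active[idx]]
        for _ in range(k):
            rho = rng.uniform(r, 2 * r)
            theta = rng.uniform(0, 2 * np.pi)
            cand = (base[0] + rho * np.cos(theta), base[1] + rho * np.sin(theta))
            if 0 <= cand[0] < width and 0 <= cand[1] < height and point_valid(cand):
                accept(cand)
                active.append(len(points) - 1)
                break
        else:
            active.pop(idx)
    if n_points is not None and len(points) < n_points:
        logger.warning(
            "Poisson-disc sampling placed %d of %d requested points "
            "(r=%g too large for canvas %s)",
            len(points), n_points, r, canvas_dims,
        )
    return points[:n_points] if n_points is not None else points


def shuffle_order(image_ids: Sequence[str], seed: int = 42) -> list[str]:
    """Uniform random permutation of the render order; later ids draw on top."""
    if not image_ids:
        raise ValueError("image_ids must be nonempty")
    rng = np.random.default_rng(seed)
    ids = list(image_ids)
    return [ids[i] for i in rng.permutation(len(ids))]


def build_layout(
    image_ids: Sequence[str],
    mode: str,
    tile_dims: tuple[int, int],
    coords: CoordinateTable | None = None,
    canvas_dims: tuple[int, int] = DEFAULT_CANVAS,
    margin_px: int = DEFAULT_MARGIN,
    gap_px: int = 10,
    shuffle: bool = False,
    seed: int = 42,
) -> LayoutResult:
    """Assemble a LayoutResult for one of the three modes.

    ``coords`` mode requires a CoordinateTable covering every image;
    ``random`` mode draws Poisson-disc positions at a minimum separation
    of half the longer tile edge (tiles may still overlap, as in
    coordinate mode); ``grid`` mode never overlaps.
    """
    ids = list(image_ids)
    tile_h, tile_w = tile_dims
    if mode == "coords":
        if coords is None:
            raise ValueError("coords mode requires a CoordinateTable")
        missing = [i for i in ids if i not in coords.coords]
        if missing:
            raise ValueError(f"no coordinates for images: {missing}")
        sub = CoordinateTable({i: coords.coords[i] for i in ids})
        positions = scale_coords_to_canvas(sub, canvas_dims, tile_dims, margin_px)
        dims = canvas_dims
    elif mode == "grid":
        positions, dims = grid_layout(ids, canvas_dims[0], tile_dims, gap_px)
    elif mode == "random":
        drawable = (
            canvas_dims[0] - 2 * margin_px - tile_w,
            canvas_dims[1] - 2 * margin_px - tile_h,
        )
        if drawable[0] <= 0 or drawable[1] <= 0:
            raise ValueError("tile plus margins exceed canvas dims")
        min_sep = max(tile_dims) / 2.0
        pts = poisson_disc_sample(drawable, r=min_sep, n_points=len(ids), seed=seed)
        if len(pts) < len(ids):  # under-filled domain: halve r, then top up uniformly
            pts = poisson_disc_sample(
                drawable, r=max(min_sep / 2.0, 1.0), n_points=len(ids), seed=seed
            )
        if len(pts) < len(ids):
            extra = np.random.default_rng(seed).uniform(
                (0, 0), drawable, size=(len(ids) - len(pts), 2)
            )
            pts = pts + [(float(x), float(y)) for x, y in extra]
        positions = {
            image_id: (int(round(margin_px + x)), int(round(margin_px + y)))
            for image_id, (x, y) in zip(ids, pts)
        }
        dims = canvas_dims
    else:
        raise ValueError(f"unknown layout mode {mode!r}")

    order = shuffle_order(ids, seed) if (shuffle and ids) else ids
    return LayoutResult(
        mode=mode, positions=positions, render_order=order, canvas_dims=dims
    )
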