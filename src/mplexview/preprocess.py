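"""Per-channel denoising and marker compositing.

Each user-selected marker channel is cleaned independently through a fixed
five-step pipeline — median filter, Otsu binarization, morphological
closing of the foreground mask, removal of components touching the image
border, and intensity upweighting — then the cleaned channels are blended
additively into an RGB composite using a per-marker display color.  All
cleaned output is unsigned byte ([0, 255]); background pixels are zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import closing, disk
from skimage.segmentation import clear_border

from .io_formats import MultiplexImage

logger = logging.getLogger(__name__)

__all__ = [
    "CleanParams",
    "CleanedComposite",
    "OtsuResult",
    "otsu_threshold",
    "clean_channel",
    "composite_channels",
    "to_uint8",
    "default_palette",
    "PALETTE_CYCLE",
]

#: Fixed 10-color categorical cycle (RGB, 0-255) assigned in marker order.
PALETTE_CYCLE: tuple[tuple[int, int, int], ...] = (
    (31, 119, 180), (255, 127, 14), (44, 160, 44), (214, 39, 40),
    (148, 103, 189), (140, 86, 75), (227, 119, 194), (127, 127, 127),
    (188, 189, 34), (23, 190, 207),
)


@dataclass
class CleanParams:
    """Tunables of the five-step channel cleaning pipeline.

    median_kernel : odd window size of the median filter, px.
    closing_radius : radius of the disk structuring element used to close
        gaps in the foreground mask, px (0 disables closing).
    upweight_factor : multiplier applied to surviving foreground
        intensities to preserve morphology, clipped to 255.
    """

    median_kernel: int = 3
    closing_radius: int = 1
    upweight_factor: float = 1.5

    def __post_init__(self) -> None:
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and >= 1")
        if self.closing_radius < 0:
            raise ValueError("closing_radius must be >= 0")
        if self.upweight_factor < 1:
            raise ValueError("upweight_factor must be >= 1")


@dataclass
class CleanedComposite:
    """Cleaned selected channels plus their additive RGB blend."""

    cleaned_channels: np.ndarray  # (n_selected, rows, cols) uint8
    selected_markers: list[str]
    rgb: np.ndarray  # (rows, cols, 3) uint8
    palette: dict[str, tuple[int, int, int]]
    source_id: str = ""


class OtsuResult(NamedTuple):
    threshold: float
    degenerate: bool


def to_uint8(raster: np.ndarray) -> np.ndarray:
    """Min–max scale a single channel into unsigned byte range.

    uint8 input is passed through unchanged; a constant channel maps to
    all zeros (no contrast to preserve).
    """
    raster = np.asarray(raster)
    if raster.dtype == np.uint8:
        return raster
    lo = float(raster.min())
    hi = float(raster.max())
    if hi <= lo:
        return np.zeros(raster.shape, dtype=np.uint8)
    scaled = (raster.astype(np.float64) - lo) * (255.0 / (hi - lo))
    return np.rint(scaled).astype(np.uint8)


def otsu_threshold(raster: np.ndarray) -> OtsuResult:
    """Histogram threshold minimizing total within-class intensity variance.

    The threshold ``t`` assigns pixels ``<= t`` to background and ``> t``
    to foreground.  All candidate thresholds are searched exhaustively on
    the 256-bin histogram; ties break toward the smallest threshold.  A
    constant raster is degenerate: its value is returned with the
    ``degenerate`` flag set and the whole image is treated as background.
    """
    raster = np.asarray(raster)
    if raster.size == 0:
        raise ValueError("empty raster")
    if raster.min() == raster.max():
        return OtsuResult(float(raster.ravel()[0]), True)
    values = to_uint8(raster).ravel()

    hist = np.bincount(values, minlength=256).astype(np.float64)
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)  # pixels <= t
    w1 = values.size - w0
    s0 = np.cumsum(hist * levels)
    sq0 = np.cumsum(hist * levels * levels)
    s_tot, sq_tot = s0[-1], sq0[-1]

    with np.errstate(divide="ignore", invalid="ignore"):
        var0 = sq0 / w0 - (s0 / w0) ** 2
        var1 = (sq_tot - sq0) / w1 - ((s_tot - s0) / w1) ** 2
    var0 = np.where(w0 > 0, var0, 0.0)
    var1 = np.where(w1 > 0, var1, 0.0)
    total = np.where((w0 > 0) & (w1 > 0), w0 * var0 + w1 * var1, np.inf)
    t = int(np.argmin(total[:-1]))  # t == 255 leaves foreground empty
    return OtsuResult(float(t), False)


def clean_channel(raster: np.ndarray, params: CleanParams | None = None) -> np.ndarray:
    """Clean one marker channel; returns an unsigned-byte raster.

    Steps, in order: median filter; Otsu binarization into a foreground
    mask; morphological closing of the mask to refine morphological
    boundaries; clearing of mask components that touch the raster border
    to sharpen the boundaries; multiplicative upweighting of surviving
    foreground intensities, clipped to [0, 255].  Background pixels are 0.
    The mask is applied multiplicatively to the median-filtered
    intensities, so foreground morphology is preserved rather than
    binarized.  A degenerate (constant) channel yields all zeros.
    """
    params = params or CleanParams()
    img = to_uint8(np.asarray(raster))
    if img.size == 0:
        raise ValueError("empty raster")

    med = ndimage.median_filter(img, size=params.median_kernel)
    t, degenerate = otsu_threshold(med)
    if degenerate:
        return np.zeros(img.shape, dtype=np.uint8)
    mask = med > t
    if params.closing_radius > 0:
        mask = closing(mask, disk(params.closing_radius))
    mask = clear_border(mask)
    out = med.astype(np.float64) * mask * params.upweight_factor
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def default_palette(marker_names: Sequence[str]) -> dict[str, tuple[int, int, int]]:
    """Assign the fixed categorical color cycle in marker order."""
    return {
        name: PALETTE_CYCLE[i % len(PALETTE_CYCLE)]
        for i, name in enumerate(marker_names)
    }


def composite_channels(
    image: MultiplexImage,
    selection: Sequence[str],
    params: CleanParams | None = None,
    palette: Mapping[str, tuple[int, int, int]] | None = None,
    weights: Mapping[str, float] | None = None,
) -> CleanedComposite:
    """Clean each selected channel and blend them additively into RGB.

    Each cleaned channel contributes ``intensity/255 * color`` (scaled by
    its optional nonnegative weight) to the composite, which is clipped to
    unsigned-byte range.  Unselected channels contribute nothing.
    """
    if not selection:
        raise ValueError("selection must name at least one marker")
    unknown = [m for m in selection if m not in image.marker_names]
    if unknown:
        raise ValueError(
            f"unknown markers {unknown}; valid names: {image.marker_names}"
        )
    if weights is not None:
        bad = {m: w for m, w in weights.items() if w < 0}
        if bad:
            raise ValueError(f"negative channel weights: {bad}")

    params = params or CleanParams()
    full_palette = default_palette(image.marker_names)
    if palette:
        full_palette.update(palette)

    rows, cols = image.pixel_dims
    cleaned = np.zeros((len(selection), rows, cols), dtype=np.uint8)
    rgb = np.zeros((rows, cols, 3), dtype=np.float64)
    for i, marker in enumerate(selection):
        plane = image.channels[image.marker_names.index(marker)]
        chan = clean_channel(plane, params).astype(np.float64)
        if weights is not None:
            chan = np.clip(chan * weights.get(marker, 1.0), 0, 255)
        cleaned[i] = np.rint(chan).astype(np.uint8)
        color = np.asarray(full_palette[marker], dtype=np.float64)
        rgb += chan[:, :, np.newaxis] / 255.0 * color
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    return CleanedComposite(
        cleaned_channels=cleaned,
        selected_markers=list(selection),
        rgb=rgb,
        palette={m: full_palette[m] for m in selection},
        source_id=image.image_id,
    )
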