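"""Reading multichannel tissue images and cohort side-files.

Three TIFF-family container dialects are supported: plain multi-page TIFF,
OME-TIFF (channel names taken from the embedded OME-XML), and QPTIFF-style
pyramidal TIFF as produced by Vectra/CODEX instruments.  Every reader
normalises to a single in-memory type, :class:`MultiplexImage`, so the rest
of the pipeline is dialect-agnostic.  Metadata annotations and 2D embedding
coordinates arrive as small delimited text files, one table per annotation
category.
"""

from __future__ import annotations

import csv
import io
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

logger = logging.getLogger(__name__)

__all__ = [
    "MultiplexImage",
    "CohortMetadata",
    "CoordinateTable",
    "FormatError",
    "DimensionMismatchError",
    "read_multiplex",
    "read_metadata_dir",
    "read_coordinates",
    "write_coordinates",
    "save_png",
    "parse_color",
]

IMAGE_SUFFIXES = (".tif", ".tiff", ".qptiff")

#: Default ceiling on the longer edge when loading pyramidal containers.
DEFAULT_MAX_EDGE = 4096


class FormatError(ValueError):
    """Raised when a container cannot be read as the claimed dialect."""


class DimensionMismatchError(ValueError):
    """Raised when supplied marker names do not match the plane count."""


@dataclass
class MultiplexImage:
    """One multichannel image: a (channel, row, col) stack with marker labels."""

    channels: np.ndarray
    marker_names: list[str]
    source_format: str  # "tiff" | "ome-tiff" | "qptiff"
    image_id: str

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels)
        if self.channels.ndim == 2:
            self.channels = self.channels[np.newaxis]
        if self.channels.ndim != 3:
            raise DimensionMismatchError(
                f"expected (channel, row, col) stack, got shape {self.channels.shape}"
            )
        if len(self.marker_names) != self.channels.shape[0]:
            raise DimensionMismatchError(
                f"{len(self.marker_names)} marker names for "
                f"{self.channels.shape[0]} channel planes"
            )

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def pixel_dims(self) -> tuple[int, int]:
        return self.channels.shape[1], self.channels.shape[2]


@dataclass
class CohortMetadata:
    """Categorical annotations per image, grouped by category name.

    ``categories`` maps a category name (e.g. ``response``, ``treatment``,
    ``cluster``, ``patient``) to a per-image value map.  ``colors`` is an
    optional display-color map keyed by annotation value; values without an
    entry fall back to a categorical palette cycle at render time.
    """

    categories: dict[str, dict[str, str]] = field(default_factory=dict)
    colors: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def category_names(self) -> list[str]:
        return sorted(self.categories)

    def value_for(self, category: str, image_id: str) -> str | None:
        return self.categories.get(category, {}).get(image_id)

    def annotations_for(self, image_id: str) -> dict[str, str]:
        return {
            cat: values[image_id]
            for cat, values in sorted(self.categories.items())
            if image_id in values
        }


@dataclass
class CoordinateTable:
    """Per-image (x, y) pairs in embedding space (unitless)."""

    coords: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for image_id, (x, y) in self.coords.items():
            if not (np.isfinite(x) and np.isfinite(y)):
                raise ValueError(f"non-finite coordinate for image {image_id!r}")

    @property
    def image_ids(self) -> list[str]:
        return list(self.coords)

    def as_arrays(self, order: Sequence[str] | None = None) -> np.ndarray:
        ids = list(order) if order is not None else self.image_ids
        return np.array([self.coords[i] for i in ids], dtype=float)

    def __len__(self) -> int:
        return len(self.coords)


def _autogen_names(n: int) -> list[str]:
    return [f"ch{i:02d}" for i in range(n)]


def _ome_channel_names(xml_text: str) -> list[str]:
    """Channel names from OME-XML, namespace-agnostic, in document order."""
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError:
        return []
    names = []
    for elem in root.iter():
        if elem.tag.rsplit("}", 1)[-1] == "Channel":
            names.append(elem.get("Name") or "")
    return names if all(names) else []


def _select_pyramid_level(series, max_edge: int | None):
    """Highest-resolution level whose longer edge fits under ``max_edge``."""
    levels = getattr(series, "levels", None) or [series]
    if max_edge is None:
        return levels[0]
    for level in levels:  # levels are ordered full-res first
        rows, cols = level.shape[-2], level.shape[-1]
        if max(rows, cols) <= max_edge:
            return level
    return levels[-1]


def read_multiplex(
    path: str | Path,
    marker_names: Sequence[str] | None = None,
    pyramid_policy: int | None = DEFAULT_MAX_EDGE,
) -> MultiplexImage:
    """Read a plain TIFF, OME-TIFF, or QPTIFF container into a MultiplexImage.

    Marker-name precedence: embedded OME/QPTIFF channel metadata, then the
    supplied ``marker_names`` list, then autogenerated ``ch00..chNN``.
    ``pyramid_policy`` bounds the longer edge of the level loaded from
    pyramidal files (``None`` loads full resolution).  Pixel dtype is
    preserved as stored; conversion to unsigned byte happens downstream.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = "qptiff" if path.suffix.lower() == ".qptiff" else "tiff"
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            embedded: list[str] = []
            if tif.ome_metadata:
                if dialect != "qptiff":
                    dialect = "ome-tiff"
                embedded = _ome_channel_names(tif.ome_metadata)
            if getattr(series, "is_pyramidal", False) and dialect == "tiff":
                dialect = "qptiff"
            level = _select_pyramid_level(series, pyramid_policy)
            data = level.asarray()
    except (tifffile.TiffFileError, ValueError, OSError) as exc:
        raise FormatError(f"cannot read {path.name} as {dialect}: {exc}") from exc

    data = np.asarray(data)
    if data.ndim == 2:
        data = data[np.newaxis]
    data = data.reshape((-1,) + data.shape[-2:])

    n = data.shape[0]
    if embedded and len(embedded) == n:
        names = list(embedded)
    elif marker_names is not None:
        if len(marker_names) != n:
            raise DimensionMismatchError(
                f"{len(marker_names)} marker names supplied for {n} planes in {path.name}"
            )
        names = list(marker_names)
    else:
        names = _autogen_names(n)

    return MultiplexImage(
        channels=data,
        marker_names=names,
        source_format=dialect,
        image_id=image_id_from_path(path),
    )


def image_id_from_path(path: str | Path) -> str:
    """File basename without extension(s); ``a.ome.tif`` -> ``a``."""
    name = Path(path).name
    for suffix in (".ome.tif", ".ome.tiff"):
        if name.lower().endswith(suffix):
            return name[: -len(suffix)]
    return Path(name).stem


def _sniff_table(path: Path) -> pd.DataFrame:
    """Delimited table with a header row; comma or tab, sniffed."""
    sample = path.read_text()
    try:
        sep = csv.Sniffer().sniff(sample.splitlines()[0], delimiters=",\t;").delimiter
    except (csv.Error, IndexError):
        sep = ","
    return pd.read_csv(io.StringIO(sample), sep=sep, dtype=str)


def parse_color(text: str) -> tuple[int, int, int]:
    """Parse '#rrggbb' or a small set of CSS color names into an RGB triple."""
    named = {
        "black": "#000000", "white": "#ffffff", "red": "#ff0000",
        "green": "#008000", "blue": "#0000ff", "yellow": "#ffff00",
        "orange": "#ffa500", "purple": "#800080", "pink": "#ffc0cb",
        "gray": "#808080", "grey": "#808080", "cyan": "#00ffff",
        "magenta": "#ff00ff",
    }
    text = text.strip().lower()
    text = named.get(text, text)
    if not (text.startswith("#") and len(text) == 7):
        raise ValueError(f"unparseable color {text!r}")
    return tuple(int(text[i : i + 2], 16) for i in (1, 3, 5))  # type: ignore[return-value]


def read_metadata_dir(
    directory: str | Path,
    known_ids: Sequence[str] | None = None,
) -> CohortMetadata:
    """Merge one delimited table per annotation category into CohortMetadata.

    Each table (``<category>.csv``/``.tsv``) maps image_id to a value in its
    first two columns.  A file whose stem is ``colors`` instead maps
    annotation values to display colors.  Rows naming an image outside
    ``known_ids`` (when given) are skipped with a warning; for duplicate
    image ids within one table the last row wins.
    """
    directory = Path(directory)
    meta = CohortMetadata()
    if not directory.is_dir():
        return meta
    for path in sorted(directory.iterdir()):
        if path.suffix.lower() not in (".csv", ".tsv", ".txt") or not path.is_file():
            continue
        table = _sniff_table(path)
        if table.shape[1] < 2:
            logger.warning("metadata file %s has <2 columns; skipped", path.name)
            continue
        if path.stem.lower() == "colors":
            for value, color in zip(table.iloc[:, 0], table.iloc[:, 1]):
                try:
                    meta.colors[str(value)] = parse_color(str(color))
                except ValueError:
                    logger.warning("unparseable color %r in %s", color, path.name)
            continue
        category: dict[str, str] = {}
        for _, row in table.iterrows():
            image_id, value = str(row.iloc[0]), str(row.iloc[1])
            if known_ids is not None and image_id not in known_ids:
                logger.warning(
                    "metadata row for unknown image %r in %s skipped",
                    image_id, path.name,
                )
                continue
            if image_id in category:
                logger.warning(
                    "duplicate image id %r in %s; keeping last value",
                    image_id, path.name,
                )
            category[image_id] = value
        meta.categories[path.stem] = category
    return meta


#: Decimal places preserved by the coordinate round-trip.
COORD_PRECISION = 6


def read_coordinates(path: str | Path) -> CoordinateTable:
    """Read a delimited file with image_id, x, y columns."""
    path = Path(path)
    table = _sniff_table(path)
    if table.shape[1] < 3:
        raise ValueError(f"{path.name}: expected image_id, x, y columns")
    coords: dict[str, tuple[float, float]] = {}
    for idx, row in table.iterrows():
        image_id = str(row.iloc[0])
        try:
            x, y = float(row.iloc[1]), float(row.iloc[2])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path.name} row {idx}: unparseable coordinate") from exc
        if not (np.isfinite(x) and np.isfinite(y)):
            raise ValueError(
                f"{path.name} row {idx} (image {image_id!r}): non-finite coordinate"
            )
        coords[image_id] = (x, y)
    return CoordinateTable(coords)


def write_coordinates(table: CoordinateTable, path: str | Path) -> Path:
    """Write a CoordinateTable in the same dialect :func:`read_coordinates` reads."""
    path = Path(path)
    frame = pd.DataFrame(
        [
            (i, round(x, COORD_PRECISION), round(y, COORD_PRECISION))
            for i, (x, y) in table.coords.items()
        ],
        columns=["image_id", "x", "y"],
    )
    frame.to_csv(path, index=False)
    return path


def save_png(rgb: np.ndarray, path: str | Path) -> Path:
    """Write an (rows, cols, 3) unsigned-byte raster as PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.asarray(rgb, dtype=np.uint8)).save(path, format="PNG")
    return path
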