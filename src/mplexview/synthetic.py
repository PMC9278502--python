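"""Synthetic multiplexed-cohort generation.

Fabricates everything the pipeline consumes — multichannel TIFF/OME-TIFF/
QPTIFF images, metadata tables, coordinate files — so the package is fully
testable without downloaded data.  Images emulate immunofluorescence
fields of view: a dark background, compact bright Gaussian blobs standing
in for stained cells (count and amplitude set per group and channel), and
additive sensor noise.  Group contrast is parameterised in pooled-SD units
of the per-image channel mean, which makes cluster-recovery experiments
well-posed: within-group spread comes from a per-image amplitude jitter,
so the expected separation between groups on a contrast channel is
``|amp_a − amp_b| / (mean_amp · jitter)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .io_formats import MultiplexImage

__all__ = [
    "CohortRecipe",
    "two_group_recipe",
    "generate_image",
    "generate_cohort",
    "write_tiff",
    "write_ome_tiff",
    "write_qptiff",
]


@dataclass
class CohortRecipe:
    """Parameters of a synthetic cohort.

    ``group_channel_amps`` has one row per group and one column per
    channel: the nominal peak amplitude of that group's blobs on that
    channel.  ``amp_jitter`` is the relative SD of the per-image amplitude
    multiplier, the sole source of within-group channel-mean spread (blob
    centers are kept clear of the border so no signal is clipped away).
    """

    n_images: int = 12
    n_channels: int = 7
    image_dims: tuple[int, int] = (336, 252)  # Vectra-style FoV at 1/4 scale
    n_groups: int = 2
    group_channel_amps: np.ndarray | None = None
    blobs_per_channel: int = 12
    blob_sigma: float = 6.0
    background: float = 8.0
    noise_sd: float = 3.0
    amp_jitter: float = 0.05
    seed: int = 42

    def __post_init__(self) -> None:
        if self.group_channel_amps is None:
            self.group_channel_amps = np.full(
                (self.n_groups, self.n_channels), 150.0
            )
        self.group_channel_amps = np.asarray(self.group_channel_amps, dtype=float)
        if self.group_channel_amps.shape != (self.n_groups, self.n_channels):
            raise ValueError("group_channel_amps must be (n_groups, n_channels)")

    def expected_separation(self, channel: int, group_a: int, group_b: int) -> float:
        """Group separation on one channel, in pooled-SD units of the mean."""
        a = self.group_channel_amps[group_a, channel]
        b = self.group_channel_amps[group_b, channel]
        pooled = (a + b) / 2.0 * self.amp_jitter
        return abs(a - b) / pooled if pooled > 0 else np.inf


def two_group_recipe(
    separation_sd: float = 5.0,
    n_images: int = 12,
    n_channels: int = 7,
    image_dims: tuple[int, int] = (336, 252),
    base_amp: float = 150.0,
    amp_jitter: float = 0.05,
    seed: int = 42,
    **kwargs,
) -> CohortRecipe:
    """Two-group recipe with a stated channel-mean separation.

    Group A is brighter on channel 1 and group B on channel 2, each by the
    amount that makes the between-group distance on that channel equal to
    ``separation_sd`` pooled standard deviations.
    """
    delta = separation_sd * amp_jitter * base_amp / 2.0
    amps = np.full((2, n_channels), base_amp)
    amps[0, 1 % n_channels] = base_amp + delta
    amps[1, 1 % n_channels] = base_amp - delta
    amps[0, 2 % n_channels] = base_amp - delta
    amps[1, 2 % n_channels] = base_amp + delta
    return CohortRecipe(
        n_images=n_images,
        n_channels=n_channels,
        image_dims=image_dims,
        n_groups=2,
        group_channel_amps=amps,
        amp_jitter=amp_jitter,
        seed=seed,
        **kwargs,
    )


def _add_blob(plane: np.ndarray, cy: float, cx: float, sigma: float, amp: float) -> None:
    """Add one Gaussian-profile spot in place (3-sigma patch)."""
    rows, cols = plane.shape
    rad = int(np.ceil(3 * sigma))
    y0, y1 = max(int(cy) - rad, 0), min(int(cy) + rad + 1, rows)
    x0, x1 = max(int(cx) - rad, 0), min(int(cx) + rad + 1, cols)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    plane[y0:y1, x0:x1] += amp * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)
    )


def generate_image(
    recipe: CohortRecipe,
    group: int,
    seed: int,
    image_id: str = "synthetic",
) -> MultiplexImage:
    """One synthetic multichannel image for the given group; seeded.

    Each channel is dark background + ``blobs_per_channel`` Gaussian blobs
    whose common amplitude is the group's nominal amplitude times a
    per-channel jitter multiplier, plus additive Gaussian noise, clipped
    to unsigned-byte range.
    """
    if not 0 <= group < recipe.n_groups:
        raise ValueError(f"group must be in [0, {recipe.n_groups})")
    rng = np.random.default_rng(seed)
    rows, cols = recipe.image_dims
    margin = 3 * recipe.blob_sigma
    stack = np.empty((recipe.n_channels, rows, cols), dtype=np.uint8)
    for c in range(recipe.n_channels):
        plane = np.full((rows, cols), recipe.background, dtype=np.float64)
        amp = recipe.group_channel_amps[group, c] * max(
            1.0 + rng.normal(0.0, recipe.amp_jitter), 0.1
        )
        # keep blobs fully interior so the per-channel mean tracks amplitude;
        # tiny images fall back to center placement
        ylo, yhi = (margin, rows - margin) if rows > 2 * margin else (rows / 2, rows / 2)
        xlo, xhi = (margin, cols - margin) if cols > 2 * margin else (cols / 2, cols / 2)
        for _ in range(recipe.blobs_per_channel):
            cy = rng.uniform(ylo, yhi)
            cx = rng.uniform(xlo, xhi)
            _add_blob(plane, cy, cx, recipe.blob_sigma, amp)
        if recipe.noise_sd > 0:
            plane += rng.normal(0.0, recipe.noise_sd, size=plane.shape)
        stack[c] = np.clip(np.rint(plane), 0, 255).astype(np.uint8)
    return MultiplexImage(
        channels=stack,
        marker_names=[f"ch{i:02d}" for i in range(recipe.n_channels)],
        source_format="tiff",
        image_id=image_id,
    )


def write_tiff(path: str | Path, channels: np.ndarray) -> Path:
    """Plain multi-page TIFF, one page per channel."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(channels), photometric="minisblack")
    return path


def write_ome_tiff(
    path: str | Path, channels: np.ndarray, marker_names: Sequence[str]
) -> Path:
    """OME-TIFF with channel names embedded in the OME-XML."""
    path = Path(path)
    tifffile.imwrite(
        path,
        np.asarray(channels),
        ome=True,
        photometric="minisblack",
        metadata={"axes": "CYX", "Channel": {"Name": list(marker_names)}},
    )
    return path


def write_qptiff(
    path: str | Path, channels: np.ndarray, n_levels: int = 2
) -> Path:
    """Pyramidal multiplex TIFF (Vectra-compatible layout) with sub-levels."""
    path = Path(path)
    data = np.asarray(channels)
    with tifffile.TiffWriter(path) as writer:
        writer.write(data, subifds=n_levels, photometric="minisblack")
        level = data
        for _ in range(n_levels):
            level = level[:, ::2, ::2]
            writer.write(level, subfiletype=1, photometric="minisblack")
    return path


def generate_cohort(
    recipe: CohortRecipe,
    out_dir: str | Path,
    image_format: str = "tiff",
    with_coords: bool = False,
) -> dict:
    """Write a full synthetic cohort in the directory layout the readers expect.

    Layout: ``images/`` with one container per image (balanced across
    groups, round-robin), ``metadata/group.csv`` and ``metadata/patient.csv``
    annotation tables, and optionally ``coordinates.csv`` with random 2D
    embedding coordinates.  Returns a manifest with paths and the true
    group of every image.
    """
    if image_format not in ("tiff", "ome-tiff", "qptiff"):
        raise ValueError(f"unknown image_format {image_format!r}")
    out_dir = Path(out_dir)
    images_dir = out_dir / "images"
    metadata_dir = out_dir / "metadata"
    images_dir.mkdir(parents=True, exist_ok=True)
    metadata_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(recipe.seed)
    suffix = {"tiff": ".tif", "ome-tiff": ".ome.tif", "qptiff": ".qptiff"}[image_format]
    manifest: dict = {
        "images_dir": images_dir,
        "metadata_dir": metadata_dir,
        "image_paths": [],
        "groups": {},
        "coords_file": None,
    }
    rows_group, rows_patient = [], []
    for i in range(recipe.n_images):
        group = i % recipe.n_groups
        image_id = f"img{i:03d}"
        img = generate_image(
            recipe, group, seed=int(rng.integers(0, 2**31 - 1)), image_id=image_id
        )
        path = images_dir / f"{image_id}{suffix}"
        if image_format == "tiff":
            write_tiff(path, img.channels)
        elif image_format == "ome-tiff":
            write_ome_tiff(path, img.channels, img.marker_names)
        else:
            write_qptiff(path, img.channels)
        manifest["image_paths"].append(path)
        manifest["groups"][image_id] = group
        rows_group.append((image_id, f"group{group}"))
        rows_patient.append((image_id, f"P{i % max(recipe.n_images // 3, 1)}"))

    pd.DataFrame(rows_group, columns=["image_id", "value"]).to_csv(
        metadata_dir / "group.csv", index=False
    )
    pd.DataFrame(rows_patient, columns=["image_id", "value"]).to_csv(
        metadata_dir / "patient.csv", index=False
    )
    if with_coords:
        coords = pd.DataFrame(
            {
                "image_id": [f"img{i:03d}" for i in range(recipe.n_images)],
                "x": np.round(rng.uniform(-40, 40, recipe.n_images), 4),
                "y": np.round(rng.uniform(-40, 40, recipe.n_images), 4),
            }
        )
        coords_path = out_dir / "coordinates.csv"
        coords.to_csv(coords_path, index=False)
        manifest["coords_file"] = coords_path
    return manifest
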