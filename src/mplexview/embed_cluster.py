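"""Inbuilt dimensionality reduction and Bayesian clustering.

When the user supplies neither embedding coordinates nor cluster labels,
the cohort is embedded and clustered from scratch: each multiplexed image
is abstracted to a vector of length 6 holding the means of its initial six
channels (raw, pre-cleaning intensities), the stacked vectors are embedded
in 2D with t-SNE, and the feature matrix is clustered with a variational
Bayesian Gaussian mixture whose stick-breaking prior prunes unused
components.  The generated coordinates and labels are written back in the
same delimited dialect the coordinate/metadata readers consume, so a
fallback run is reproducible as a pure coordinate-mode run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE
from sklearn.mixture import BayesianGaussianMixture

from .io_formats import CoordinateTable, MultiplexImage, write_coordinates

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "EmbeddingResult",
    "image_feature_vector",
    "build_feature_matrix",
    "embed_2d",
    "cluster_vbgmm",
    "run_fallback",
    "N_FEATURES",
]

#: Every image is abstracted to the means of its initial six channels.
N_FEATURES = 6


@dataclass
class FeatureMatrix:
    """One 6-vector of initial-channel means per cohort image."""

    values: np.ndarray  # (n_images, 6) float
    row_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_FEATURES:
            raise ValueError(f"feature matrix must have {N_FEATURES} columns")
        if self.values.shape[0] != len(self.row_ids):
            raise ValueError("one row per image id required")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]


@dataclass
class EmbeddingResult:
    """2D coordinates plus mixture-model cluster labels for a cohort."""

    coords: CoordinateTable
    labels: dict[str, int]
    n_components_used: int
    seed: int


def image_feature_vector(image: MultiplexImage) -> np.ndarray:
    """Arithmetic means of channels 0-5, in stored plane order.

    Raw (uncleaned) intensities are used.  Images with fewer than six
    channels are zero-padded with a warning so the cohort matrix stays
    rectangular; any channels beyond the sixth are ignored.
    """
    n = min(image.n_channels, N_FEATURES)
    vec = np.zeros(N_FEATURES, dtype=float)
    vec[:n] = image.channels[:n].reshape(n, -1).mean(axis=1)
    if image.n_channels < N_FEATURES:
        logger.warning(
            "image %s has %d channels (<%d); feature vector zero-padded",
            image.image_id, image.n_channels, N_FEATURES,
        )
    return vec


def build_feature_matrix(images: Sequence[MultiplexImage]) -> FeatureMatrix:
    """Stack per-image feature vectors in cohort order."""
    return FeatureMatrix(
        values=np.array([image_feature_vector(img) for img in images]).reshape(
            -1, N_FEATURES
        ),
        row_ids=[img.image_id for img in images],
    )


def embed_2d(
    matrix: FeatureMatrix,
    perplexity: float | None = None,
    seed: int = 42,
) -> CoordinateTable:
    """t-SNE embedding of the feature matrix into 2D; seeded, deterministic.

    Default perplexity is ``min(30, (n − 1) / 3)``; a requested perplexity
    too large for the cohort is auto-reduced with a warning.  Requires at
    least 3 rows.
    """
    n = matrix.n_rows
    if n < 3:
        raise ValueError("t-SNE embedding requires at least 3 images")
    limit = (n - 1) / 3.0
    if perplexity is None:
        perplexity = min(30.0, limit)
    elif perplexity >= n:
        reduced = max(2.0, limit)
        logger.warning(
            "perplexity %g >= n_rows %d; reduced to %g", perplexity, n, reduced
        )
        perplexity = reduced
    perplexity = max(perplexity, 1.0)
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    xy = tsne.fit_transform(matrix.values)
    return CoordinateTable(
        {rid: (float(x), float(y)) for rid, (x, y) in zip(matrix.row_ids, xy)}
    )


def cluster_vbgmm(
    matrix: FeatureMatrix,
    max_components: int = 10,
    seed: int = 42,
) -> dict[str, int]:
    """Variational Bayesian Gaussian-mixture labels for the feature matrix.

    A Dirichlet-process (stick-breaking) weight prior lets the fit prune
    to fewer effective components than ``max_components``; each row gets
    its most-probable component.  Component variances are floored
    (``reg_covar``) at half the mean per-feature cohort variance — a
    scale-free smoothing that stops tight, well-separated groups from
    being shredded into micro-components on small cohorts while leaving
    between-group structure, which dominates the total variance, intact.
    A degenerate fit falls back to a single cluster with a warning.
    """
    n = matrix.n_rows
    if n < 2:
        raise ValueError("clustering requires at least 2 images")
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    n_components = min(max_components, n)
    reg_covar = max(0.5 * float(matrix.values.var(axis=0).mean()), 1e-6)
    try:
        gmm = BayesianGaussianMixture(
            n_components=n_components,
            weight_concentration_prior_type="dirichlet_process",
            covariance_type="full",
            reg_covar=reg_covar,
            max_iter=500,
            random_state=seed,
        )
        labels = gmm.fit_predict(matrix.values)
    except ValueError as exc:
        logger.warning("mixture fit degenerate (%s); single cluster assigned", exc)
        labels = np.zeros(n, dtype=int)
    return {rid: int(lab) for rid, lab in zip(matrix.row_ids, labels)}


def run_fallback(
    images: Sequence[MultiplexImage],
    seed: int = 42,
    max_components: int = 10,
    perplexity: float | None = None,
    out_dir: str | Path | None = None,
) -> EmbeddingResult:
    """Full inbuilt pipeline: features -> t-SNE coords -> mixture labels.

    When ``out_dir`` is given the coordinates are written as
    ``generated_coordinates.csv`` and the labels as a ``cluster`` metadata
    table, both in the dialect the readers consume.
    """
    matrix = build_feature_matrix(images)
    coords = embed_2d(matrix, perplexity=perplexity, seed=seed)
    labels = cluster_vbgmm(matrix, max_components=max_components, seed=seed)
    result = EmbeddingResult(
        coords=coords,
        labels=labels,
        n_components_used=len(set(labels.values())),
        seed=seed,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_coordinates(coords, out_dir / "generated_coordinates.csv")
        pd.DataFrame(
            [(rid, f"c{lab}") for rid, lab in labels.items()],
            columns=["image_id", "value"],
        ).to_csv(out_dir / "cluster.csv", index=False)
    return result
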