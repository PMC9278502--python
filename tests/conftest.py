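import numpy as np
import pytest

from mplexview import synthetic


@pytest.fixture()
def small_recipe():
    """Fast 7-channel Vectra-style recipe for unit tests."""
    return synthetic.two_group_recipe(n_images=6, image_dims=(96, 72), seed=11)


@pytest.fixture()
def small_image(small_recipe):
    return synthetic.generate_image(small_recipe, group=0, seed=11, image_id="img000")


@pytest.fixture()
def blob_channel(small_image):
    """One channel with compact bright blobs on a dark background."""
    return small_image.channels[1]


@pytest.fixture()
def cohort_dir(tmp_path, small_recipe):
    """A written 6-image, 2-group cohort with metadata and coordinates."""
    return synthetic.generate_cohort(small_recipe, tmp_path / "cohort", with_coords=True)


def min_pairwise_distance(points):
    pts = np.asarray(points, dtype=float)
    best = np.inf
    for i in range(len(pts)):
        d = np.hypot(pts[i + 1 :, 0] - pts[i, 0], pts[i + 1 :, 1] - pts[i, 1])
        if len(d):
            best = min(best, d.min())
    return best


def rectangles_overlap(pos_a, pos_b, tile_dims):
    """Axis-aligned overlap test for two equally sized tiles."""
    h, w = tile_dims
    ax, ay = pos_a
    bx, by = pos_b
    return ax < bx + w and bx < ax + w and ay < by + h and by < ay + h
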