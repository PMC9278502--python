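"""Static canvas compositing, stack montage, and the live HTML scatter."""

import json
import re

import numpy as np
import pytest

from mplexview.io_formats import CohortMetadata, CoordinateTable, MultiplexImage
from mplexview.layout import LayoutResult
from mplexview.render import (
    CanvasSpec,
    THEMES,
    build_live_scatter,
    make_hover_records,
    render_static_canvas,
    stack_montage,
)
from mplexview.thumbnail import Thumbnail


def _tile(value, source_id, size=(100, 100)):
    return Thumbnail(
        rgb_tile=np.full(size + (3,), value, dtype=np.uint8), source_id=source_id
    )


def _spec(thumbs, positions, theme="black", canvas=(400, 400), order=None):
    layout = LayoutResult(
        mode="grid",
        positions=positions,
        render_order=order or list(positions),
        canvas_dims=canvas,
    )
    return CanvasSpec(theme=theme, layout=layout, thumbnails=thumbs)


class TestStaticCanvas:
    def test_empty_cohort_pure_background(self):
        canvas = render_static_canvas(_spec([], {}, theme="dark_blue"))
        assert canvas.shape == (400, 400, 3)
        assert (canvas == THEMES["dark_blue"]).all()

    def test_single_tile_occupies_exactly_its_rectangle(self):
        canvas = render_static_canvas(
            _spec([_tile(200, "a")], {"a": (50, 50)}, theme="black")
        )
        non_bg = (canvas != 0).any(axis=2)
        assert non_bg[50:150, 50:150].all()
        assert non_bg.sum() == 100 * 100

    def test_overlapping_tiles_later_wins(self):
        thumbs = [_tile(60, "under"), _tile(220, "over")]
        canvas = render_static_canvas(
            _spec(
                thumbs,
                {"under": (10, 10), "over": (10, 10)},
                order=["under", "over"],
            )
        )
        assert (canvas[10:110, 10:110] == 220).all()
        flipped = render_static_canvas(
            _spec(
                thumbs,
                {"under": (10, 10), "over": (10, 10)},
                order=["over", "under"],
            )
        )
        assert (flipped[10:110, 10:110] == 60).all()

    def test_nonoverlapping_render_conserves_tile_pixels(self):
        thumbs = [_tile(v, f"i{k}", (50, 50)) for k, v in enumerate((10, 20, 30))]
        positions = {"i0": (0, 0), "i1": (100, 0), "i2": (200, 100)}
        canvas = render_static_canvas(_spec(thumbs, positions))
        assert canvas.sum() == sum(t.rgb_tile.sum() for t in thumbs)

    def test_out_of_bounds_tile_rejected(self):
        with pytest.raises(ValueError):
            render_static_canvas(_spec([_tile(9, "a")], {"a": (350, 350)}))

    def test_theme_hex_values(self):
        assert THEMES["black"] == (0, 0, 0)
        assert THEMES["gray"] == (64, 64, 64)
        assert THEMES["dark_blue"] == (11, 11, 69)

    def test_byte_identical_png_for_same_inputs(self, tmp_path):
        spec = _spec([_tile(99, "a")], {"a": (0, 0)})
        render_static_canvas(spec, tmp_path / "one.png")
        render_static_canvas(spec, tmp_path / "two.png")
        assert (tmp_path / "one.png").read_bytes() == (tmp_path / "two.png").read_bytes()


def _multichannel_image(n_channels):
    rng = np.random.default_rng(1)
    channels = np.zeros((n_channels, 64, 48), dtype=np.uint8)
    for c in range(n_channels):
        r0, c0 = rng.integers(4, 30), rng.integers(4, 20)
        channels[c, r0 : r0 + 10, c0 : c0 + 10] = 180
    return MultiplexImage(
        channels=channels,
        marker_names=[f"marker{c:02d}" for c in range(n_channels)],
        source_format="tiff",
        image_id="stack",
    )


class TestStackMontage:
    def test_44_channel_image_yields_44_labelled_tiles(self):
        image = _multichannel_image(44)
        spec = stack_montage(image, tile_edge=32)
        assert len(spec.thumbnails) == 44
        for thumb, marker in zip(spec.thumbnails, image.marker_names):
            assert marker in thumb.source_id
        canvas = render_static_canvas(spec)
        assert canvas.shape[0] > 0

    def test_single_channel_image_single_tile(self):
        spec = stack_montage(_multichannel_image(1), tile_edge=32)
        assert len(spec.thumbnails) == 1

    def test_tile_order_matches_channel_order(self):
        image = _multichannel_image(6)
        spec = stack_montage(image, tile_edge=32)
        ids = [t.source_id for t in spec.thumbnails]
        assert ids == sorted(ids, key=lambda s: int(s.split("_")[1]))
        assert spec.layout.render_order == ids


def _extract_data(html):
    payload = re.search(r"const DATA = (\{.*?\});\n", html, re.S).group(1)
    return json.loads(payload)


class TestLiveScatter:
    def test_two_value_category_two_colors_and_legend(self):
        coords = CoordinateTable({f"i{k}": (float(k), float(k % 3)) for k in range(6)})
        meta = CohortMetadata(
            categories={
                "response": {
                    f"i{k}": "Response 1" if k < 3 else "Response 2"
                    for k in range(6)
                }
            }
        )
        html = build_live_scatter(coords, meta)
        data = _extract_data(html)
        assert len(data["points"]) == 6
        assert data["categories"] == ["response"]
        assert len(data["colors"]["response"]) == 2

    def test_no_metadata_single_uncolored_scatter(self):
        coords = CoordinateTable({"a": (0.0, 0.0), "b": (1.0, 2.0)})
        data = _extract_data(build_live_scatter(coords))
        assert data["categories"] == []
        assert len(data["points"]) == 2

    def test_hover_record_reproduces_source_values_exactly(self):
        coords = CoordinateTable({"img007": (3.25, -1.5)})
        meta = CohortMetadata(categories={"patient": {"img007": "P2"}})
        records = make_hover_records(coords, meta, {"img007": "img007.png"})
        assert records[0].image_id == "img007"
        assert records[0].thumbnail_name == "img007.png"
        assert (records[0].x, records[0].y) == (3.25, -1.5)
        assert records[0].metadata == {"patient": "P2"}
        data = _extract_data(build_live_scatter(coords, meta))
        point = data["points"][0]
        assert point["image"] == "img007"
        assert point["thumbnail"] == "img007.png"
        assert point["x"] == 3.25 and point["y"] == -1.5
        assert point["meta"] == {"patient": "P2"}

    def test_plot_tools_present_in_document(self, tmp_path):
        coords = CoordinateTable({"a": (0.0, 0.0), "b": (1.0, 1.0)})
        out = tmp_path / "live.html"
        html = build_live_scatter(coords, out_path=out)
        assert out.read_text() == html
        for tool in ("wheel", "mousedown", "reset", "save", "viewBox", "tooltip"):
            assert tool in html

    def test_user_color_map_respected(self):
        coords = CoordinateTable({"a": (0.0, 0.0), "b": (1.0, 1.0)})
        meta = CohortMetadata(
            categories={"response": {"a": "R1", "b": "R2"}},
            colors={"R1": (255, 255, 0)},
        )
        data = _extract_data(build_live_scatter(coords, meta))
        assert data["colors"]["response"]["R1"] == "#ffff00"
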