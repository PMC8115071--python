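import numpy as np
import pandas as pd
import pytest

from oxprof import panel
from oxprof.errors import (
    DataError,
    EmptyCytoplasmError,
    FormatError,
    GeometryError,
)
from oxprof.imaging import (
    ImageStack,
    PanelEntry,
    RoiPolygon,
    cytoplasmic_mean,
    default_panel,
    extract_neuron_table,
    rasterize_roi,
    read_rois,
    read_stack,
    render_image,
    write_rois,
    write_stack,
)
from oxprof.synthetic import plan_geometry, simulate_cohort
from tests.conftest import make_config
from oxprof.synthetic import GroupSpec


def point_in_polygon(px, py, vertices):
    """Independent even-odd ray-casting oracle."""
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_cross:
                inside = not inside
    return inside


def small_stack(channel_arrays: dict[str, np.ndarray]) -> ImageStack:
    targets = list(channel_arrays)
    entries = [PanelEntry(i, "tag", t, panel.ROLE_BY_TARGET.get(t, "oxphos_subunit"))
               for i, t in enumerate(targets)]
    pixels = np.stack([channel_arrays[t] for t in targets]).astype(np.float32)
    return ImageStack(pixels=pixels, panel=entries)


class TestStackIO:
    def test_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        stack = ImageStack(
            pixels=rng.uniform(0, 50, size=(12, 16, 16)).astype(np.float32),
            panel=default_panel(),
        )
        img, pan = tmp_path / "stack.tiff", tmp_path / "panel.csv"
        write_stack(stack, img, pan)
        loaded = read_stack(img, pan)
        np.testing.assert_array_equal(loaded.pixels, stack.pixels)
        assert loaded.targets == stack.targets

    def test_channel_count_mismatch(self, tmp_path):
        stack = ImageStack(
            pixels=np.zeros((12, 8, 8), dtype=np.float32), panel=default_panel()
        )
        img, pan = tmp_path / "s.tiff", tmp_path / "p.csv"
        write_stack(stack, img, pan)
        short = pd.read_csv(pan).iloc[:11]
        pan2 = tmp_path / "p11.csv"
        short.to_csv(pan2, index=False)
        with pytest.raises(FormatError):
            read_stack(img, pan2)

    def test_negative_intensities_rejected(self):
        with pytest.raises(FormatError):
            ImageStack(pixels=-np.ones((12, 4, 4)), panel=default_panel())

    def test_panel_mismatch_in_constructor(self):
        with pytest.raises(FormatError):
            ImageStack(pixels=np.zeros((3, 4, 4)), panel=default_panel())


class TestRasterize:
    def test_axis_aligned_square(self):
        roi = RoiPolygon(
            "n0", "c0",
            np.array([[0.5, 0.5], [3.5, 0.5], [3.5, 3.5], [0.5, 3.5]]),
        )
        mask = rasterize_roi(roi, (6, 6))
        expected = np.zeros((6, 6), dtype=bool)
        expected[1:4, 1:4] = True
        np.testing.assert_array_equal(mask, expected)

    def test_degenerate_polygon(self):
        with pytest.raises(GeometryError):
            RoiPolygon("n0", "c0", np.array([[0, 0], [1, 1], [2, 2]]))

    def test_full_image_polygon(self):
        h, w = 5, 7
        roi = RoiPolygon(
            "n0", "c0",
            np.array([[-0.5, -0.5], [w - 0.5, -0.5], [w - 0.5, h - 0.5], [-0.5, h - 0.5]]),
        )
        assert rasterize_roi(roi, (h, w)).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_ray_casting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # random star-shaped polygon with half-integer-free vertices
        theta = np.sort(rng.uniform(0, 2 * np.pi, 7))
        r = rng.uniform(2.0, 6.0, 7)
        verts = np.column_stack(
            [8.13 + r * np.cos(theta), 8.27 + r * np.sin(theta)]
        )
        roi = RoiPolygon("n0", "c0", verts)
        mask = rasterize_roi(roi, (16, 16))
        for row in range(16):
            for col in range(16):
                assert mask[row, col] == point_in_polygon(col, row, verts)


class TestCytoplasmicMean:
    def test_constant_image_no_exclusions(self):
        stack = small_stack({"NDUFB8": np.full((3, 3), 7.0)})
        mask = np.ones((3, 3), dtype=bool)
        means, n_total, n_cyto = cytoplasmic_mean(stack, mask, exclusion_targets=())
        assert means["NDUFB8"] == 7.0
        assert n_total == n_cyto == 9

    def test_hand_enumerated_2x2(self):
        # HistoneH3 [[6,0],[0,0]], target [[100,2],[4,6]], threshold 5
        stack = small_stack(
            {
                "NDUFB8": np.array([[100.0, 2.0], [4.0, 6.0]]),
                "HistoneH3": np.array([[6.0, 0.0], [0.0, 0.0]]),
            }
        )
        mask = np.ones((2, 2), dtype=bool)
        means, n_total, n_cyto = cytoplasmic_mean(
            stack, mask, exclusion_targets=("HistoneH3",), threshold=5.0
        )
        assert means["NDUFB8"] == pytest.approx(4.0)
        assert (n_total, n_cyto) == (4, 3)

    def test_all_excluded_raises(self):
        stack = small_stack(
            {"NDUFB8": np.ones((2, 2)), "HistoneH3": np.full((2, 2), 9.0)}
        )
        with pytest.raises(EmptyCytoplasmError):
            cytoplasmic_mean(stack, np.ones((2, 2), dtype=bool),
                             exclusion_targets=("HistoneH3",))

    def test_threshold_is_strict(self):
        # exactly == threshold is kept
        stack = small_stack(
            {"NDUFB8": np.array([[1.0, 3.0]]), "HistoneH3": np.array([[5.0, 5.0]])}
        )
        means, _, n_cyto = cytoplasmic_mean(
            stack, np.ones((1, 2), dtype=bool), exclusion_targets=("HistoneH3",)
        )
        assert n_cyto == 2
        assert means["NDUFB8"] == pytest.approx(2.0)

    def test_partition_invariant(self):
        rng = np.random.default_rng(5)
        stack = small_stack(
            {
                "NDUFB8": rng.uniform(0, 10, (8, 8)),
                "HistoneH3": rng.uniform(0, 10, (8, 8)),
            }
        )
        mask = rng.random((8, 8)) < 0.6
        mask[0, 0] = True
        excl = mask & (stack.channel("HistoneH3") > 5.0)
        if (mask & ~excl).sum() == 0:
            pytest.skip("all excluded for this draw")
        _, n_total, n_cyto = cytoplasmic_mean(
            stack, mask, exclusion_targets=("HistoneH3",)
        )
        assert n_cyto + int(excl.sum()) == n_total == int(mask.sum())


def _render_fixture(seed, n_cases=1, neurons=8, shape=(256, 256), noise_sd=0.0,
                    relative=False):
    cfg = make_config(seed, groups=[GroupSpec("control", n_cases, neurons, 0)])
    table, _ = simulate_cohort(cfg)
    cells = plan_geometry(table, shape, seed=seed)
    stack, rois = render_image(
        cells, table, shape, noise_sd=noise_sd, seed=seed, relative_noise=relative
    )
    return table, cells, stack, rois


class TestExtract:
    def test_noiseless_round_trip_exact(self):
        table, _, stack, rois = _render_fixture(2)
        meta = {c: ("control", 70.0) for c in table["case_id"].unique()}
        extracted, dropped = extract_neuron_table(stack, rois, meta)
        assert not dropped
        assert len(extracted) == len(table)
        merged = extracted.merge(table, on="neuron_id", suffixes=("_x", "_t"))
        for target in list(panel.SUBUNITS) + [panel.MASS_TARGET]:
            np.testing.assert_allclose(
                merged[f"{target}_x"], merged[f"{target}_t"], rtol=1e-5
            )

    def test_row_order_follows_rois(self):
        table, _, stack, rois = _render_fixture(3)
        meta = {c: ("control", 70.0) for c in table["case_id"].unique()}
        extracted, _ = extract_neuron_table(stack, rois[::-1], meta)
        assert list(extracted["neuron_id"]) == [r.neuron_id for r in rois[::-1]]

    def test_unknown_case_raises(self):
        table, _, stack, rois = _render_fixture(4)
        with pytest.raises(DataError):
            extract_neuron_table(stack, rois, {"bogus": ("control", 1.0)})

    def test_noisy_round_trip_within_3se(self):
        table, _, stack, rois = _render_fixture(5, neurons=10, noise_sd=0.1,
                                                relative=True)
        meta = {c: ("control", 70.0) for c in table["case_id"].unique()}
        extracted, _ = extract_neuron_table(stack, rois, meta)
        merged = extracted.merge(table, on="neuron_id", suffixes=("_x", "_t"))
        for target in [panel.MASS_TARGET, "NDUFB8"]:
            mean_t = merged[f"{target}_t"].to_numpy()
            se = 0.1 * mean_t / np.sqrt(merged["n_pixels_cytoplasm"].to_numpy())
            assert np.all(np.abs(merged[f"{target}_x"] - mean_t) < 3.5 * se)

    def test_render_determinism(self):
        _, _, s1, _ = _render_fixture(6, noise_sd=0.5)
        _, _, s2, _ = _render_fixture(6, noise_sd=0.5)
        np.testing.assert_array_equal(s1.pixels, s2.pixels)

    def test_fully_nuclear_roi_dropped(self):
        table, cells, stack, rois = _render_fixture(7)
        # paint the nuclear channel above threshold across one whole cell
        idx = {e.target: e.channel_index for e in stack.panel}
        mask = rasterize_roi(cells[0].polygon, stack.shape)
        stack.pixels[idx[panel.NUCLEAR_TARGET]][mask] = 50.0
        meta = {c: ("control", 70.0) for c in table["case_id"].unique()}
        extracted, dropped = extract_neuron_table(stack, rois, meta)
        assert len(extracted) == len(table) - 1
        assert dropped == [
            {"neuron_id": cells[0].neuron_id, "reason": "empty_cytoplasm"}
        ]

    def test_roi_geojson_round_trip(self, tmp_path):
        _, _, _, rois = _render_fixture(8)
        path = tmp_path / "rois.geojson"
        write_rois(rois, path)
        loaded = read_rois(path)
        assert [r.neuron_id for r in loaded] == [r.neuron_id for r in rois]
        for a, b in zip(loaded, rois):
            np.testing.assert_allclose(a.vertices, b.vertices)
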