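import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cortexmetrics as cm
from conftest import rasterize_disk, rasterize_mask
from cortexmetrics.synthetic_data import _regular_polygon
from oracle_geometry import (
    ellipse_perimeter_quadrature,
    regular_polygon_angularity_oracle,
)


class TestEllipsePerimeter:
    def test_circle_flat_and_two_to_one(self):
        assert cm.ellipse_perimeter(1.0, 1.0) == pytest.approx(2 * np.pi, rel=1e-12)
        assert cm.ellipse_perimeter(1.0, 0.0) == pytest.approx(4.0, rel=1e-12)
        # frozen value from the independent quadrature oracle
        assert ellipse_perimeter_quadrature(2.0, 1.0) == pytest.approx(9.688448,
                                                                       abs=1e-6)
        assert cm.ellipse_perimeter(2.0, 1.0) == pytest.approx(9.688448, abs=1e-6)

    def test_axis_validation(self):
        with pytest.raises(ValueError):
            cm.ellipse_perimeter(1.0, -0.1)
        with pytest.raises(ValueError):
            cm.ellipse_perimeter(1.0, 2.0)
        with pytest.raises(ValueError):
            cm.ellipse_perimeter(0.0, 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(a=st.floats(0.1, 50.0), ratio=st.floats(0.01, 1.0))
    def test_perimeter_bounds(self, a, ratio):
        b = a * ratio
        p = cm.ellipse_perimeter(a, b)
        assert 2 * np.pi * b <= p + 1e-9
        assert 4 * a - 1e-9 <= p <= 2 * np.pi * a + 1e-9


class TestAngularity:
    def test_rasterized_disk_is_one(self):
        s = cm.opening_shape(rasterize_disk(40), 1)
        assert s.angularity == pytest.approx(1.0, abs=0.02)
        assert s.area == pytest.approx(np.pi * 40 ** 2, rel=0.01)

    def test_hexagon_and_square_match_continuum_oracle(self):
        hex_meas = cm.opening_shape(
            rasterize_mask(_regular_polygon((0, 0), 40, 6), 200), 1).angularity
        sq_meas = cm.opening_shape(
            rasterize_mask(_regular_polygon((0, 0), 40, 4, 45), 200), 1).angularity
        assert hex_meas == pytest.approx(regular_polygon_angularity_oracle(6),
                                         rel=0.02)
        assert sq_meas == pytest.approx(regular_polygon_angularity_oracle(4),
                                        rel=0.02)

    def test_ordering_disk_hexagon_square_strict(self):
        disk = cm.opening_shape(rasterize_disk(40), 1).angularity
        hexa = cm.opening_shape(
            rasterize_mask(_regular_polygon((0, 0), 40, 6), 200), 1).angularity
        square = cm.opening_shape(
            rasterize_mask(_regular_polygon((0, 0), 40, 4, 45), 200), 1).angularity
        assert disk < hexa < square

    def test_rotation_invariance_within_one_percent(self):
        vals = [cm.opening_shape(
            rasterize_mask(_regular_polygon((0, 0), 40, 6, rot), 200), 1).angularity
            for rot in np.arange(0.0, 90.0, 7.5)]
        assert (max(vals) - min(vals)) / min(vals) < 0.01

    def test_scale_invariance_within_one_percent(self):
        a = cm.opening_shape(
            rasterize_mask(_regular_polygon((0, 0), 40, 6, 13), 200), 1).angularity
        b = cm.opening_shape(
            rasterize_mask(_regular_polygon((0, 0), 80, 6, 13), 300), 1).angularity
        assert abs(b - a) / a < 0.01

    def test_circle_limit_error_decays_monotonically(self):
        errs = [abs(cm.opening_shape(rasterize_disk(r), 1).angularity - 1.0)
                for r in (10, 20, 40, 80, 160, 200)]
        assert all(e2 < e1 for e1, e2 in zip(errs, errs[1:]))

    def test_missing_and_degenerate_labels(self):
        lab = rasterize_disk(10)
        with pytest.raises(KeyError):
            cm.opening_shape(lab, 99)
        tiny = cm.LabelImage(np.pad(np.ones((1, 1), np.int32), 3),
                             pixel_size_xy=1.0, border_excluded=False)
        with pytest.raises(ValueError, match="degenerate"):
            cm.opening_shape(tiny, 1)

    def test_border_flagged_label_excluded(self):
        arr = np.zeros((40, 40), np.int32)
        arr[0:10, 0:10] = 1  # truncated by the frame border
        arr[20:30, 20:30] = 2
        lab = cm.LabelImage(arr, pixel_size_xy=1.0, border_excluded=True,
                            border_labels=frozenset({1}))
        assert lab.label_ids == [2]
        with pytest.raises(ValueError, match="border"):
            cm.opening_shape(lab, 1)
        cm.opening_shape(lab, 2)  # interior label measurable

    def test_physical_units_scale_with_pixel_size(self):
        lab = rasterize_disk(40)
        half = cm.LabelImage(lab.labels, pixel_size_xy=0.5, border_excluded=False)
        s1, s2 = cm.opening_shape(lab, 1), cm.opening_shape(half, 1)
        assert s2.area == pytest.approx(s1.area / 4.0)
        assert s2.angularity == pytest.approx(s1.angularity, rel=1e-9)


def disk_map(radii_px, centers, size=120, px=0.2):
    from skimage.draw import disk as draw_disk

    img = np.zeros((size, size), np.int32)
    for i, (r, c) in enumerate(zip(radii_px, centers), start=1):
        rr, cc = draw_disk(c, r, shape=img.shape)
        img[rr, cc] = i
    return cm.LabelImage(img, pixel_size_xy=px, border_excluded=False)


class TestKinetics:
    def test_normalized_series_starts_at_one_and_is_flat_for_constant_scene(self):
        maps = [disk_map([20, 20], [(30, 30), (80, 80)])] * 3
        series = cm.area_series(maps, None, [0.0, 1.0, 2.0], normalize=True)
        np.testing.assert_allclose(series.value, 1.0)
        assert series.kind == "normalized_area"

    def test_mean_area_and_region_membership(self):
        maps = [disk_map([10, 20], [(30, 30), (80, 80)])]
        left = cm.area_series(maps, (0.0, 0.0, 24.0, 12.0), [0.0])
        both = cm.area_series(maps, None, [0.0])
        assert left.n_regions[0] == 1
        assert both.n_regions[0] == 2
        assert left.value[0] < both.value[0]

    def test_empty_region_at_t0_rejected(self):
        maps = [disk_map([10], [(30, 30)])]
        with pytest.raises(ValueError, match="no openings"):
            cm.area_series(maps, (20.0, 20.0, 23.0, 23.0), [0.0])

    def test_fold_change_identity_and_known_ratio(self):
        t = np.arange(4.0)
        x = cm.KineticsSeries(t, [13.0, 12.0, 11.0, 10.0], "mean_area")
        ident = cm.constriction_fold_change(x, x)
        np.testing.assert_allclose(ident.value, 1.0)
        at65 = cm.KineticsSeries(t, 0.65 * x.value, "mean_area")
        fold = cm.constriction_fold_change(x, at65)
        np.testing.assert_allclose(fold.value, 1.0 / 0.65)

    def test_fold_change_requires_matching_times_and_nonzero_area(self):
        x = cm.KineticsSeries([0.0, 1.0], [2.0, 2.0], "mean_area")
        y = cm.KineticsSeries([0.0, 2.0], [2.0, 2.0], "mean_area")
        with pytest.raises(ValueError, match="time"):
            cm.constriction_fold_change(x, y)
        z = cm.KineticsSeries([0.0, 1.0], [2.0, 0.0], "mean_area")
        with pytest.raises(ValueError, match="zero"):
            cm.constriction_fold_change(x, z)

    def test_constriction_rate_exact_on_linear_series(self):
        t = np.arange(0.0, 2.5, 0.5)
        series = cm.KineticsSeries(t, 13.0 - 0.65 * t, "mean_area")
        assert cm.constriction_rate(series, window=2.0) == pytest.approx(0.65)
        assert cm.constriction_rate(
            cm.KineticsSeries(t, np.full_like(t, 9.0), "mean_area"),
            2.0) == pytest.approx(0.0, abs=1e-12)

    def test_effective_diameter_mode(self):
        t = np.arange(0.0, 2.5, 0.5)
        areas = 13.0 - 0.65 * t
        series = cm.KineticsSeries(t, areas, "mean_area")
        expect = -np.polyfit(t, 2 * np.sqrt(areas / np.pi), 1)[0]
        assert cm.constriction_rate(series, 2.0, "effective_diameter") == \
            pytest.approx(expect)

    def test_rate_window_needs_two_samples(self):
        series = cm.KineticsSeries([0.0, 5.0], [13.0, 10.0], "mean_area")
        with pytest.raises(ValueError, match="2 samples"):
            cm.constriction_rate(series, window=1.0)


def myosin_stack(net_frame, gain=1.0, n_z=11, peak=6):
    weights = np.exp(-0.5 * ((np.arange(n_z) - peak) / 1.0) ** 2)
    stack = 0.1 + gain * net_frame[None] * weights[:, None, None]
    return cm.VoxelGrid(stack[None, :, :, :, None], pixel_size_xy=0.1, z_step=0.5)


class TestMyosinFoldChange:
    def test_known_intensity_gain_recovered(self, hex_scene, hex_labels):
        net = hex_scene[0].frame()
        pre = myosin_stack(net, 1.0)
        post = [myosin_stack(net, 1.2), myosin_stack(net, 1.5)]
        fold = cm.myosin_fold_change(pre, post, hex_labels)
        assert fold == pytest.approx(1.5, rel=0.02)

    def test_identity_when_post_equals_pre(self, hex_scene, hex_labels):
        pre = myosin_stack(hex_scene[0].frame(), 1.0)
        assert cm.myosin_fold_change(pre, [pre], hex_labels) == pytest.approx(1.0)

    def test_background_dominated_pre_stack_rejected(self, hex_scene, hex_labels):
        inverted_net = 1.05 - hex_scene[0].frame()  # openings brighter than fibers
        pre = myosin_stack(inverted_net, 1.0)
        with pytest.raises(ValueError, match="background"):
            cm.myosin_fold_change(pre, [pre], hex_labels)


class TestShapeVsDepth:
    def test_ring_phase_angularity_near_one_at_depth(self, small_config):
        ring_grid, _ = cm.make_network_frame("ring", n_cells=(3, 3), seed=0)
        ring_labels = cm.segment_openings(ring_grid, small_config)
        deep, _ = cm.make_embryo_zstack(10.5, seed=0)
        shallow, _ = cm.make_embryo_zstack(5.0, seed=0)
        hex_grid, _ = cm.make_network_frame("hexagonal", n_cells=(3, 3), seed=0)
        hex_labels = cm.segment_openings(hex_grid, small_config)
        table = cm.shape_vs_depth([(deep, ring_labels), (shallow, hex_labels)])
        assert table.depth_um.tolist() == [10.5, 5.0]
        assert table.mean_angularity[0] == pytest.approx(1.0, abs=0.03)
        assert table.mean_angularity[1] == pytest.approx(
            regular_polygon_angularity_oracle(6), rel=0.02)
        assert (table.n_openings == 9).all()

    def test_sample_without_openings_skipped_with_warning(self, caplog):
        stack, _ = cm.make_embryo_zstack(5.0, seed=0)
        empty = cm.LabelImage(np.zeros((32, 32), np.int32), pixel_size_xy=0.1)
        with caplog.at_level("WARNING", logger="cortexmetrics"):
            table = cm.shape_vs_depth([(stack, empty)])
        assert table.empty
        assert any("skipped" in r.message for r in caplog.records)
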