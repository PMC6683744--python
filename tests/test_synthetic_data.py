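import math

import numpy as np
import pytest

import cortexmetrics as cm
from oracle_geometry import polygon_angularity_oracle


class TestNetworkFrame:
    def test_truth_counts_and_equal_areas(self, hex_scene):
        _, truth = hex_scene
        assert len(truth.opening_centers) == 9
        areas = truth.true_areas[0]
        assert np.ptp(areas) < 1e-9 * areas[0]

    def test_ring_truth_angularity_is_one(self):
        _, truth = cm.make_network_frame("ring", n_cells=(3, 3), seed=0)
        assert all(a == 1.0 for a in truth.true_angularity)

    def test_truth_angularity_matches_independent_oracle(self, hex_scene):
        # analytic truth vs continuum oracle, to 1e-9
        _, truth = hex_scene
        pitch, fw = 8.0, 1.0
        apothem = (pitch - fw) / 2.0
        circum = apothem * 2.0 / math.sqrt(3.0)
        ang = np.deg2rad(90.0) + 2 * np.pi * np.arange(6) / 6
        verts = np.column_stack([circum * np.cos(ang), circum * np.sin(ang)])
        oracle = polygon_angularity_oracle(verts)
        assert truth.true_angularity[0] == pytest.approx(oracle, abs=1e-9)

    def test_seed_determinism_and_noise_only_stochasticity(self):
        noise = {"peak_photons": 100}
        g1, t1 = cm.make_network_frame("hexagonal", n_cells=(3, 3),
                                       noise_params=noise, seed=1)
        g1b, _ = cm.make_network_frame("hexagonal", n_cells=(3, 3),
                                       noise_params=noise, seed=1)
        g2, t2 = cm.make_network_frame("hexagonal", n_cells=(3, 3),
                                       noise_params=noise, seed=2)
        np.testing.assert_array_equal(g1.intensities, g1b.intensities)
        assert not np.array_equal(g1.intensities, g2.intensities)
        assert t1.opening_centers == t2.opening_centers
        assert t1.true_areas == t2.true_areas

    def test_noiseless_scene_is_exactly_analytic(self, hex_scene):
        grid, truth = hex_scene
        frame = grid.frame()
        cy, cx = truth.opening_centers[0]
        px = truth.params["pixel_size_xy"]
        assert frame[int(round(cy / px)), int(round(cx / px))] == 0.05
        assert frame[2, 2] == 1.0  # cortex margin

    def test_priming_has_no_openings(self):
        grid, truth = cm.make_network_frame("priming", seed=0)
        assert truth.opening_centers is None
        assert grid.frame().std() > 0

    def test_geometric_infeasibility_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            cm.make_network_frame("hexagonal", grid_pitch=2.0, fiber_width=1.2)
        with pytest.raises(ValueError, match="peak_photons"):
            cm.make_network_frame("hexagonal", n_cells=(3, 3),
                                  noise_params={"peak_photons": -1}, seed=0)

    def test_meshwork_openings_vary(self):
        _, truth = cm.make_network_frame("meshwork", n_cells=(3, 3), seed=5)
        assert np.ptp(truth.true_areas[0]) > 0
        assert all(a > 1.0 for a in truth.true_angularity)


class TestConstrictionMovie:
    def test_truth_slopes_by_region(self):
        _, truth = cm.make_constriction_movie(
            "ring", base_params={"n_cells": (4, 4)}, control_rate=0.0,
            activated_rate=0.65, n_frames=4, frame_interval=60.0, seed=0)
        areas = np.asarray(truth.true_areas)  # (frames, openings)
        t_min = np.arange(4) * 1.0
        y0, x0, y1, x1 = truth.activated_region
        for j, (cy, cx) in enumerate(truth.opening_centers):
            slope = np.polyfit(t_min, areas[:, j], 1)[0]
            expect = -0.65 if (y0 <= cy <= y1 and x0 <= cx <= x1) else 0.0
            assert slope == pytest.approx(expect, abs=1e-9)

    def test_equal_rates_give_unit_fold_change(self):
        _, truth = cm.make_constriction_movie(
            "ring", base_params={"n_cells": (4, 4)}, control_rate=0.3,
            activated_rate=0.3, n_frames=3, frame_interval=60.0, seed=0)
        areas = np.asarray(truth.true_areas)
        act = areas[:, :8].mean(axis=1)
        ctrl = areas[:, 8:].mean(axis=1)
        np.testing.assert_allclose(ctrl / act, 1.0)

    def test_collapse_before_last_frame_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cm.make_constriction_movie("ring", base_params={"n_cells": (4, 4)},
                                       activated_rate=5.0, n_frames=100,
                                       frame_interval=60.0, seed=0)


class TestEmbryoZstack:
    def test_noiseless_profile_peaks_at_planted_slice(self):
        grid, truth = cm.make_embryo_zstack(6.0, z_step=0.5, n_slices=30, seed=0)
        prof = grid.intensities[0, :, :, :, 0].mean(axis=(1, 2))
        interior = slice(4, None)
        assert 4 + int(np.argmax(prof[interior])) == 12
        assert truth.basal_depth == 6.0

    def test_staging_threshold_depth_recorded(self):
        _, truth = cm.make_embryo_zstack(4.0, seed=0)
        assert truth.basal_depth == 4.0

    def test_same_seed_identical_voxels(self):
        noise = {"peak_photons": 25}
        a, _ = cm.make_embryo_zstack(6.0, noise=noise, seed=3)
        b, _ = cm.make_embryo_zstack(6.0, noise=noise, seed=3)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_depth_outside_stack_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            cm.make_embryo_zstack(30.0, z_step=0.5, n_slices=30, seed=0)


class TestRecoilTracks:
    def test_closed_form_saturation_value(self):
        _, truth = cm.make_recoil_tracks(6.0, 3.0, noise_sd=0.0, seed=0)
        expect = 6.0 * (1.0 - math.exp(-125.0 / 3.0))
        assert truth.recoil["d_saturation"] == pytest.approx(expect, abs=1e-12)
        assert truth.recoil["d_saturation"] == pytest.approx(6.0, abs=1e-3)

    def test_noiseless_exact_curve_and_v0(self):
        table, truth = cm.make_recoil_tracks(6.0, 3.0, n_tracks=2,
                                             noise_sd=0.0, seed=0)
        assert truth.recoil["v0"] == 2.0
        one = table[table.track_id == 0]
        expect = 6.0 * (1.0 - np.exp(-one.time_s.to_numpy() / 3.0))
        np.testing.assert_allclose(one.displacement_um.to_numpy(), expect)

    def test_default_track_count_is_ten(self):
        table, _ = cm.make_recoil_tracks(6.0, 3.0, seed=0)
        assert table.track_id.nunique() == 10

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="tau"):
            cm.make_recoil_tracks(6.0, 0.0, seed=0)
        with pytest.raises(ValueError, match="include 0"):
            cm.make_recoil_tracks(6.0, 3.0, t_grid=[1.0, 200.0], seed=0)
        with pytest.raises(ValueError, match="saturation"):
            cm.make_recoil_tracks(6.0, 3.0, t_grid=[0.0, 10.0], seed=0)


class TestFiberImage:
    def test_zero_noise_is_deterministic(self):
        a, _ = cm.make_fiber_image([0.2], seed=1)
        b, _ = cm.make_fiber_image([0.2], seed=99)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_bar_width_in_pixels(self):
        grid, truth = cm.make_fiber_image([0.2], pixel_size_xy=0.015, seed=0)
        frame = grid.frame()
        row = int(truth.fibers["row_centers_um"][0] / 0.015)
        col = frame[:, frame.shape[1] // 2]
        assert np.sum(col > 0.5) == pytest.approx(0.2 / 0.015, abs=1.0)

    def test_reference_density_of_one(self):
        _, truth = cm.make_fiber_image([0.2], intensities=[1.0],
                                       reference_intensity=1.0, seed=0)
        assert truth.fibers["intensities"][0] / truth.fibers["reference_intensity"] == 1.0

    def test_sub_resolution_width_rejected(self):
        with pytest.raises(ValueError, match="below 2 px"):
            cm.make_fiber_image([0.02], pixel_size_xy=0.015, seed=0)

    def test_overlapping_fibers_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            cm.make_fiber_image([0.2, 0.2], angles_deg=[45.0, -45.0], seed=0)
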