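"""Generator contracts: determinism, symmetry, flow encoding, lesion model."""

import numpy as np
import pandas as pd
import pytest

import vulm
from vulm.synthetic_data import (HEALTHY_SPEED_RANGE_MM_S, TumorSpec,
                                 VesselSegment)


class TestVesselNetwork:
    def test_deterministic_for_fixed_seed(self, small_grid):
        ext = tuple(small_grid.extent_mm)
        a = vulm.generate_vessel_network(ext, n_trees=3, seed=7)
        b = vulm.generate_vessel_network(ext, n_trees=3, seed=7)
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())

    def test_different_seed_differs(self, small_grid):
        ext = tuple(small_grid.extent_mm)
        a = vulm.generate_vessel_network(ext, n_trees=3, seed=7)
        b = vulm.generate_vessel_network(ext, n_trees=3, seed=8)
        assert not a.to_frame().equals(b.to_frame())

    @pytest.mark.parametrize("seed", [0, 3, 11])
    def test_mirror_raster_is_reflection_symmetric(self, small_grid, seed):
        net = vulm.generate_vessel_network(tuple(small_grid.extent_mm),
                                           n_trees=2, mirror=True, seed=seed)
        raster = vulm.rasterize_centerlines(net, small_grid)
        assert vulm.dice_score(raster, raster[:, ::-1, :]) == 1.0

    def test_segment_speeds_within_healthy_range(self, mirror_network):
        speeds = mirror_network.to_frame().speed_mm_s
        lo, hi = HEALTHY_SPEED_RANGE_MM_S
        assert speeds.between(lo, hi).all()

    def test_endpoints_inside_domain(self, mirror_network):
        ext = np.asarray(mirror_network.domain_extent)
        df = mirror_network.to_frame()
        pts = np.concatenate([df[["z0_mm", "x0_mm", "y0_mm"]].to_numpy(),
                              df[["z1_mm", "x1_mm", "y1_mm"]].to_numpy()])
        assert (pts >= 0).all() and (pts <= ext).all()

    def test_domain_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            vulm.generate_vessel_network((0.1, 0.1, 0.1), n_trees=1, seed=0)

    def test_invalid_segment_rejected(self):
        with pytest.raises(ValueError):
            VesselSegment((0, 0, 0), (0, 0, 0), 0.1, 1.0, "left")
        with pytest.raises(ValueError):
            VesselSegment((0, 0, 0), (1, 0, 0), -0.1, 1.0, "left")


class TestTumorModel:
    def test_zero_radii_identity(self, mirror_network):
        tumor = TumorSpec(center=(1.0, 1.0, 1.0), core_radius=0.0,
                          periphery_radius=0.0)
        out = vulm.apply_tumor_model(mirror_network, tumor, seed=0)
        pd.testing.assert_frame_equal(out.to_frame(),
                                      mirror_network.to_frame())

    def test_full_dropout_empties_core(self, mirror_network):
        ext = np.asarray(mirror_network.domain_extent)
        center = tuple(0.5 * ext)
        tumor = TumorSpec(center=center, core_radius=1.2,
                          periphery_radius=1.2, dropout_fraction_in_core=1.0)
        out = vulm.apply_tumor_model(mirror_network, tumor, seed=0)
        # brute-force distance check over every surviving segment midpoint
        for seg in out.segments:
            assert np.linalg.norm(seg.midpoint - np.asarray(center)) > 1.2

    def test_periphery_speeds_resampled_into_tumor_range(self,
                                                         mirror_network):
        ext = np.asarray(mirror_network.domain_extent)
        center = tuple(0.5 * ext)
        tumor = TumorSpec(center=center, core_radius=0.0,
                          periphery_radius=2.0,
                          periphery_speed_range=(0.1, 0.8),
                          dropout_fraction_in_core=0.0)
        out = vulm.apply_tumor_model(mirror_network, tumor, seed=0)
        for seg in out.segments:
            if np.linalg.norm(seg.midpoint - np.asarray(center)) <= 2.0:
                assert 0.1 <= seg.centerline_speed <= 0.8

    def test_outside_periphery_untouched(self, mirror_network):
        center = (0.5, 0.5, 0.5)
        tumor = TumorSpec(center=center, core_radius=0.3,
                          periphery_radius=0.6)
        out = vulm.apply_tumor_model(mirror_network, tumor, seed=0)
        orig = {(tuple(s.start_point), tuple(s.end_point)): s
                for s in mirror_network.segments}
        for seg in out.segments:
            if np.linalg.norm(seg.midpoint - np.asarray(center)) > 0.6:
                key = (tuple(seg.start_point), tuple(seg.end_point))
                assert seg.centerline_speed == orig[key].centerline_speed


class TestTransits:
    def test_interframe_displacement_encodes_speed(self):
        # one segment at 10 mm/s, 500 vps -> 0.020 mm per frame exactly
        seg = VesselSegment((1.0, 0.2, 1.0), (1.0, 2.8, 1.0), 0.05, 10.0,
                            "left")
        net = vulm.VesselNetwork([seg], (3.0, 3.0, 3.0))
        truth = vulm.simulate_mb_transits(net, 100, volume_rate=500.0,
                                          mean_mb_per_volume=3.0, seed=1)
        rec = truth.records
        for _, bub in rec.groupby("bubble_id"):
            if len(bub) < 2:
                continue
            bub = bub.sort_values("volume_index")
            d = np.diff(bub[["z_mm", "x_mm", "y_mm"]].to_numpy(), axis=0)
            steps = np.linalg.norm(d, axis=1)
            dt = np.diff(bub.volume_index.to_numpy())
            np.testing.assert_allclose(steps / dt, 0.020, rtol=1e-9)

    def test_zero_speed_bubbles_static(self):
        seg = VesselSegment((1.0, 0.2, 1.0), (1.0, 2.8, 1.0), 0.05, 0.0,
                            "left")
        net = vulm.VesselNetwork([seg], (3.0, 3.0, 3.0))
        truth = vulm.simulate_mb_transits(net, 50, mean_mb_per_volume=5.0,
                                          seed=2)
        for _, bub in truth.records.groupby("bubble_id"):
            pos = bub[["z_mm", "x_mm", "y_mm"]].to_numpy()
            assert np.ptp(pos, axis=0).max() == 0.0

    def test_mean_count_matches_requested_density(self, mirror_network):
        truth = vulm.simulate_mb_transits(mirror_network, 200,
                                          mean_mb_per_volume=80.0, seed=3)
        mean = truth.mean_count_per_volume()
        assert 60.0 <= mean <= 100.0
        # within 3 standard errors of the Poisson target:
        # total ~ Poisson(80*200), SE(mean) = sqrt(80/200)
        assert abs(mean - 80.0) <= 3 * np.sqrt(80.0 / 200)

    def test_positions_within_vessel_radius(self, mirror_network):
        truth = vulm.simulate_mb_transits(mirror_network, 20,
                                          mean_mb_per_volume=30.0, seed=4)
        segs = mirror_network.segments
        rec = truth.records
        for sid, sub in rec.groupby("segment_id"):
            seg = segs[int(sid)]
            p0 = np.asarray(seg.start_point)
            d = seg.direction
            pts = sub[["z_mm", "x_mm", "y_mm"]].to_numpy()
            rel = pts - p0
            along = rel @ d
            radial = np.linalg.norm(rel - np.outer(along, d), axis=1)
            assert (radial <= seg.radius + 1e-9).all()

    def test_empty_network_rejected(self):
        net = vulm.VesselNetwork([], (3.0, 3.0, 3.0))
        with pytest.raises(ValueError, match="zero segments"):
            vulm.simulate_mb_transits(net, 10)

    def test_deterministic(self, mirror_network):
        a = vulm.simulate_mb_transits(mirror_network, 30, seed=9)
        b = vulm.simulate_mb_transits(mirror_network, 30, seed=9)
        pd.testing.assert_frame_equal(a.records, b.records)


class TestVolumeSynthesis:
    def test_no_bubbles_gives_static_tissue(self, fixtures):
        stack = fixtures["static_tissue"]["stack"].data
        for t in range(1, stack.shape[3]):
            np.testing.assert_array_equal(stack[..., t], stack[..., 0])
        assert stack.min() >= 0

    def test_argmax_at_true_bubble_voxel(self, fixtures, small_grid):
        stack = fixtures["single_bubble"]["stack"]
        truth = fixtures["single_bubble"]["truth"]
        for t in range(stack.n_volumes):
            frame = stack.data[..., t]
            vox = np.unravel_index(np.argmax(frame), frame.shape)
            true_idx = small_grid.position_to_index(truth.positions(t)[0])
            assert np.all(np.abs(np.asarray(vox) - true_idx) <= 0.5 + 1e-9)

    def test_blob_fwhm_spans_two_voxels(self, small_grid):
        import pandas as pd
        # one bubble exactly on a voxel center
        pos = small_grid.index_to_position(np.array([16, 16, 16]))
        df = pd.DataFrame([[0, 0, *pos, 0.0, 0]],
                          columns=["volume_index", "bubble_id", "z_mm",
                                   "x_mm", "y_mm", "speed_mm_s",
                                   "segment_id"])
        truth = vulm.MBGroundTruth(df, n_volumes=1)
        stack = vulm.synthesize_volume_stack(truth, small_grid, seed=0)
        profile = stack.data[16, :, 16, 0]
        half = profile.max() / 2.0
        width = np.count_nonzero(profile >= half)
        # FWHM = lambda = two half-wavelength voxels -> 1 or 2 samples wide
        assert width in (1, 2, 3)
        sigma_vox = vulm.psf_sigma_from_fwhm(2.0)
        expected = np.exp(-0.5 * (1.0 / sigma_vox) ** 2)
        np.testing.assert_allclose(profile[17] / profile[16], expected,
                                   rtol=1e-5)

    def test_determinism(self, small_grid, mirror_network):
        truth = vulm.simulate_mb_transits(mirror_network, 5, seed=5)
        a = vulm.synthesize_volume_stack(truth, small_grid,
                                         tissue_amplitude=5.0,
                                         noise_sigma=0.1, seed=6)
        b = vulm.synthesize_volume_stack(truth, small_grid,
                                         tissue_amplitude=5.0,
                                         noise_sigma=0.1, seed=6)
        np.testing.assert_array_equal(a.data, b.data)
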