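"""Biomarker oracles: skeleton density, mirror dice, shell profiles."""

import numpy as np
import pandas as pd
import pytest

import vulm
from vulm.core import GridSpec
from vulm.metrics import (ROIMask, ShellSpec, SymmetryConfig,
                          bilateral_symmetry, dice_score, shell_profiles,
                          skeletonize_ulm, vascular_density)
from vulm.rendering import ULMImage, VelocityMap


def cylinder_image(shape=(64, 64, 64), radius_vox=4, voxel=0.01):
    """Solid cylinder along the lateral axis, spanning the full width."""
    zz, _, yy = np.mgrid[:shape[0], :shape[1], :shape[2]]
    c = (shape[0] // 2, shape[2] // 2)
    mask = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 <= radius_vox ** 2
    return ULMImage(mask.astype(np.float32), voxel)


class TestSkeleton:
    def test_cylinder_skeleton_count_near_analytic_length(self):
        img = cylinder_image()
        skel = skeletonize_ulm(img)
        assert skel.sum() == pytest.approx(64, rel=0.10)

    def test_empty_image_empty_skeleton(self):
        img = ULMImage(np.zeros((16, 16, 16)), 0.01)
        assert skeletonize_ulm(img).sum() == 0

    def test_skeleton_subset_of_support(self):
        img = cylinder_image(shape=(32, 32, 32), radius_vox=3)
        skel = skeletonize_ulm(img)
        assert not np.any(skel & ~(img.density > 0))


class TestVascularDensity:
    def test_count_per_cubic_millimeter(self):
        voxel = 0.1  # 1000 voxels per mm^3
        skel = np.zeros((20, 20, 20), dtype=bool)
        skel[:10, 0, 0] = True  # 10 centerline voxels
        roi = ROIMask(np.ones((20, 20, 20), dtype=bool), voxel)
        vd = vascular_density(skel, roi)
        assert vd == pytest.approx(10 / (8000 * 0.001))

    def test_hundred_voxels_in_unit_roi(self):
        voxel = 0.1
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[:10, :10, :10] = True  # 1000 voxels = 1 mm^3
        skel = np.zeros_like(mask)
        skel[:5, :5, :4] = True  # 100 voxels inside
        assert vascular_density(skel, ROIMask(mask, voxel)) \
            == pytest.approx(100.0)

    def test_linear_in_skeleton_count(self):
        voxel = 0.05
        roi = ROIMask(np.ones((16, 16, 16), dtype=bool), voxel)
        skel = np.zeros((16, 16, 16), dtype=bool)
        skel[0, :4, 0] = True
        v1 = vascular_density(skel, roi)
        skel[1, :4, 0] = True
        assert vascular_density(skel, roi) == pytest.approx(2 * v1)

    def test_roi_excluding_skeleton_zero(self):
        skel = np.zeros((8, 8, 8), dtype=bool)
        skel[0] = True
        roi_mask = np.zeros_like(skel)
        roi_mask[4:] = True
        assert vascular_density(skel, ROIMask(roi_mask, 0.1)) == 0.0

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            vascular_density(np.zeros((4, 4, 4), dtype=bool),
                             ROIMask(np.zeros((4, 4, 4), dtype=bool), 0.1))


class TestDice:
    def test_half_overlap_is_half(self):
        a = np.zeros((10, 10, 10), dtype=bool)
        b = np.zeros_like(a)
        a[:4] = True          # |A| = 400
        b[2:6] = True         # |B| = 400, |A∩B| = 200
        assert dice_score(a, b) == pytest.approx(0.5)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(0)
        a = rng.random((8, 8, 8)) > 0.5
        b = rng.random((8, 8, 8)) > 0.5
        d = dice_score(a, b)
        assert d == dice_score(b, a)
        assert 0.0 <= d <= 1.0
        assert dice_score(a, a) == 1.0


class TestBilateralSymmetry:
    def test_mirror_symmetric_volume_scores_one(self):
        rng = np.random.default_rng(1)
        half = rng.random((40, 20, 40)).astype(np.float32)
        half[half < 0.98] = 0  # sparse vessel-like support
        vol = np.concatenate([half, half[:, ::-1, :]], axis=1)
        img = ULMImage(vol, 0.01)
        cfg = SymmetryConfig(rotation_search=False)
        score, info = bilateral_symmetry(img, cfg)
        assert score == pytest.approx(1.0)
        assert not info["empty"]

    def test_single_hemisphere_scores_zero(self):
        # pre-centered frame of reference: content strictly on one side of
        # the midline reflects onto empty space
        vol = np.zeros((40, 80, 40), dtype=np.float32)
        vol[10:30, 2:20, 10:30] = 1.0  # ends 1λ short of the midline
        img = ULMImage(vol, 0.01)
        cfg = SymmetryConfig(rotation_search=False,
                             translation_centering=False)
        score, _ = bilateral_symmetry(img, cfg)
        assert score == pytest.approx(0.0, abs=0.05)

    def test_empty_volume_flagged_zero(self):
        img = ULMImage(np.zeros((16, 16, 16)), 0.01)
        score, info = bilateral_symmetry(img)
        assert score == 0.0 and info["empty"]

    def test_rotation_search_recovers_rotated_volume(self):
        from scipy import ndimage
        # symmetric bundle of vessel-like lines, rotated about the depth
        # axis; the search should undo (most of) the rotation
        vol = np.zeros((96, 96, 96), dtype=np.float32)
        for x in (16, 32):
            vol[20:80, x, 30:90] = 1.0
            vol[20:80, 95 - x, 30:90] = 1.0
        rot = ndimage.rotate(vol, 6.0, axes=(1, 2), reshape=False, order=1)
        cfg = SymmetryConfig(rotation_search=True)
        score_rot, info = bilateral_symmetry(ULMImage(rot, 0.01), cfg)
        cfg_off = SymmetryConfig(rotation_search=False)
        score_off, _ = bilateral_symmetry(ULMImage(rot, 0.01), cfg_off)
        assert score_rot >= score_off
        assert abs(info["rotation_deg"][0] - (-6.0)) <= 3.0

    def test_no_rotation_found_on_flat_landscape(self):
        # compact symmetric blob: every angle scores alike, so the search
        # must settle on zero rotation
        vol = np.zeros((32, 32, 32), dtype=np.float32)
        vol[12:20, 12:20, 12:20] = 1.0
        cfg = SymmetryConfig(rotation_search=True)
        _, info = bilateral_symmetry(ULMImage(vol, 0.01), cfg)
        assert info["rotation_deg"] == (0.0, 0.0)


class TestShellProfiles:
    def grid_map(self, speed_value=10.0, shape=(80, 80, 80), voxel=0.05):
        speed = np.full(shape, speed_value, dtype=np.float32)
        support = np.ones(shape, dtype=np.int32)
        return VelocityMap(speed, support, voxel)

    def spec(self, voxel=0.05, shape=(80, 80, 80)):
        ext = np.array(shape) * voxel
        left = (0.5 * ext[0], 0.3 * ext[1], 0.5 * ext[2])
        return ShellSpec.from_left_center(left, midline_lateral_mm=ext[1] / 2,
                                          shell_outer_radii=tuple(
                                              np.arange(0.25, 1.51, 0.25)))

    def test_uniform_field_flat_profile_zero_difference(self):
        vmap = self.grid_map()
        df = shell_profiles(vmap, self.spec())
        np.testing.assert_allclose(df.mean_speed_left_mm_s, 10.0)
        np.testing.assert_allclose(df.mean_speed_right_mm_s, 10.0)
        np.testing.assert_allclose(df.difference_mm_s, 0.0)

    def test_zero_flow_core_transition(self):
        vmap = self.grid_map(12.0)
        spec = self.spec()
        c = np.asarray(spec.center_left)
        grid = vmap.grid
        coords = [(np.arange(n) + 0.5) * grid.voxel_size
                  for n in grid.shape]
        dist = np.sqrt((coords[0] - c[0])[:, None, None] ** 2 +
                       (coords[1] - c[1])[None, :, None] ** 2 +
                       (coords[2] - c[2])[None, None, :] ** 2)
        core = dist <= 1.0
        vmap.speed[core] = 0.0  # supported voxels with stalled flow
        df = shell_profiles(vmap, spec)
        left = df.mean_speed_left_mm_s.to_numpy()
        # means rise from 0 toward 12 as r passes the core radius
        assert left[0] < 1.0
        assert left[-1] == pytest.approx(12.0, abs=0.5)
        valid = ~np.isnan(left)
        assert np.all(np.diff(left[valid]) >= -1e-6)
        # contralateral side is intact, so differences are negative early
        assert df.difference_mm_s.to_numpy()[valid][0] < 0

    def test_unsupported_shell_reported_missing(self):
        vmap = self.grid_map()
        vmap.support_count[:] = 0
        df = shell_profiles(vmap, self.spec())
        assert df.mean_speed_left_mm_s.isna().all()
        assert (df.n_voxels_left == 0).all()

    def test_default_radii_extend_to_four_millimeters(self):
        spec = ShellSpec.from_left_center((1, 1, 1), 2.0)
        assert max(spec.shell_outer_radii) == pytest.approx(4.0)
        assert np.all(np.diff(spec.shell_outer_radii)
                      == pytest.approx(0.25))

    def test_mirrored_center(self):
        spec = ShellSpec.from_left_center((3.0, 1.0, 2.0),
                                          midline_lateral_mm=2.5)
        assert spec.center_right == (3.0, 4.0, 2.0)


class TestReductionSummary:
    def make_lhr(self, rows):
        return pd.DataFrame(rows, columns=[
            "radius_mm", "mean_speed_left_mm_s", "mean_speed_right_mm_s",
            "n_voxels_left", "n_voxels_right"])

    def test_balanced_shells_weighted_difference(self):
        from vulm.metrics import hemodynamic_reduction_summary
        lhr = self.make_lhr([(0.5, 8.0, 10.0, 100, 100),
                             (1.0, 10.0, 10.0, 300, 300)])
        # weights 100 and 300: (-2*100 + 0*300)/400 = -0.5
        assert hemodynamic_reduction_summary(lhr) == pytest.approx(-0.5)

    def test_unsupported_tumoral_shell_counts_as_full_reduction(self):
        from vulm.metrics import hemodynamic_reduction_summary
        lhr = self.make_lhr([(0.5, np.nan, 10.0, 0, 200)])
        assert hemodynamic_reduction_summary(lhr) == pytest.approx(-10.0)

    def test_radius_window_and_empty_case(self):
        from vulm.metrics import hemodynamic_reduction_summary
        lhr = self.make_lhr([(3.5, 0.0, 10.0, 50, 50)])
        assert np.isnan(hemodynamic_reduction_summary(lhr, r_max=2.75))
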