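"""Hole filling, masking, outlier removal, translation-only ICP and fusion."""

import numpy as np
import pytest

from depthvol.geometry import (
    DepthImage,
    PointCloud,
    back_project,
    register_to_world,
    RigidPose,
    rotation_about_y,
)
from depthvol.completion import (
    IcpParams,
    complete_cloud,
    contour_mask,
    estimate_rim_retreat,
    extract_object_mask,
    fill_depth_holes,
    icp_translation,
    remove_outliers,
    smooth_depth,
)


class TestFillDepthHoles:
    def test_hole_free_image_unchanged(self, sphere_sample):
        out = fill_depth_holes(sphere_sample.initial)
        np.testing.assert_array_equal(out.values, sphere_sample.initial.values)

    def test_single_interior_hole_filled_with_neighbour_value(self):
        vals = np.full((7, 7), 0.55)
        vals[3, 3] = 0.0
        out = fill_depth_holes(DepthImage(vals))
        assert out.values[3, 3] == pytest.approx(0.55)

    def test_hole_in_ramp_fills_within_neighbour_range(self):
        vals = np.tile(np.linspace(0.5, 0.6, 9), (9, 1))
        vals[4, 4] = 0.0
        out = fill_depth_holes(DepthImage(vals))
        neigh = np.tile(np.linspace(0.5, 0.6, 9), (9, 1))[2:7, 2:7]
        assert neigh.min() <= out.values[4, 4] <= neigh.max()

    def test_border_connected_background_not_filled(self, sphere_sample):
        # rendered images have a large border-connected zero background
        out = fill_depth_holes(sphere_sample.initial)
        assert out.n_valid == sphere_sample.initial.n_valid

    def test_multi_pixel_hole_filled_iteratively(self):
        vals = np.full((11, 11), 0.5)
        vals[4:7, 4:7] = 0.0
        out = fill_depth_holes(DepthImage(vals), radius=1)
        assert out.n_valid == 121
        np.testing.assert_allclose(out.values, 0.5)

    def test_valid_pixels_never_modified(self):
        rng = np.random.default_rng(0)
        vals = 0.5 + 0.01 * rng.random((9, 9))
        vals[4, 4] = 0.0
        original = vals.copy()
        out = fill_depth_holes(DepthImage(vals))
        keep = original > 0
        np.testing.assert_array_equal(out.values[keep], original[keep])


class TestSmoothDepth:
    def test_zeros_preserved_and_not_smeared(self, sphere_sample):
        out = smooth_depth(sphere_sample.initial)
        np.testing.assert_array_equal(
            out.valid_mask, sphere_sample.initial.valid_mask)

    def test_constant_region_unchanged(self):
        out = smooth_depth(DepthImage(np.full((9, 9), 0.5)))
        np.testing.assert_allclose(out.values, 0.5, atol=1e-12)

    def test_noise_variance_reduced(self, rng):
        vals = 0.5 + 0.003 * rng.standard_normal((40, 40))
        out = smooth_depth(DepthImage(np.clip(vals, 0.01, None)))
        assert out.values.std() < 0.5 * vals.std()


class TestExtractObjectMask:
    def test_rendered_primitive_mask_is_exactly_valid_pixels(self, sphere_sample):
        mask = extract_object_mask(sphere_sample.initial)
        np.testing.assert_array_equal(mask, sphere_sample.initial.valid_mask)

    def test_largest_component_kept(self):
        vals = np.zeros((20, 40))
        vals[2:12, 2:12] = 0.5  # 100 px
        vals[15:17, 30:32] = 0.5  # 4 px speck
        mask = extract_object_mask(DepthImage(vals))
        assert mask.sum() == 100
        assert not mask[15, 30]

    def test_background_depth_removed(self):
        vals = np.full((10, 10), 0.8)
        vals[4:7, 4:7] = 0.5
        mask = extract_object_mask(DepthImage(vals), background_depth=0.8)
        assert mask.sum() == 9

    def test_all_invalid_is_an_error(self):
        with pytest.raises(ValueError, match="no object"):
            extract_object_mask(DepthImage(np.zeros((5, 5))))

    def test_contour_is_the_mask_boundary(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:8, 2:8] = True
        edge = contour_mask(mask)
        assert edge.sum() == 20  # 6x6 block has a 20-pixel boundary
        assert not edge[4, 4]


class TestRemoveOutliers:
    def test_far_point_removed_sphere_kept(self, rng):
        pts = rng.normal(size=(1000, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        cloud = PointCloud(np.vstack([pts, [[10.0, 0.0, 0.0]]]), "world")
        out = remove_outliers(cloud, k=20, std_ratio=3.0)
        assert np.abs(out.points).max() < 2.0
        assert len(out) >= 990

    def test_uniform_grid_keeps_interior(self):
        # corner points of a finite grid legitimately have larger mean-kNN
        # distances; the filter may trim them but never interior points
        g = np.stack(np.meshgrid(*[np.arange(8.0)] * 3), -1).reshape(-1, 3)
        out = remove_outliers(PointCloud(g, "world"))
        assert len(out) >= 0.98 * len(g)
        interior = g[((g > 0) & (g < 7)).all(axis=1)]
        kept = {tuple(p) for p in out.points}
        assert all(tuple(p) in kept for p in interior)

    def test_clean_rendered_cloud_loses_under_ten_percent(self, sphere_sample, k_small):
        cloud = back_project(sphere_sample.initial, k_small)
        out = remove_outliers(cloud)
        assert len(out) >= 0.9 * len(cloud)

    def test_empty_cloud_passthrough(self):
        out = remove_outliers(PointCloud(np.zeros((0, 3)), "world"))
        assert len(out) == 0

    def test_small_cloud_warns_and_passes_through(self):
        with pytest.warns(UserWarning, match="skipped"):
            out = remove_outliers(PointCloud(np.eye(3), "world"), k=5)
        assert len(out) == 3

    def test_survivor_order_preserved(self, rng):
        pts = rng.normal(size=(200, 3))
        out = remove_outliers(PointCloud(pts, "world"), k=10, std_ratio=3.0)
        # survivors appear in their original relative order
        idx = [np.flatnonzero((pts == p).all(axis=1))[0] for p in out.points]
        assert idx == sorted(idx)


class TestIcpTranslation:
    def test_identical_clouds_zero_shift(self, rng):
        pts = rng.normal(size=(300, 3))
        res = icp_translation(PointCloud(pts, "world"), PointCloud(pts, "world"))
        np.testing.assert_allclose(res.translation, 0.0, atol=1e-6)
        assert res.rms < 1e-6
        assert res.converged

    @pytest.mark.parametrize("shift", [(0.05, 0.0, 0.02), (-0.03, 0.04, 0.0)])
    def test_rigid_shift_recovered_to_millimetre(self, rng, shift):
        pts = rng.normal(scale=0.03, size=(500, 3))
        src = PointCloud(pts, "world")
        tgt = PointCloud(pts + np.array(shift), "world")
        res = icp_translation(src, tgt)
        np.testing.assert_allclose(res.translation, shift, atol=1e-3)

    def test_start_at_optimum_converges_immediately(self, rng):
        pts = rng.normal(size=(200, 3))
        shift = np.array([0.01, -0.02, 0.005])
        res = icp_translation(PointCloud(pts, "world"),
                              PointCloud(pts + shift, "world"), t_init=shift)
        assert res.iterations <= 2
        assert res.rms < 1e-5

    def test_cost_non_increasing(self, rng):
        pts = rng.normal(scale=0.05, size=(400, 3))
        tgt = PointCloud(pts + [0.04, 0.0, -0.03], "world")
        res = icp_translation(PointCloud(pts, "world"), tgt)
        diffs = np.diff(res.history)
        assert (diffs <= 1e-12).all()

    def test_recovery_beats_initialization_for_most_perturbations(self, rng):
        pts = rng.normal(scale=0.03, size=(400, 3))
        shift = np.array([0.01, 0.02, -0.01])
        src = PointCloud(pts, "world")
        tgt = PointCloud(pts + shift, "world")
        wins = 0
        n = 40
        for _ in range(n):
            eps = rng.uniform(-1, 1, 3)
            eps *= rng.uniform(0, 0.05) / np.linalg.norm(eps)
            res = icp_translation(src, tgt, t_init=shift + eps)
            if np.linalg.norm(res.translation - shift) <= np.linalg.norm(eps):
                wins += 1
        assert wins >= 0.95 * n

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError):
            icp_translation(PointCloud(np.zeros((0, 3)), "w"),
                            PointCloud(np.ones((5, 3)), "w"))

    def test_bad_params_rejected(self):
        with pytest.raises(ValueError):
            IcpParams(max_iterations=0)
        with pytest.raises(ValueError):
            IcpParams(tolerance=0.1, rejection_distance=0.01)


class TestRimRetreat:
    def test_smooth_limb_detected_on_sphere(self, sphere_sample, k_small):
        depth = sphere_sample.initial
        mask = extract_object_mask(depth)
        retreat, weight = estimate_rim_retreat(depth, mask, k_small)
        # sqrt(2 * pitch * r) at quarter-VGA pitch (~3.9 mm) is ~12 mm of
        # geometric retreat scale; estimates must be positive and bounded
        assert 0.002 < retreat < 0.025
        assert weight > 0.5

    def test_face_on_cube_has_small_retreat(self, cube_mesh, k_small):
        from depthvol.render import render_depth
        pose = RigidPose(np.eye(3), [0.0, 0.0, 0.55])
        depth = render_depth(cube_mesh, pose, k_small)
        mask = extract_object_mask(depth)
        retreat, _ = estimate_rim_retreat(depth, mask, k_small)
        assert retreat < 0.004

    def test_tiny_mask_returns_zero(self, k_small):
        vals = np.zeros((120, 160))
        vals[60, 80] = 0.5
        retreat, weight = estimate_rim_retreat(
            DepthImage(vals), vals > 0, k_small)
        assert retreat == 0.0 and weight == 0.0


class TestCompleteCloud:
    def test_zero_noise_fusion_is_the_union_of_masked_clouds(
            self, sphere_sample, k_small):
        n_init = sphere_sample.initial.n_valid
        n_opp = sphere_sample.opposite.n_valid
        cloud = complete_cloud(
            sphere_sample.initial, sphere_sample.opposite, k_small,
            sphere_sample.t_gt, remove_outliers_after=False)
        assert len(cloud) == n_init + n_opp

    def test_fused_sphere_extents_match_diameter(self, sphere_sample_vga):
        # full VGA resolution: the two opposite views cover the sphere up to
        # the tangent rim, so each bounding-box extent is the diameter
        from depthvol.geometry import DEFAULT_INTRINSICS
        s = sphere_sample_vga
        cloud = complete_cloud(s.initial, s.opposite, DEFAULT_INTRINSICS, s.t_gt)
        extents = cloud.points.max(axis=0) - cloud.points.min(axis=0)
        np.testing.assert_allclose(extents, 0.073, rtol=0.02)

    def test_refinement_with_clean_inputs_stays_near_truth(
            self, sphere_sample, k_small):
        base = complete_cloud(sphere_sample.initial, sphere_sample.opposite,
                              k_small, sphere_sample.t_gt)
        refined = complete_cloud(sphere_sample.initial, sphere_sample.opposite,
                                 k_small, sphere_sample.t_gt, refine=True)
        # the refinement re-estimates the registration from the images alone;
        # with clean inputs it must land within a few mm of the truth
        b = base.points.mean(axis=0)
        r = refined.points.mean(axis=0)
        assert np.linalg.norm(b - r) < 0.005

    def test_refinement_recovers_from_noisy_translation(
            self, sphere_sample, k_small, rng):
        t_noisy = sphere_sample.t_gt + rng.normal(0, 0.02, 3)
        refined = complete_cloud(sphere_sample.initial, sphere_sample.opposite,
                                 k_small, t_noisy, refine=True)
        truth = complete_cloud(sphere_sample.initial, sphere_sample.opposite,
                               k_small, sphere_sample.t_gt)
        drift = np.linalg.norm(
            refined.points.mean(axis=0) - truth.points.mean(axis=0))
        init_err = np.linalg.norm(t_noisy - sphere_sample.t_gt)
        assert drift < 0.5 * init_err

    def test_rotation_is_never_updated(self, sphere_sample, k_small, rng):
        # the opposite cloud in the fusion differs from its raw registration
        # by a pure translation, whatever the refinement did
        t_noisy = sphere_sample.t_gt + rng.normal(0, 0.02, 3)
        fused = complete_cloud(sphere_sample.initial, sphere_sample.opposite,
                               k_small, t_noisy, refine=True,
                               remove_outliers_after=False)
        n_init = sphere_sample.initial.n_valid
        opp_part = fused.points[n_init:]
        from depthvol.completion import fill_depth_holes as _f
        pose = RigidPose(rotation_about_y(180.0), t_noisy)
        from depthvol.completion import smooth_depth as _s
        raw = register_to_world(
            back_project(_s(_f(sphere_sample.opposite)), k_small), pose).points
        deltas = opp_part - raw
        assert np.allclose(deltas, deltas[0], atol=1e-9)

    def test_empty_mask_is_an_error(self, k_small):
        empty = DepthImage(np.zeros((120, 160)))
        with pytest.raises(ValueError):
            complete_cloud(empty, empty, k_small, np.zeros(3))

    def test_non_finite_translation_rejected(self, sphere_sample, k_small):
        with pytest.raises(ValueError):
            complete_cloud(sphere_sample.initial, sphere_sample.opposite,
                           k_small, np.array([np.nan, 0, 0]))
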