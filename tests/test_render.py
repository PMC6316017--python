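"""Synthetic primitives, pose sampling, depth rendering and dataset I/O."""

import json

import numpy as np
import pytest

from depthvol.geometry import RigidPose, rotation_about_y
from depthvol import io as dvio
from depthvol.render import (
    PrimitiveSpec,
    ViewConfig,
    build_dataset,
    default_catalogue,
    holdout_split,
    make_primitive,
    render_depth,
    render_sample,
    sample_pose_pair,
)


class TestPrimitives:
    @pytest.mark.parametrize("spec, expected_cm3", [
        (PrimitiveSpec("cube", {"edge": 5.7}), 5.7**3),               # 185.193
        (PrimitiveSpec("sphere", {"radius": 1.0}), 4.18879),
        (PrimitiveSpec("cylinder", {"radius": 3.0, "height": 5.0}), 141.372),
        (PrimitiveSpec("capsule", {"radius": 2.5, "length": 6.0}), 183.2595),
        (PrimitiveSpec("ellipsoid", {"a": 1.0, "b": 2.0, "c": 3.0}), 25.1327),
    ])
    def test_analytic_volumes(self, spec, expected_cm3):
        assert spec.analytic_volume == pytest.approx(expected_cm3, rel=1e-4)

    @pytest.mark.parametrize("name", ["cube", "sphere", "cylinder", "capsule"])
    def test_meshes_watertight_and_near_analytic(self, catalogue, name):
        mesh, analytic = make_primitive(catalogue[name])
        assert mesh.is_watertight
        assert mesh.volume * 1e6 == pytest.approx(analytic, rel=0.01)

    def test_mesh_volume_converges_with_resolution(self, catalogue):
        spec = catalogue["sphere"]
        errs = [abs(make_primitive(spec, r)[0].volume * 1e6 - spec.analytic_volume)
                for r in (1, 2)]
        assert errs[1] < errs[0]

    def test_bent_capsule_matches_pappus_volume(self):
        spec = PrimitiveSpec(
            "bent_capsule", {"radius": 1.9, "bend_radius": 5.0, "angle_deg": 150.0})
        mesh, analytic = make_primitive(spec, mesh_resolution=2)
        assert mesh.volume * 1e6 == pytest.approx(analytic, rel=0.03)

    def test_bent_capsule_volume_against_voxel_oracle(self):
        # independent reference: dense voxelization of the arc distance field
        spec = PrimitiveSpec(
            "bent_capsule", {"radius": 1.9, "bend_radius": 5.0, "angle_deg": 150.0})
        r, rb = 0.019, 0.05
        half = np.radians(150.0) / 2
        pitch = 0.0008
        ax = np.arange(-rb - r - pitch, rb + r + 2 * pitch, pitch)
        az = np.arange(-r - pitch, r + 2 * pitch, pitch)
        x, y, z = np.meshgrid(ax, ax, az, indexing="ij")
        alpha = np.clip(np.arctan2(y, x), -half, half)
        d = np.sqrt((x - rb * np.cos(alpha)) ** 2
                    + (y - rb * np.sin(alpha)) ** 2 + z**2)
        voxel_cm3 = (d <= r).sum() * pitch**3 * 1e6
        assert voxel_cm3 == pytest.approx(spec.analytic_volume, rel=0.01)

    @pytest.mark.parametrize("spec_kwargs", [
        ("cube", {"edge": -1.0}),
        ("bent_capsule", {"radius": 3.0, "bend_radius": 1.0, "angle_deg": 90.0}),
        ("wedge", {"size": 1.0}),
    ])
    def test_invalid_specs_rejected(self, spec_kwargs):
        kind, params = spec_kwargs
        with pytest.raises(ValueError):
            PrimitiveSpec(kind, params)


class TestPoseSampling:
    def test_draws_stay_in_configured_ranges(self, rng):
        cfg = ViewConfig()
        for _ in range(200):
            _, _, _, p = sample_pose_pair(rng, cfg)
            assert 0 <= p["azimuth"] <= 360
            assert 90 <= p["elevation"] <= 270
            assert 0.5 <= p["height"] <= 0.6
            assert -0.1 <= p["shift_x"] <= 0.1 and -0.1 <= p["shift_y"] <= 0.1
            assert 0.5 <= p["opposite_height"] <= 0.6

    def test_opposite_orientation_is_exactly_ry180(self, rng):
        init, opp, _, _ = sample_pose_pair(rng)
        np.testing.assert_allclose(opp.R, rotation_about_y(180.0) @ init.R, atol=1e-12)

    def test_t_gt_maps_initial_frame_to_opposite_frame(self, rng):
        init, opp, t_gt, _ = sample_pose_pair(rng)
        pts = rng.normal(scale=0.03, size=(20, 3))  # scene points near the object
        p_init = init.world_to_camera(pts)
        p_opp = opp.world_to_camera(pts)
        np.testing.assert_allclose(
            p_opp, p_init @ rotation_about_y(180.0).T + t_gt, atol=1e-9)

    def test_centred_cameras_give_axial_translation(self, rng):
        cfg = ViewConfig(height=(0.55, 0.55), opposite_height=(-0.55, -0.55)).centered()
        _, _, t_gt, _ = sample_pose_pair(rng, cfg)
        np.testing.assert_allclose(t_gt, [0.0, 0.0, 1.1], atol=1e-9)

    def test_zero_width_ranges_are_deterministic(self):
        cfg = ViewConfig(azimuth=(10, 10), elevation=(120, 120), height=(0.5, 0.5),
                         shift_x=(0, 0), shift_y=(0, 0), opposite_height=(-0.5, -0.5),
                         opposite_shift_x=(0, 0), opposite_shift_y=(0, 0))
        a = sample_pose_pair(np.random.default_rng(1), cfg)
        b = sample_pose_pair(np.random.default_rng(999), cfg)
        np.testing.assert_array_equal(a[0].T, b[0].T)

    def test_same_seed_reproduces_pair(self):
        a = sample_pose_pair(np.random.default_rng(7))
        b = sample_pose_pair(np.random.default_rng(7))
        np.testing.assert_array_equal(a[2], b[2])

    def test_degenerate_range_rejected(self, rng):
        with pytest.raises(ValueError, match="degenerate"):
            sample_pose_pair(rng, ViewConfig(azimuth=(20, 10)))


class TestRenderDepth:
    def test_centred_sphere_min_depth_is_distance_minus_radius(
            self, sphere_mesh, k_small):
        cfg = ViewConfig(height=(0.55, 0.55), opposite_height=(-0.55, -0.55)).centered()
        sample = render_sample(sphere_mesh, seed=3, config=cfg, k=k_small)
        min_depth = sample.initial.values[sample.initial.valid_mask].min()
        assert min_depth == pytest.approx(0.55 - 0.0365, abs=5e-4)

    def test_cube_face_on_modal_depth(self, cube_mesh, k_small):
        pose = RigidPose(np.eye(3), [0.0, 0.0, 0.55])  # camera 0.55 m in front
        img = render_depth(cube_mesh, pose, k_small)
        vals = img.values[img.valid_mask]
        modal = np.bincount(np.round(vals * 1e4).astype(int)).argmax() / 1e4
        assert modal == pytest.approx(0.55 - 0.057 / 2, abs=2e-4)

    def test_empty_mesh_renders_all_zero(self, k_small):
        import trimesh
        empty = trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3)))
        img = render_depth(empty, RigidPose.identity(), k_small)
        assert img.n_valid == 0

    def test_rendering_is_deterministic(self, sphere_mesh, k_small):
        a = render_sample(sphere_mesh, seed=5, k=k_small)
        b = render_sample(sphere_mesh, seed=5, k=k_small)
        np.testing.assert_array_equal(a.initial.values, b.initial.values)
        np.testing.assert_array_equal(a.opposite.values, b.opposite.values)

    def test_opposite_view_of_centred_sphere_mirrors_initial(
            self, sphere_mesh, k_small):
        cfg = ViewConfig(height=(0.55, 0.55), opposite_height=(-0.55, -0.55)).centered()
        s = render_sample(sphere_mesh, seed=11, config=cfg, k=k_small)
        a, b = s.initial, s.opposite
        assert a.n_valid == pytest.approx(b.n_valid, rel=0.01)
        assert a.values[a.valid_mask].mean() == pytest.approx(
            b.values[b.valid_mask].mean(), rel=0.01)


class TestDataset:
    def test_build_writes_counts_and_round_trips(self, sphere_mesh, cube_mesh,
                                                 k_small, tmp_path):
        meshes = {"sphere": sphere_mesh, "cube": cube_mesh}
        index = build_dataset(meshes, 3, seed=9, out_dir=tmp_path, k=k_small)
        assert len(index) == 6
        pngs = list(tmp_path.rglob("*.png"))
        assert len(pngs) == 12
        # metadata and depth round-trip through the readers
        entry = index[0]
        depth = dvio.read_depth_png(tmp_path / entry["init"])
        k2, pose, extra = dvio.read_camera_json(tmp_path / entry["meta"])
        assert k2 == k_small
        assert depth.n_valid > 0
        assert len(extra["t_gt"]) == 3

    def test_rebuild_same_seed_is_byte_identical(self, sphere_mesh, k_small, tmp_path):
        a_dir, b_dir = tmp_path / "a", tmp_path / "b"
        build_dataset({"sphere": sphere_mesh}, 2, seed=4, out_dir=a_dir, k=k_small)
        build_dataset({"sphere": sphere_mesh}, 2, seed=4, out_dir=b_dir, k=k_small)
        for rel in ["sphere/00000.json", "sphere/00001.json", "index.jsonl"]:
            assert (a_dir / rel).read_bytes() == (b_dir / rel).read_bytes()

    def test_invalid_count_rejected(self, sphere_mesh, tmp_path):
        with pytest.raises(ValueError):
            build_dataset({"sphere": sphere_mesh}, 0, 0, tmp_path)


class TestHoldoutSplit:
    def test_published_split_sizes(self):
        index = list(range(28571))
        train, val, test = holdout_split(index, (0.7, 0.1, 0.2), seed=0)
        assert (len(train), len(val), len(test)) == (20000, 2857, 5714)

    def test_small_exact_split(self):
        train, val, test = holdout_split(list(range(10)), (0.7, 0.1, 0.2), seed=1)
        assert (len(train), len(val), len(test)) == (7, 1, 2)

    def test_partition_is_disjoint_and_exhaustive(self):
        index = list(range(137))
        parts = holdout_split(index, (0.7, 0.1, 0.2), seed=3)
        joined = sorted(x for part in parts for x in part)
        assert joined == index
        assert len(set(map(id, parts[0])) & set(map(id, parts[2]))) == 0

    def test_empty_index_rejected(self):
        with pytest.raises(ValueError):
            holdout_split([], (0.7, 0.1, 0.2))

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            holdout_split([1, 2], (0.5, 0.1, 0.2))

    def test_seed_controls_shuffle(self):
        index = list(range(50))
        a = holdout_split(index, seed=1)[0]
        b = holdout_split(index, seed=2)[0]
        assert a != b
        assert a == holdout_split(index, seed=1)[0]
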