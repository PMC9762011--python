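"""Stereo scene renderer and dataset assembly tests.

The frozen projection values come from an independent similar-triangles
pinhole oracle worked by hand: camera at (-0.03, -0.5, 0.2), focal length
0.375 * 64 = 24 px, principal point (31.5, 31.5).
"""

import numpy as np
import pytest

from hemisim.kinematics import HOME_LEFT, HOME_RIGHT
from hemisim.scene import (
    ALL_HSP_MODES,
    SceneConfig,
    TargetSpec,
    build_dataset,
    fold_to_side,
    project_target,
    projected_radius,
    render_stereo,
    sample_target_grid,
)

CFG = SceneConfig(resolution=64)


class TestProjection:
    def test_hand_computed_pinhole_values(self):
        # target (0.1, 0.1, 0.3): depth 0.6, u = 31.5 + 24*0.13/0.6 = 36.7,
        # v = 31.5 - 24*0.1/0.6 = 27.5 (left camera at x = -0.03)
        u, v, depth = project_target([0.1, 0.1, 0.3], -0.03, CFG)
        assert (u, v, depth) == pytest.approx((36.7, 27.5, 0.6))
        u_r, _, _ = project_target([0.1, 0.1, 0.3], +0.03, CFG)
        assert u_r == pytest.approx(34.3)
        # disparity f*baseline/depth = 24*0.06/0.6 = 2.4 px
        assert u - u_r == pytest.approx(2.4)
        assert projected_radius([0.1, 0.1, 0.3], -0.03, CFG, size_id=0) == pytest.approx(2.4)

    def test_behind_camera_rejected(self):
        with pytest.raises(ValueError):
            project_target([0.0, -0.6, 0.2], 0.0, CFG)

    def test_radius_shrinks_with_depth(self):
        near = projected_radius([0.1, 0.1, 0.3], 0.0, CFG, 0)
        far = projected_radius([0.1, 0.5, 0.3], 0.0, CFG, 0)
        assert far < near

    def test_midsagittal_target_projects_symmetrically(self):
        cam = CFG.camera
        ul, _, _ = project_target([0.0, 0.2, 0.3], -cam.baseline / 2, CFG)
        ur, _, _ = project_target([0.0, 0.2, 0.3], +cam.baseline / 2, CFG)
        centre = (CFG.resolution - 1) / 2
        assert ul - centre == pytest.approx(centre - ur)

    def test_disparity_strictly_decreases_with_depth(self):
        cam = CFG.camera
        disparities = []
        for y in np.linspace(0.0, 0.6, 7):
            ul, _, _ = project_target([0.1, y, 0.2], -cam.baseline / 2, CFG)
            ur, _, _ = project_target([0.1, y, 0.2], +cam.baseline / 2, CFG)
            disparities.append(ul - ur)
        assert np.all(np.diff(disparities) < 0)
        assert np.all(np.array(disparities) > 0)


class TestRender:
    def test_stereo_pair_shape_and_range(self):
        img = render_stereo(TargetSpec(position=np.array([0.1, 0.3, 0.2])), CFG)
        assert img.shape == (2, 64, 64)
        assert img.min() >= 0.0 and img.max() <= 1.0
        assert img.max() > 0.1  # the sphere is actually visible

    def test_brightest_pixel_near_projection(self):
        target = np.array([0.2, 0.1, 0.1])
        img = render_stereo(TargetSpec(position=target), CFG)
        u, v, _ = project_target(target, -CFG.camera.baseline / 2, CFG)
        row, col = np.unravel_index(np.argmax(img[0]), img[0].shape)
        assert abs(col - u) <= 2.5 and abs(row - v) <= 2.5


class TestTargetGrid:
    def test_requested_counts_inside_bounds(self):
        pos = sample_target_grid(200, seed=5)
        assert pos.shape == (200, 3)
        assert np.all(np.abs(pos[:, 0]) <= 0.6)
        assert np.all((pos[:, 1] >= 0.0) & (pos[:, 1] <= 0.6))
        assert np.all((pos[:, 2] >= -0.1) & (pos[:, 2] <= 0.5))

    def test_zero_positions_gives_empty(self):
        assert sample_target_grid(0, seed=1).shape == (0, 3)

    def test_deterministic_per_seed(self):
        assert np.array_equal(sample_target_grid(50, seed=9), sample_target_grid(50, seed=9))
        assert not np.array_equal(sample_target_grid(50, seed=9), sample_target_grid(50, seed=10))

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            sample_target_grid(5, bounds=((0.2, 0.1), (0, 1), (0, 1)), seed=0)


class TestFolding:
    def test_fold_mirrors_into_requested_side(self, rng):
        pos = rng.uniform([-0.6, 0, -0.1], [0.6, 0.6, 0.5], size=(50, 3))
        left = fold_to_side(pos, "left")
        right = fold_to_side(pos, "right")
        assert np.all(left[:, 0] <= 0) and np.all(right[:, 0] >= 0)
        # y, z never change; |x| never changes
        assert np.array_equal(left[:, 1:], pos[:, 1:])
        assert np.array_equal(np.abs(left[:, 0]), np.abs(pos[:, 0]))


class TestDatasetAssembly:
    def test_size_is_positions_times_variants_times_modes(self, tiny_scene):
        pos = sample_target_grid(5, seed=2)
        ds = build_dataset(pos, n_variants=3, config=tiny_scene, render=False)
        assert len(ds) == 5 * 3 * 4
        assert ds.manifest()["position_id"].nunique() == 5

    def test_single_sample_dataset(self, tiny_scene):
        ds = build_dataset(
            sample_target_grid(1, seed=2), n_variants=1, hsp_modes=[(1, 1)], config=tiny_scene
        )
        assert len(ds) == 1

    def test_hand_selection_endpoint_semantics(self, tiny_dataset):
        hsp = tiny_dataset.hsp
        rest = np.all(hsp == 0, axis=1)
        # HSP [0 0]: both arms at their home positions
        assert np.allclose(tiny_dataset.required_left[rest], HOME_LEFT)
        assert np.allclose(tiny_dataset.required_right[rest], HOME_RIGHT)
        # active arms go to the scene target; bimanual-joint shares one target
        active_l = hsp[:, 0] == 1
        assert np.array_equal(tiny_dataset.required_left[active_l], tiny_dataset.positions[active_l])
        bim = np.all(hsp == 1, axis=1)
        assert np.array_equal(tiny_dataset.required_left[bim], tiny_dataset.required_right[bim])
        # unimanual targets are presented on the active arm's side
        uni_l = (hsp[:, 0] == 1) & (hsp[:, 1] == 0)
        uni_r = (hsp[:, 0] == 0) & (hsp[:, 1] == 1)
        assert np.all(tiny_dataset.positions[uni_l][:, 0] <= 0)
        assert np.all(tiny_dataset.positions[uni_r][:, 0] >= 0)

    def test_without_rest_mode_drops_only_rest(self, tiny_dataset):
        trimmed = tiny_dataset.without_rest_mode()
        assert len(trimmed) == len(tiny_dataset) * 3 // 4
        assert not np.any(np.all(trimmed.hsp == 0, axis=1))

    def test_deterministic_and_variant_invariant(self, tiny_scene):
        pos = sample_target_grid(4, seed=7)
        a = build_dataset(pos, n_variants=2, config=tiny_scene)
        b = build_dataset(pos, n_variants=2, config=tiny_scene)
        assert np.array_equal(a.images, b.images)
        # a different palette shares positions and endpoints exactly
        other = SceneConfig(
            resolution=tiny_scene.resolution,
            sphere_radii=(0.05, 0.06, 0.07),
            colour_levels=(0.9, 0.6, 0.4),
        )
        c = build_dataset(pos, n_variants=2, config=other)
        assert np.array_equal(a.positions, c.positions)
        assert np.array_equal(a.required_left, c.required_left)
        assert not np.array_equal(a.images, c.images)

    def test_manifest_roundtrip_to_disk(self, tiny_dataset, tmp_path):
        tiny_dataset.save(tmp_path / "ds")
        import pandas as pd

        df = pd.read_csv(tmp_path / "ds" / "manifest.csv")
        assert len(df) == len(tiny_dataset)
        npz = np.load(tmp_path / "ds" / "images.npz")
        assert npz["images"].shape[0] == tiny_dataset.images.shape[0]
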