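"""Phantom generator: torso anatomy, tumour shapes, patterns, assembly."""

import numpy as np
import pytest

import petrestore as pr
from petrestore import phantom, quantify


class TestVoxelGrid:
    def test_voxel_volume(self):
        grid = pr.VoxelGrid((10, 10, 10), (2.09, 2.09, 2.03))
        assert grid.voxel_volume_ml == pytest.approx(2.09 * 2.09 * 2.03 / 1000.0)

    @pytest.mark.parametrize("shape,size", [((0, 4, 4), (1, 1, 1)), ((4, 4, 4), (1, 0, 1))])
    def test_invalid_grid_rejected(self, shape, size):
        with pytest.raises(ValueError):
            pr.VoxelGrid(shape, size)


class TestTorso:
    def test_organ_masks_disjoint_from_left_lung(self, torso):
        for organ in ("heart", "bone"):
            assert not np.logical_and(torso.lung_mask, torso.organ_masks[organ]).any()

    def test_bone_adjacent_to_left_lung(self, torso):
        from scipy import ndimage

        grown = ndimage.binary_dilation(torso.lung_mask, iterations=6)
        assert np.logical_and(grown, torso.organ_masks["bone"]).any()

    def test_zero_activity_table_gives_zero_volume(self, small_grid):
        table = {k: (0.0, v[1]) for k, v in phantom.DEFAULT_ORGAN_TABLE.items()}
        t = phantom.make_torso_phantom(small_grid, organ_table=table)
        assert np.all(t.activity.values == 0)

    def test_lung_attenuation_below_soft_tissue(self, torso):
        mu = torso.attenuation.values
        assert mu[torso.lung_mask].max() < mu[torso.organ_masks["soft_tissue"]].min()

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            phantom.make_torso_phantom(pr.VoxelGrid((8, 8, 4), (2, 2, 2)))


class TestTumourShape:
    @pytest.mark.parametrize("target_ml", [0.18, 1.0, 4.19])
    def test_volume_close_to_target(self, small_grid, target_ml):
        spec = pr.TumourSpec("uniform", target_ml, 20.0, seed=1)
        mask = phantom.sample_tumour_shape(spec, small_grid)
        achieved = mask.sum() * small_grid.voxel_volume_ml
        # within roughly one voxel layer of the surface
        assert achieved == pytest.approx(target_ml, rel=0.25, abs=small_grid.voxel_volume_ml)

    def test_smallest_tumours_span_about_20_voxels(self, small_grid):
        # a 0.18 ml tumour is ~20 voxels at the reference voxel size
        spec = pr.TumourSpec("uniform", 0.18, 20.0, seed=2)
        mask = phantom.sample_tumour_shape(spec, small_grid)
        assert 14 <= mask.sum() <= 26

    def test_single_connected_component(self, small_grid):
        from scipy import ndimage

        spec = pr.TumourSpec("uniform", 3.0, 20.0, elongation=0.4, seed=3)
        mask = phantom.sample_tumour_shape(spec, small_grid)
        _, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_deterministic_given_seed(self, small_grid):
        spec = pr.TumourSpec("hollow", 2.5, 18.0, seed=7)
        m1 = phantom.sample_tumour_shape(spec, small_grid)
        m2 = phantom.sample_tumour_shape(spec, small_grid)
        assert np.array_equal(m1, m2)

    def test_sphere_is_near_spherical_on_fine_grid(self):
        # the mesh area estimator carries a small staircase bias, so even a
        # perfectly voxelized sphere measures slightly below 1
        grid = pr.VoxelGrid((48, 48, 48), (1.0, 1.0, 1.0))
        spec = pr.TumourSpec("uniform", 4.19, 20.0, elongation=0.0, perturbation=0.0, seed=0)
        mask = phantom.sample_tumour_shape(spec, grid)
        assert quantify.sphericity(mask, grid.voxel_size) >= 0.90

    def test_elongation_decreases_sphericity(self):
        grid = pr.VoxelGrid((64, 64, 64), (1.0, 1.0, 1.0))
        values = []
        for e in (0.0, 0.4, 0.8):
            spec = pr.TumourSpec("uniform", 4.0, 20.0, elongation=e, perturbation=0.0, seed=5)
            mask = phantom.sample_tumour_shape(spec, grid)
            values.append(quantify.sphericity(mask, grid.voxel_size))
        assert values[0] > values[1] > values[2]

    def test_subvoxel_volume_rejected_with_minimum_named(self):
        coarse = pr.VoxelGrid((24, 24, 24), (3.0, 3.0, 3.0))  # voxel = 0.027 ml
        with pytest.raises(ValueError, match="minimum representable"):
            phantom.sample_tumour_shape(pr.TumourSpec("uniform", 0.01, 20.0), coarse)


class TestPatterns:
    @pytest.fixture()
    def sphere_mask(self, small_grid):
        spec = pr.TumourSpec("uniform", 4.19, 20.0, perturbation=0.0, seed=0)
        return phantom.sample_tumour_shape(spec, small_grid)

    def test_uniform_fills_mask_only(self, small_grid, sphere_mask):
        spec = pr.TumourSpec("uniform", 4.19, 20.0, seed=0)
        patch, _ = phantom.apply_pattern(sphere_mask, spec, 2.0, small_grid)
        assert np.all(patch[sphere_mask] == 20.0)
        assert np.all(patch[~sphere_mask] == 0.0)

    def test_hollow_core_at_background_shell_partitions_mask(self, small_grid, sphere_mask):
        spec = pr.TumourSpec("hollow", 4.19, 20.0, seed=0)
        patch, info = phantom.apply_pattern(sphere_mask, spec, 2.0, small_grid)
        core, shell = info["core_mask"], info["shell_mask"]
        assert not np.logical_and(core, shell).any()
        assert np.array_equal(np.logical_or(core, shell), sphere_mask)
        assert core.any() and shell.any()
        assert np.all(patch[core] == 2.0)
        assert np.all(patch[shell] == 20.0)

    def test_hollow_core_depth_is_half_equivalent_radius(self, small_grid, sphere_mask):
        # for a sphere of radius r the core is (almost) a sphere of radius r/2,
        # i.e. about 1/8 of the voxels
        spec = pr.TumourSpec("hollow", 4.19, 20.0, seed=0)
        _, info = phantom.apply_pattern(sphere_mask, spec, 2.0, small_grid)
        frac = info["core_mask"].sum() / sphere_mask.sum()
        assert 0.04 <= frac <= 0.22

    def test_halves_partition_and_activities(self, small_grid, sphere_mask):
        spec = pr.TumourSpec("halves", 4.19, 24.0, secondary_activity=12.0, seed=0)
        patch, info = phantom.apply_pattern(sphere_mask, spec, 2.0, small_grid)
        a, b = info["half_masks"]
        assert not np.logical_and(a, b).any()
        assert np.array_equal(np.logical_or(a, b), sphere_mask)
        assert set(np.unique(patch[sphere_mask])) == {12.0, 24.0}
        assert info["half_ratio"] == pytest.approx(2.0)

    def test_halves_with_equal_activities_degenerates_to_uniform(self, small_grid, sphere_mask):
        spec = pr.TumourSpec("halves", 4.19, 20.0, secondary_activity=20.0, seed=0)
        patch, _ = phantom.apply_pattern(sphere_mask, spec, 2.0, small_grid)
        uniform = np.zeros_like(patch)
        uniform[sphere_mask] = 20.0
        assert np.array_equal(patch, uniform)

    def test_halves_on_single_voxel_rejected(self, small_grid):
        mask = np.zeros(small_grid.shape, dtype=bool)
        mask[24, 24, 12] = True
        spec = pr.TumourSpec("halves", 4.19, 20.0, secondary_activity=10.0, seed=0)
        with pytest.raises(ValueError):
            phantom.apply_pattern(mask, spec, 2.0, small_grid)

    def test_empty_mask_rejected(self, small_grid):
        spec = pr.TumourSpec("uniform", 1.0, 20.0)
        with pytest.raises(ValueError):
            phantom.apply_pattern(np.zeros(small_grid.shape, bool), spec, 2.0, small_grid)


class TestAssembly:
    @pytest.mark.parametrize("pattern,secondary", [("uniform", None), ("halves", 14.0), ("hollow", None)])
    def test_tumour_to_background_ratio_is_ten(self, torso, small_grid, pattern, secondary):
        spec = pr.TumourSpec(pattern, 2.0, 35.0, secondary_activity=secondary, seed=4)
        mask = phantom.sample_tumour_shape(spec, small_grid)
        truth, record = phantom.assemble_ground_truth(torso, mask, spec, 11)
        assert record.background_activity == pytest.approx(3.5)
        assert truth.values[record.mask].max() / record.background_activity == pytest.approx(10.0)

    def test_tumour_placed_inside_left_lung(self, torso, small_grid):
        spec = pr.TumourSpec("uniform", 3.0, 20.0, seed=5)
        mask = phantom.sample_tumour_shape(spec, small_grid)
        _, record = phantom.assemble_ground_truth(torso, mask, spec, 3)
        assert not np.logical_and(record.mask, ~torso.lung_mask).any()

    def test_placement_seed_moves_centroid_not_shape(self, torso, small_grid):
        spec = pr.TumourSpec("uniform", 2.0, 20.0, seed=6)
        mask = phantom.sample_tumour_shape(spec, small_grid)
        _, r1 = phantom.assemble_ground_truth(torso, mask, spec, 1)
        _, r2 = phantom.assemble_ground_truth(torso, mask, spec, 2)
        assert r1.centroid != r2.centroid
        assert r1.mask.sum() == r2.mask.sum()

    def test_oversized_tumour_rejected(self, torso, small_grid):
        spec = pr.TumourSpec("uniform", 150.0, 20.0, seed=0)
        mask = phantom.sample_tumour_shape(spec, small_grid)
        with pytest.raises(ValueError, match="lung"):
            phantom.assemble_ground_truth(torso, mask, spec, 0)


class TestCrop:
    def test_crop_shape_and_roundtrip(self, small_grid):
        rng = np.random.default_rng(0)
        vol = rng.random(small_grid.shape)
        patch, offset = phantom.crop_around_tumour(vol, (24.0, 24.0, 12.0), (16, 16, 12))
        assert patch.shape == (16, 16, 12)
        restored = phantom.embed_patch(np.zeros_like(vol), patch, offset)
        sl = tuple(slice(o, o + c) for o, c in zip(offset, patch.shape))
        assert np.array_equal(restored[sl], vol[sl])

    def test_corner_tumour_crop_is_clamped(self, small_grid):
        vol = np.zeros(small_grid.shape)
        patch, offset = phantom.crop_around_tumour(vol, (0.0, 0.0, 0.0), (16, 16, 12))
        assert patch.shape == (16, 16, 12)
        assert offset == (0, 0, 0)

    def test_crop_larger_than_volume_rejected(self, small_grid):
        with pytest.raises(ValueError):
            phantom.crop_around_tumour(np.zeros(small_grid.shape), (0, 0, 0), (64, 64, 64))
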