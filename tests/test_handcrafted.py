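import numpy as np
import pytest

from nodalrad.cohort import render_node_volume
from nodalrad.errors import ConfigurationError, EmptySegmentationError
from nodalrad.handcrafted import (
    DiscretizationConfig,
    assemble_handcrafted,
    compute_first_order,
    compute_glcm,
    compute_shape,
    compute_voxel_map,
    select_features,
)
from nodalrad.preprocessing import ImageVolume, NodeVOI


def _voi(values, mask=None, spacing=(1.0, 1.0, 1.0)):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, bool)
    return NodeVOI(ImageVolume(values, spacing), mask)


class TestFirstOrder:
    def test_constant_region(self):
        fo = compute_first_order(_voi(np.full((5, 5, 4), 40.0)))
        assert fo["firstorder.mean"] == 40.0
        assert fo["firstorder.variance"] == 0.0
        assert fo["firstorder.range"] == 0.0
        assert fo["firstorder.entropy"] == 0.0

    def test_enumerated_moments(self):
        # {0, 0, 2, 2}: mean 1, population variance 1, symmetric -> skewness 0
        fo = compute_first_order(_voi(np.array([0.0, 0.0, 2.0, 2.0]).reshape(4, 1, 1)))
        assert fo["firstorder.mean"] == 1.0
        assert fo["firstorder.variance"] == 1.0
        assert fo["firstorder.skewness"] == 0.0

    def test_energy_is_sum_of_squares(self):
        fo = compute_first_order(_voi(np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)))
        assert fo["firstorder.energy"] == 14.0

    def test_only_in_mask_voxels_counted(self):
        values = np.full((4, 4, 1), 1000.0)
        mask = np.zeros((4, 4, 1), bool)
        mask[0, 0, 0] = mask[1, 1, 0] = True
        values[0, 0, 0] = values[1, 1, 0] = 40.0
        fo = compute_first_order(_voi(values, mask))
        assert fo["firstorder.mean"] == 40.0
        assert fo["firstorder.maximum"] == 40.0

    def test_invariant_to_voxel_permutation(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(50, 15, size=(3, 4, 5))
        fo1 = compute_first_order(_voi(vals))
        fo2 = compute_first_order(_voi(rng.permutation(vals.ravel()).reshape(3, 4, 5)))
        for k in fo1:
            assert fo1[k] == pytest.approx(fo2[k])


class TestShape:
    def test_single_voxel_volume(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        s = compute_shape(mask, (1.0, 1.0, 1.0))
        assert s["shape.volume_mm3"] == 1.0

    def test_digital_ball_matches_analytic_sphere(self):
        _, mask = render_node_volume((10, 10, 10), 40.0, 0.0, (1, 1, 1), 0)
        s = compute_shape(mask, (1.0, 1.0, 1.0))
        assert s["shape.volume_mm3"] == pytest.approx(4188.79, rel=0.03)
        assert 0.95 <= s["shape.sphericity"] <= 1.05
        assert s["shape.elongation"] == pytest.approx(1.0, abs=0.03)
        assert s["shape.max_diameter_mm"] == pytest.approx(20.0, rel=0.03)

    def test_shape_ignores_intensities(self):
        _, mask = render_node_volume((6, 6, 6), 40.0, 0.0, (1, 1, 1), 0)
        assert compute_shape(mask, (1, 1, 1)) == compute_shape(mask, (1, 1, 1))

    def test_rotation_by_90_degrees_about_z(self):
        _, mask = render_node_volume((8, 5, 6), 40.0, 0.0, (1, 1, 1), 0)
        rot = np.rot90(mask, k=1, axes=(0, 1))
        a = compute_shape(mask, (1, 1, 1))
        b = compute_shape(rot, (1, 1, 1))
        for key in ("shape.volume_mm3", "shape.sphericity", "shape.max_diameter_mm"):
            assert a[key] == pytest.approx(b[key], rel=0.01)

    def test_anisotropic_spacing_volume(self):
        mask = np.ones((4, 4, 2), bool)
        s = compute_shape(mask, (0.7, 0.7, 2.0))
        assert s["shape.volume_mm3"] == pytest.approx(32 * 0.7 * 0.7 * 2.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptySegmentationError):
            compute_shape(np.zeros((3, 3, 3), bool), (1, 1, 1))


class TestGlcm:
    # 2x2x1 grid, two gray levels laid out in rows:
    #   axis 0 (rows): [0, 0] / [1, 1] after discretization with bin width 25
    grid = np.array([[0.0, 0.0], [25.0, 25.0]]).reshape(2, 2, 1)

    def test_within_row_offset_sees_equal_pairs(self):
        g = compute_glcm(_voi(self.grid), offsets=((0, 1, 0),))
        assert g["glcm.contrast"] == 0.0
        assert g["glcm.joint_energy"] == pytest.approx(0.5)  # P(0,0)=P(1,1)=0.5

    def test_across_row_offset_sees_unequal_pairs(self):
        g = compute_glcm(_voi(self.grid), offsets=((1, 0, 0),))
        assert g["glcm.contrast"] == 1.0  # P(0,1)=P(1,0)=0.5

    def test_constant_region(self):
        g = compute_glcm(_voi(np.full((3, 3, 2), 80.0)))
        assert g["glcm.joint_energy"] == 1.0
        assert g["glcm.joint_entropy"] == 0.0

    def test_matrix_restricted_to_in_mask_pairs(self):
        values = self.grid.copy()
        mask = np.ones((2, 2, 1), bool)
        mask[1, :, 0] = False  # only the 0-level row remains
        g = compute_glcm(_voi(values, mask), offsets=((0, 1, 0),))
        assert g["glcm.joint_energy"] == 1.0

    def test_contrast_zero_iff_constant_along_offsets(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 100, size=(4, 4, 4))
        g = compute_glcm(_voi(vals), DiscretizationConfig(bin_width=1000.0))
        assert g["glcm.contrast"] == 0.0  # one bin -> constant discretized image


class TestVoxelMaps:
    def test_constant_voi_gives_constant_map(self):
        voi = _voi(np.full((4, 4, 3), 55.0))
        vmap = compute_voxel_map(voi, "firstorder.mean", kernel_radius=1)
        assert np.allclose(vmap.voxels[voi.mask], 55.0)

    def test_full_kernel_reduces_to_global_feature(self, cube_voi):
        vmap = compute_voxel_map(cube_voi, "firstorder.mean", kernel_radius=10)
        expected = compute_first_order(cube_voi)["firstorder.mean"]
        assert np.allclose(vmap.voxels[cube_voi.mask], expected)

    def test_map_mean_close_to_global_mean(self, cube_voi):
        vmap = compute_voxel_map(cube_voi, "firstorder.mean", kernel_radius=1)
        global_mean = compute_first_order(cube_voi)["firstorder.mean"]
        assert np.nanmean(vmap.voxels[cube_voi.mask]) == pytest.approx(
            global_mean, rel=0.15
        )

    def test_out_of_mask_carries_sentinel(self):
        values = np.zeros((3, 3, 1))
        mask = np.zeros((3, 3, 1), bool)
        mask[1, 1, 0] = True
        vmap = compute_voxel_map(_voi(values, mask), "firstorder.mean", 1)
        assert np.isnan(vmap.voxels[0, 0, 0])

    def test_unknown_feature_rejected(self, cube_voi):
        with pytest.raises(ConfigurationError):
            compute_voxel_map(cube_voi, "shape.volume_mm3", 1)


class TestAssemble:
    def test_block_lengths_sum(self, cube_voi):
        vec = assemble_handcrafted(cube_voi)
        fo = select_features(vec, ("firstorder",))
        sh = select_features(vec, ("shape",))
        gl = select_features(vec, ("glcm",))
        assert len(fo) + len(sh) + len(gl) == len(vec)

    def test_subset_excludes_texture_block(self, cube_voi):
        vec = assemble_handcrafted(cube_voi)
        sub = select_features(vec, ("firstorder", "shape"))
        assert not any(k.startswith("glcm.") for k in sub)
        assert any(k.startswith("shape.") for k in sub)

    def test_deterministic_on_identical_vois(self, cube_voi):
        v1 = assemble_handcrafted(cube_voi)
        v2 = assemble_handcrafted(cube_voi)
        assert v1 == v2
        assert list(v1) == list(v2)  # stable ordering
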