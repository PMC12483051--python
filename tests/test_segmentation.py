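"""Thresholding, component statistics, sphericity and shape filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from lymphmorph.segmentation import (
    SegmentationParams,
    apply_exclusion,
    component_surface_area,
    compute_sphericity,
    filter_components,
    label_components,
    threshold_mask,
)
from lymphmorph.presets import segmentation_params
from lymphmorph.stacks import BinaryMask, ImageStack

from conftest import make_ball_mask, make_tube_mask


class TestThreshold:
    def test_all_zero_stack_gives_empty_mask(self):
        stack = ImageStack(np.zeros((5, 5, 5)), (1, 1, 1))
        assert threshold_mask(stack, 173).foreground_count == 0

    def test_single_bright_voxel_at_printed_threshold(self):
        vox = np.zeros((6, 6, 6))
        vox[2, 3, 4] = 200.0
        mask = threshold_mask(ImageStack(vox, (1, 1, 1)), 173)
        assert mask.foreground_count == 1
        assert mask.voxels[2, 3, 4]

    def test_zero_threshold_selects_everything(self):
        stack = ImageStack(np.zeros((4, 4, 4)), (1, 1, 1))
        assert threshold_mask(stack, 0).foreground_count == 64

    def test_raising_threshold_never_adds_foreground(self):
        rng = np.random.default_rng(5)
        stack = ImageStack(rng.random((10, 10, 10)) * 300, (1, 1, 1))
        prev = threshold_mask(stack, 50).voxels
        for t in (100, 150, 250):
            cur = threshold_mask(stack, t).voxels
            assert not np.any(cur & ~prev)
            prev = cur


class TestLabelComponents:
    def test_corner_touching_voxels_depend_on_connectivity(self):
        vox = np.zeros((4, 4, 4), bool)
        vox[0, 0, 0] = vox[1, 1, 1] = True
        mask = BinaryMask(vox, (1, 1, 1))
        assert label_components(mask, connectivity=26).n_components == 1
        assert label_components(mask, connectivity=6).n_components == 2

    def test_empty_mask_has_no_components(self):
        mask = BinaryMask(np.zeros((4, 4, 4), bool), (1, 1, 1))
        assert label_components(mask).n_components == 0

    def test_ball_voxel_count_matches_brute_force(self):
        mask = make_ball_mask(5.0)
        comps = label_components(mask)
        assert comps.n_components == 1
        # direct enumeration over all centers
        half = (np.asarray(mask.shape) - 1) // 2
        zz, yy, xx = np.mgrid[: mask.shape[0], : mask.shape[1], : mask.shape[2]]
        expected = int(
            ((zz - half[0]) ** 2 + (yy - half[1]) ** 2 + (xx - half[2]) ** 2 <= 25).sum()
        )
        assert comps.table["voxel_count"].iloc[0] == expected

    def test_intensity_stats(self, stack_from_mask):
        mask = make_ball_mask(3.0)
        stack = stack_from_mask(mask, fg=200.0, bg=0.0)
        stack.voxels[tuple(np.argwhere(mask.voxels)[0])] = 500.0
        comps = label_components(mask, stack=stack)
        assert comps.table["max_intensity"].iloc[0] == 500.0
        assert 200.0 < comps.table["mean_intensity"].iloc[0] < 210.0


class TestSphericity:
    def test_unit_sphere_is_one(self):
        assert compute_sphericity(4 * np.pi / 3, 4 * np.pi) == pytest.approx(1.0)

    def test_unit_cube_value(self):
        assert compute_sphericity(1.0, 6.0) == pytest.approx((np.pi / 6) ** (1 / 3), abs=1e-4)

    def test_long_cylinder_lands_inside_vessel_band(self):
        # r=1, h=100: V = 100π, A = 202π
        psi = compute_sphericity(100 * np.pi, 202 * np.pi)
        assert psi == pytest.approx(0.352, abs=0.005)
        assert 0.0566 <= psi <= 0.563

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_sphericity(0.0, 1.0)
        with pytest.raises(ValueError):
            compute_sphericity(1.0, -1.0)

    def test_rasterized_ball_sphericity_approaches_one(self):
        for r in (8.0, 12.0):
            comps = label_components(make_ball_mask(r))
            assert comps.table["sphericity"].iloc[0] == pytest.approx(1.0, abs=0.05)

    def test_tube_sphericity_decreases_with_elongation(self):
        values = []
        for length in (20, 40, 80, 160):
            comps = label_components(make_tube_mask(3.0, length))
            values.append(comps.table["sphericity"].iloc[0])
        assert all(a > b for a, b in zip(values, values[1:]))


class TestSurfaceArea:
    def test_ball_area_close_to_sphere(self):
        mask = make_ball_mask(8.0)
        comps = label_components(mask)
        area = component_surface_area(comps.labels, 1, mask.spacing)
        assert area == pytest.approx(4 * np.pi * 64, rel=0.05)
        assert comps.table["surface_area_um2"].iloc[0] == pytest.approx(area, rel=1e-6)

    def test_single_voxel_mesh_has_positive_but_unreliable_area(self):
        # the smoothed mesh of one voxel is far below the voxel's 6-face
        # surface: area is documented as unreliable below ~30 voxels and
        # such objects are gated by voxel count before sphericity is used
        vox = np.zeros((3, 3, 3), bool)
        vox[1, 1, 1] = True
        comps = label_components(BinaryMask(vox, (1, 1, 1)))
        area = comps.table["surface_area_um2"].iloc[0]
        assert 0 < area < 6.0

    def test_rod_area_scales_linearly_with_length(self):
        def rod_area(length):
            vox = np.zeros((5, 5, length + 4), bool)
            vox[2, 2, 2 : 2 + length] = True
            comps = label_components(BinaryMask(vox, (1, 1, 1)))
            return comps.table["surface_area_um2"].iloc[0]

        a20, a40 = rod_area(20), rod_area(40)
        assert a40 / a20 == pytest.approx(2.0, rel=0.15)
        # a 1-voxel rod is below the reliable-size floor: the mesh reads low
        assert 0.2 * 82 < a20 < 82


class TestFilter:
    def test_small_component_removed_by_voxel_count(self, stack_from_mask):
        mask = make_ball_mask(2.5)  # ~65 voxels, below the 173 preset floor
        comps = label_components(mask)
        assert 0 < comps.table["voxel_count"].iloc[0] <= 173
        out = filter_components(comps, segmentation_params("lyve1", 100.0))
        assert out.foreground_count == 0

    def test_ball_removed_tube_retained_by_sphericity_band(self):
        # one big ball (psi ~ 1) and one long tube (psi ~ 0.3) in one scene
        scene = np.zeros((40, 40, 130), bool)
        ball = make_ball_mask(9.0).voxels
        scene[4 : 4 + ball.shape[0], 4 : 4 + ball.shape[1], 4 : 4 + ball.shape[2]] |= ball
        tube = make_tube_mask(4.0, 100).voxels
        scene[
            22 : 22 + tube.shape[0], 22 : 22 + tube.shape[1], 10 : 10 + tube.shape[2]
        ] |= tube
        mask = BinaryMask(scene, (1, 1, 1))
        comps = label_components(mask)
        assert comps.n_components == 2
        assert (comps.table["voxel_count"] > 2000).all()
        out = filter_components(comps, segmentation_params("lyve1", 100.0))
        # only the tube survives the [0.0566, 0.563] band
        kept = label_components(out)
        assert kept.n_components == 1
        assert kept.table["sphericity"].iloc[0] < 0.563

    def test_empty_input_empty_output(self):
        mask = BinaryMask(np.zeros((4, 4, 4), bool), (1, 1, 1))
        out = filter_components(label_components(mask), segmentation_params("lyve1", 1.0))
        assert out.foreground_count == 0

    def test_params_validation(self):
        with pytest.raises(ValueError):
            SegmentationParams(100, 10, 0.6, 0.5)
        with pytest.raises(ValueError):
            SegmentationParams(100, 0, 0.1, 0.5)
        with pytest.raises(ValueError):
            SegmentationParams(100, 10, 0.1, 0.5, connectivity=10)


class TestExclusion:
    def test_empty_exclusion_is_identity(self):
        mask = make_ball_mask(3.0)
        excl = BinaryMask(np.zeros(mask.shape, bool), mask.spacing)
        out = apply_exclusion(mask, excl)
        np.testing.assert_array_equal(out.voxels, mask.voxels)

    def test_total_exclusion_empties_mask(self):
        mask = make_ball_mask(3.0)
        assert apply_exclusion(mask, mask).foreground_count == 0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        data=hnp.arrays(bool, (5, 5, 5)),
        excl=hnp.arrays(bool, (5, 5, 5)),
    )
    def test_set_arithmetic(self, data, excl):
        m = BinaryMask(data, (1, 1, 1))
        e = BinaryMask(excl, (1, 1, 1))
        out = apply_exclusion(m, e)
        assert out.foreground_count == m.foreground_count - int((data & excl).sum())

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apply_exclusion(
                BinaryMask(np.zeros((3, 3, 3), bool), (1, 1, 1)),
                BinaryMask(np.zeros((4, 4, 4), bool), (1, 1, 1)),
            )


def test_segmentation_is_deterministic(stack_from_mask):
    mask = make_tube_mask(3.0, 40)
    stack = stack_from_mask(mask, fg=300.0, bg=10.0)
    from lymphmorph.segmentation import segment_stack

    params = segmentation_params("vegfr3", 150.0)
    a = segment_stack(stack, params)
    b = segment_stack(stack, params)
    np.testing.assert_array_equal(a.voxels, b.voxels)
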