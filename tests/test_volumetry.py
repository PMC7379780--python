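"""Unit tests for the 3D volumetry operations."""

import math

import numpy as np
import pandas as pd
import pytest

from plaquekit.volumetry import (
    PlaqueObject,
    SegmentationParams,
    VoxelStack,
    control_calibration,
    exposed_surface_area,
    inclusion_filter,
    make_shell,
    match_plaques,
    percent_surface_contact,
    plaque_dynamics,
    remove_background,
    segment_plaques,
    surface_area_from_mask,
)


def _stack_from(x04=None, tr=None, iba1=None, voxel_size=(1.0, 1.0, 1.0), shape=None):
    for given in (x04, tr, iba1):
        if given is not None:
            shape = given.shape
            break
    shape = shape or (9, 9, 9)

    def arr(a):
        if a is None:
            return np.zeros(shape, dtype=np.uint16)
        return a.astype(np.uint16)

    return VoxelStack({"X04": arr(x04), "TR": arr(tr), "IBA1": arr(iba1)}, voxel_size)


class TestRemoveBackground:
    def test_all_voxels_just_below_threshold_removed(self):
        stack = _stack_from(x04=np.full((3, 3, 3), 499))
        out = remove_background(stack, 500)
        assert (out.channels["X04"] == 0).all()

    def test_zero_threshold_is_identity(self):
        arr = np.arange(27).reshape(3, 3, 3)
        stack = _stack_from(x04=arr)
        out = remove_background(stack, 0)
        np.testing.assert_array_equal(out.channels["X04"], arr)

    def test_exact_threshold_survives(self):
        vals = np.array([0, 400, 500, 600]).repeat(7)[:27].reshape(3, 3, 3)
        out = remove_background(_stack_from(x04=vals), 500)
        survived = out.channels["X04"]
        np.testing.assert_array_equal(survived[vals >= 500], vals[vals >= 500])
        assert (survived[vals < 500] == 0).all()


class TestSegmentation:
    def test_solid_cube_volume(self):
        x04 = np.zeros((9, 9, 9))
        x04[3:6, 3:6, 3:6] = 1000
        objs = segment_plaques(
            _stack_from(x04=x04), "X04", SegmentationParams(min_object_voxels=1)
        )
        assert len(objs) == 1
        assert objs[0].volume == pytest.approx(27.0)
        assert objs[0].surface_area == pytest.approx(6 * 9.0)

    def test_corner_touching_cubes_split_by_connectivity(self):
        x04 = np.zeros((10, 10, 10))
        x04[2:4, 2:4, 2:4] = 1000
        x04[4:6, 4:6, 4:6] = 1000  # touch only at the corner voxel diagonal
        stack = _stack_from(x04=x04)
        six = segment_plaques(stack, "X04", SegmentationParams(connectivity=6, min_object_voxels=1))
        twentysix = segment_plaques(stack, "X04", SegmentationParams(connectivity=26, min_object_voxels=1))
        assert len(six) == 2
        assert len(twentysix) == 1

    def test_min_object_voxels_filters_small_components(self):
        x04 = np.zeros((9, 9, 9))
        x04[1, 1, 1:4] = 1000  # 3 voxels
        objs = segment_plaques(
            _stack_from(x04=x04), "X04", SegmentationParams(min_object_voxels=5)
        )
        assert objs == []

    def test_empty_segmentation_returns_empty_list(self):
        objs = segment_plaques(_stack_from(), "X04", SegmentationParams())
        assert objs == []


class TestSurfaceArea:
    def test_single_voxel_isotropic(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        assert surface_area_from_mask(mask, (1, 1, 1)) == pytest.approx(6.0)

    def test_two_voxel_bar(self):
        mask = np.zeros((3, 3, 4), bool)
        mask[1, 1, 1:3] = True
        assert surface_area_from_mask(mask, (1, 1, 1)) == pytest.approx(10.0)

    def test_anisotropic_faces(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        # z faces: 2 * (dy*dx) = 2; y and x faces: 4 * 1.5 = 6
        assert surface_area_from_mask(mask, (1.5, 1.0, 1.0)) == pytest.approx(8.0)


class TestShell:
    def test_six_neighborhood_single_voxel(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        assert make_shell(mask, 6).sum() == 6

    def test_twentysix_neighborhood_single_voxel(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        assert make_shell(mask, 26).sum() == 26

    def test_shell_clipped_at_image_border(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[0, 0, 0] = True
        shell = make_shell(mask, 26)
        assert shell.sum() == 7  # only the in-bounds corner neighborhood

    def test_empty_object_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            make_shell(np.zeros((3, 3, 3), bool))


class TestContactAndExposure:
    def _shell(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        return make_shell(mask, 6)

    def test_no_iba1_gives_zero(self):
        assert percent_surface_contact(self._shell(), np.zeros((5, 5, 5), bool)) == 0.0

    def test_full_iba1_gives_hundred(self):
        assert percent_surface_contact(self._shell(), np.ones((5, 5, 5), bool)) == 100.0

    def test_half_covered_shell(self):
        shell = self._shell()
        iba1 = np.zeros((5, 5, 5), bool)
        covered = np.argwhere(shell)[:3]
        iba1[tuple(covered.T)] = True
        assert percent_surface_contact(shell, iba1) == pytest.approx(50.0)

    def test_empty_shell_is_an_error(self):
        with pytest.raises(ValueError, match="shell"):
            percent_surface_contact(np.zeros((3, 3, 3), bool), np.zeros((3, 3, 3), bool))

    @pytest.mark.parametrize(
        "surface,contact,expected", [(10.0, 100.0, 0.0), (10.0, 0.0, 10.0), (10.0, 25.0, 7.5)]
    )
    def test_exposed_surface_arithmetic(self, surface, contact, expected):
        assert exposed_surface_area(surface, contact) == pytest.approx(expected)


class TestMatching:
    def _objects(self, masks, channel):
        x04 = np.zeros((12, 12, 12))
        for m in masks:
            x04[m] = 1000
        stack = _stack_from(x04=x04) if channel == "X04" else _stack_from(tr=x04)
        return segment_plaques(stack, channel, SegmentationParams(min_object_voxels=1))

    def test_identical_masks_pair_with_full_overlap(self):
        region = (slice(2, 5), slice(2, 5), slice(2, 5))
        x = self._objects([region], "X04")
        t = self._objects([region], "TR")
        pairs, un_tr, un_x04, _ = match_plaques(x, t)
        assert len(pairs) == 1 and pairs[0][2] == 27
        assert un_tr == [] and un_x04 == []

    def test_tr_without_x04_overlap_is_new_deposit(self):
        x = self._objects([(slice(1, 3), slice(1, 3), slice(1, 3))], "X04")
        t = self._objects([(slice(8, 10), slice(8, 10), slice(8, 10))], "TR")
        pairs, un_tr, _, _ = match_plaques(x, t)
        assert pairs == []
        assert un_tr == [t[0].id]

    def test_larger_overlap_wins(self):
        # X04 cube 2x2x2 at origin-ish; TR-a overlaps 8 voxels, TR-b overlaps 2
        x = self._objects([(slice(2, 4), slice(2, 4), slice(2, 4))], "X04")
        tr = np.zeros((12, 12, 12))
        tr[2:4, 2:4, 2:4] = 1000  # TR-a: full 8-voxel overlap
        tr[3, 8:10, 8:10] = 1000  # TR-b: disjoint
        t = segment_plaques(_stack_from(tr=tr), "TR", SegmentationParams(min_object_voxels=1))
        pairs, un_tr, _, _ = match_plaques(x, t)
        by_overlap = {tr_id: ov for _, tr_id, ov in pairs}
        assert max(by_overlap.values()) == 8
        assert len(pairs) == 1 and len(un_tr) == 1


class TestDynamics:
    def _pair(self, x04_region, tr_region):
        arr_x = np.zeros((12, 12, 12))
        arr_x[x04_region] = 1000
        arr_t = np.zeros((12, 12, 12))
        arr_t[tr_region] = 1000
        stack = _stack_from(x04=arr_x, tr=arr_t)
        params = SegmentationParams(min_object_voxels=1)
        x = segment_plaques(stack, "X04", params)
        t = segment_plaques(stack, "TR", params)
        return (x[0] if x else None), t[0]

    def test_identical_masks_give_zero_growth_unit_fold_change(self):
        region = (slice(2, 5), slice(2, 5), slice(2, 5))
        x, t = self._pair(region, region)
        dyn = plaque_dynamics(t, x, np.zeros((12, 12, 12), bool))
        assert dyn.growth == 0.0
        assert dyn.fold_change == pytest.approx(1.0)

    def test_growth_and_fold_change_arithmetic(self):
        x, t = self._pair(
            (slice(2, 5), slice(2, 5), slice(2, 5)),  # 27 voxels
            (slice(2, 5), slice(2, 5), slice(2, 6)),  # 36 voxels
        )
        dyn = plaque_dynamics(t, x, np.zeros((12, 12, 12), bool))
        assert dyn.growth == pytest.approx(9.0)
        assert dyn.fold_change == pytest.approx(36 / 27)

    def test_new_deposit_has_missing_fold_change(self):
        _, t = self._pair((slice(0, 0), slice(0, 0), slice(0, 0)), (slice(2, 4),) * 3)
        dyn = plaque_dynamics(t, None, np.zeros((12, 12, 12), bool))
        assert dyn.fold_change is None
        assert dyn.growth == pytest.approx(dyn.tr_volume)


class TestInclusionFilter:
    def _obj(self, edge, neighbor, oid=1):
        return PlaqueObject(
            id=oid, channel="TR", coords=np.array([[1, 1, 1]]), image_shape=(3, 3, 3),
            voxel_size=(1, 1, 1), volume=1.0, surface_area=6.0,
            shell_coords=np.empty((0, 3), int), centroid=(1, 1, 1),
            distance_to_stack_edge=edge, distance_to_nearest_plaque=neighbor,
        )

    def test_isolated_central_plaque_kept(self):
        kept, rejected = inclusion_filter([self._obj(80.0, math.inf)])
        assert len(kept) == 1 and rejected == []

    def test_edge_violation_rejected_with_reason(self):
        kept, rejected = inclusion_filter([self._obj(10.0, math.inf)])
        assert kept == [] and rejected[0][1] == "edge"

    def test_close_neighbors_rejected_with_reason(self):
        objs = [self._obj(80.0, 30.0, 1), self._obj(80.0, 30.0, 2)]
        kept, rejected = inclusion_filter(objs)
        assert kept == []
        assert [r for _, r in rejected] == ["neighbor", "neighbor"]

    def test_partition_is_conserved(self):
        objs = [self._obj(10.0, 30.0, 1), self._obj(80.0, 30.0, 2), self._obj(80.0, 80.0, 3)]
        kept, rejected = inclusion_filter(objs)
        assert len(kept) + len(rejected) == len(objs)
        assert all(len(reason) > 0 for _, reason in rejected)


class TestControlCalibration:
    def test_identity_pairs_give_unit_slope_and_r2(self):
        df = pd.DataFrame(
            {"x04_volume": [10.0, 20, 30], "tr_volume": [10.0, 20, 30],
             "growth": [0.0, 0, 0], "fold_change": [1.0, 1, 1]}
        )
        cal = control_calibration(df)
        assert cal["slope"] == pytest.approx(1.0)
        assert cal["intercept"] == pytest.approx(0.0)
        assert cal["r_squared"] == pytest.approx(1.0)
        assert cal["mean_growth"] == 0.0 and cal["mean_fold_change"] == 1.0

    def test_exact_ols_on_proportional_pairs(self):
        df = pd.DataFrame(
            {"x04_volume": [10.0, 20, 30], "tr_volume": [12.0, 24, 36],
             "growth": [2.0, 4, 6], "fold_change": [1.2, 1.2, 1.2]}
        )
        cal = control_calibration(df)
        assert cal["slope"] == pytest.approx(1.2)
        assert cal["r_squared"] == pytest.approx(1.0)

    def test_zero_variance_is_an_error(self):
        df = pd.DataFrame(
            {"x04_volume": [10.0, 10, 10], "tr_volume": [12.0, 11, 13],
             "growth": [2.0, 1, 3], "fold_change": [1.2, 1.1, 1.3]}
        )
        with pytest.raises(ValueError, match="variance"):
            control_calibration(df)

    def test_too_few_pairs_is_an_error(self):
        df = pd.DataFrame(
            {"x04_volume": [10.0, 20], "tr_volume": [12.0, 24],
             "growth": [2.0, 4], "fold_change": [1.2, 1.2]}
        )
        with pytest.raises(ValueError, match="3"):
            control_calibration(df)
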