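import numpy as np
import pytest
from scipy import ndimage as ndi

from clonepipe.topology import (
    assemble_foci,
    distance_to_centroid,
    distance_to_patch_border,
    link_patches,
    partition_border_centre,
    split_foci_plane,
    track_cells,
)
from conftest import random_blob

VS = (1.0, 1.0)

# adjacency used throughout: 8-connected in-plane, face-adjacent in Z
STRUCT_Z = np.zeros((3, 3, 3), dtype=int)
STRUCT_Z[1] = 1
STRUCT_Z[0, 1, 1] = STRUCT_Z[2, 1, 1] = 1


class TestLinkPatches:
    def test_column_is_one_patch_with_exact_volume(self):
        masks = np.zeros((5, 32, 32), dtype=bool)
        masks[:, 5:15, 5:15] = True
        patches = link_patches(masks, "g", (0.5, 2.0))
        assert len(patches) == 1
        assert patches[0].volume_um3 == pytest.approx(500 * 0.5 * 0.5 * 2.0)
        assert patches[0].z_range == (0, 4)
        assert patches[0].n_components_2d == 5

    def test_y_split_stays_one_patch(self):
        masks = np.zeros((2, 32, 32), dtype=bool)
        masks[0, 10:14, 4:28] = True          # bar
        masks[1, 4:18, 6:10] = True           # child 1 overlaps bar
        masks[1, 4:18, 20:24] = True          # child 2 overlaps bar
        patches = link_patches(masks, "g", VS)
        assert len(patches) == 1
        _, n_oracle = ndi.label(masks, structure=STRUCT_Z)
        assert n_oracle == 1

    def test_disjoint_columns_are_two_patches(self):
        masks = np.zeros((3, 32, 32), dtype=bool)
        masks[:, 2:8, 2:8] = True
        masks[:, 20:26, 20:26] = True
        assert len(link_patches(masks, "g", VS)) == 2

    def test_min_overlap_breaks_weak_links(self):
        masks = np.zeros((2, 16, 16), dtype=bool)
        masks[0, 4:8, 4:8] = True
        masks[1, 7:11, 7:11] = True  # overlap exactly 1 px
        assert len(link_patches(masks, "g", VS, min_overlap_px=1)) == 1
        assert len(link_patches(masks, "g", VS, min_overlap_px=2)) == 2

    @pytest.mark.parametrize("seed", range(8))
    def test_count_matches_brute_force_union_find(self, seed):
        rng = np.random.default_rng(seed)
        masks = rng.random((8, 24, 24)) < rng.uniform(0.1, 0.5)
        patches = link_patches(masks, "g", VS)
        _, n_oracle = ndi.label(masks, structure=STRUCT_Z)
        assert len(patches) == n_oracle
        # conservation: patch volumes sum to the voxel count
        assert sum(p.voxel_count for p in patches) == int(masks.sum())

    def test_count_invariant_under_horizontal_flip(self):
        rng = np.random.default_rng(42)
        masks = rng.random((6, 24, 24)) < 0.3
        n = len(link_patches(masks, "g", VS))
        assert len(link_patches(masks[:, :, ::-1], "g", VS)) == n
        assert len(link_patches(masks[:, ::-1, :], "g", VS)) == n

    def test_ids_ordered_by_descending_volume(self):
        masks = np.zeros((1, 32, 32), dtype=bool)
        masks[0, 2:6, 2:6] = True     # 16 px
        masks[0, 10:20, 10:20] = True  # 100 px
        patches = link_patches(masks, "g", VS)
        assert patches[0].patch_id == 1 and patches[0].voxel_count == 100
        assert patches[1].patch_id == 2 and patches[1].voxel_count == 16


class TestPartition:
    def test_thin_patch_is_all_border(self):
        mask = np.zeros((2, 40, 40), dtype=bool)
        mask[:, 10:20, 5:35]  = True  # 10 px thick < 2*8
        border, centre = partition_border_centre(mask, 8.0, VS)
        assert not centre.any()
        np.testing.assert_array_equal(border, mask)

    def test_square_100px_centre_is_7056(self):
        mask = np.zeros((1, 120, 120), dtype=bool)
        mask[0, 10:110, 10:110] = True
        border, centre = partition_border_centre(mask, 8.0, (1.0, 1.0))
        assert centre.sum() == 7056
        assert border.sum() == 100 * 100 - 7056

    @pytest.mark.parametrize("seed", range(6))
    def test_partition_is_exact_on_random_blobs(self, seed):
        rng = np.random.default_rng(seed)
        mask = random_blob(rng)
        border, centre = partition_border_centre(mask, 4.0, VS)
        assert not (border & centre).any()
        np.testing.assert_array_equal(border | centre, mask)

    def test_shrinking_width_grows_centre_monotonically(self):
        rng = np.random.default_rng(11)
        mask = random_blob(rng, dilations=10)
        _, centre_wide = partition_border_centre(mask, 6.0, VS)
        _, centre_narrow = partition_border_centre(mask, 3.0, VS)
        assert not (centre_wide & ~centre_narrow).any()

    def test_anisotropic_xy_scaling(self):
        mask = np.zeros((1, 60, 60), dtype=bool)
        mask[0, 5:55, 5:55] = True  # 50x50 px at 2 um/px
        border, centre = partition_border_centre(mask, 8.0, (2.0, 1.0))
        # centre = pixels with EDT*2 > 8, i.e. depth index >= 4
        assert centre.sum() == 42 * 42


class TestTrackCells:
    def _labels_from_points(self, pts_per_plane, shape=(32, 32), r=2):
        planes = []
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        for pts in pts_per_plane:
            lab = np.zeros(shape, dtype=np.int32)
            for i, (cy, cx) in enumerate(pts, start=1):
                lab[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = i
            planes.append(lab)
        return np.stack(planes)

    def test_drifting_nucleus_is_one_cell(self):
        # present on planes 1..5 of 7, drifting 0.5 px/plane: px rounding keeps
        # adjacent-centroid distances well under max_drift of 2
        pts = [[], [(10, 10)], [(10, 10.5)], [(10, 11)], [(10, 11.5)], [(10, 12)], []]
        pts = [[(int(round(y)), int(round(x))) for y, x in p] for p in pts]
        labels = self._labels_from_points(pts)
        cells = track_cells(labels, VS, max_drift_um=2.0)
        assert len(cells) == 1
        assert sorted(cells[0].member_rois) == [1, 2, 3, 4, 5]

    def test_distant_nuclei_stay_two_cells(self):
        pts = [[(8, 8), (24, 24)]] * 4
        cells = track_cells(self._labels_from_points(pts), VS, max_drift_um=2.0)
        assert len(cells) == 2

    def test_greedy_contention_closer_child_claimed(self):
        # one parent at (10,10); two children on the next plane at distance 1 and 2
        labels = self._labels_from_points([[(10, 10)], [(10, 11), (10, 12)]])
        cells = track_cells(labels, VS, max_drift_um=3.0)
        # oracle: enumerate assignments; greedy by ascending distance links
        # parent->child at distance 1; the other child starts a new cell
        assert len(cells) == 2
        chain = next(c for c in cells if 0 in c.member_rois)
        assert chain.member_rois[1] == 1  # the closer child (label 1 at (10,11))

    def test_count_invariant_under_relabeling(self, rng):
        pts = [[(8, 8), (20, 20)], [(8, 8), (20, 21)], [(8, 9)]]
        labels = self._labels_from_points(pts)
        cells_a = track_cells(labels, VS, 2.0)
        relabeled = np.where(labels > 0, 7 - labels, 0)  # swap ids 1<->6 etc
        cells_b = track_cells(relabeled, VS, 2.0)
        assert len(cells_a) == len(cells_b)

    def test_z_plane_is_largest_area_member(self):
        planes = np.zeros((3, 32, 32), dtype=np.int32)
        planes[0, 10:12, 10:12] = 1    # 4 px
        planes[1, 9:14, 9:14] = 1      # 25 px
        planes[2, 10:12, 10:12] = 1    # 4 px
        cells = track_cells(planes, VS, 5.0)
        assert len(cells) == 1
        assert cells[0].z_plane == 1


class TestFoci3D:
    def test_empty_masks_give_no_foci(self):
        foci, labels = assemble_foci(np.zeros((3, 16, 16), dtype=bool), VS)
        assert foci == [] and labels.max() == 0

    def test_two_separate_disks_on_three_planes_are_two_foci(self):
        mask = np.zeros((3, 32, 32), dtype=bool)
        yy, xx = np.mgrid[:32, :32]
        for cy, cx in ((10, 10), (10, 20)):
            mask[:, :, :] |= ((yy - cy) ** 2 + (xx - cx) ** 2 <= 9)[None]
        foci, _ = assemble_foci(mask, VS, max_drift_um=2.0)
        assert len(foci) == 2

    def test_dumbbell_split_by_watershed(self):
        yy, xx = np.mgrid[:32, :32]
        d1 = (yy - 15) ** 2 + (xx - 12) ** 2 <= 16
        d2 = (yy - 15) ** 2 + (xx - 18) ** 2 <= 16
        mask2d = d1 | d2
        _, n_merged = ndi.label(mask2d, structure=np.ones((3, 3)))
        assert n_merged == 1
        # oracle: the analytic distance map has maxima at both centres
        dt = ndi.distance_transform_edt(mask2d)
        assert dt[15, 12] >= 3 and dt[15, 18] >= 3
        labels = split_foci_plane(mask2d, h=1.0)
        assert len(np.unique(labels[labels > 0])) == 2
        foci, _ = assemble_foci(mask2d[None], VS)
        assert len(foci) == 2

    def test_focus_volume_and_labels_cover_mask(self):
        mask = np.zeros((2, 16, 16), dtype=bool)
        mask[:, 4:7, 4:7] = True
        foci, labels = assemble_foci(mask, (0.5, 2.0))
        assert len(foci) == 1
        assert foci[0].volume_um3 == pytest.approx(18 * 0.5 * 0.5 * 2.0)
        np.testing.assert_array_equal(labels > 0, mask)


class TestDistances:
    def test_centre_of_21px_square_is_10um(self):
        mask = np.zeros((1, 31, 31), dtype=bool)
        mask[0, 5:26, 5:26] = True
        d, outside = distance_to_patch_border((15.0, 15.0, 0.0), mask, VS)
        assert not outside
        # brute-force min over boundary pixels
        boundary = mask[0] & ~ndi.binary_erosion(mask[0])
        rs, cs = np.nonzero(boundary)
        oracle = np.min(np.hypot(rs - 15, cs - 15))
        assert d == pytest.approx(oracle)
        assert abs(d - 10.0) <= 0.5

    def test_boundary_pixel_distance_zero(self):
        mask = np.zeros((1, 31, 31), dtype=bool)
        mask[0, 5:26, 5:26] = True
        d, outside = distance_to_patch_border((5.0, 15.0, 0.0), mask, VS)
        assert d == 0.0 and not outside

    def test_outside_point_flagged(self):
        mask = np.zeros((1, 31, 31), dtype=bool)
        mask[0, 5:26, 5:26] = True
        d, outside = distance_to_patch_border((1.0, 1.0, 0.0), mask, VS)
        assert d == 0.0 and outside

    def test_distance_decreases_toward_boundary(self):
        mask = np.zeros((1, 41, 41), dtype=bool)
        mask[0, 5:36, 5:36] = True
        ds = [distance_to_patch_border((float(x), 20.0, 0.0), mask, VS)[0] for x in range(20, 36)]
        assert all(a >= b for a, b in zip(ds, ds[1:]))

    def test_centroid_distance_arithmetic(self):
        mask = np.zeros((3, 11, 11), dtype=bool)
        mask[1, 5, 5] = True
        assert distance_to_centroid((2.5, 2.5, 1.0), mask, (0.5, 1.0)) == pytest.approx(0.0)
        # 3 px offset in x at 0.5 um/px
        assert distance_to_centroid((4.0, 2.5, 1.0), mask, (0.5, 1.0)) == pytest.approx(1.5)

    def test_centroid_of_symmetric_region_is_its_centre(self):
        mask = np.zeros((1, 21, 21), dtype=bool)
        mask[0, 3:18, 3:18] = True
        assert distance_to_centroid((10.0, 10.0, 0.0), mask, VS) == pytest.approx(0.0)

    def test_empty_region_raises(self):
        with pytest.raises(ValueError):
            distance_to_centroid((0, 0, 0), np.zeros((1, 4, 4), dtype=bool), VS)
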