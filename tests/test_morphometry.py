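"""Vesicle calls, enlarged-cell flags, bundle measures, cell counts."""

import math

import numpy as np
import pytest
from skimage.transform import rotate as sk_rotate

from bundlequant import (
    ContingencyTable2x2,
    PhantomSpec,
    VesicleDetector,
    count_cells,
    detect_vesicles,
    measure_bundle,
    simulate_stack,
)
from bundlequant.morphometry import contingency_from_flags, flag_cells

from conftest import voxelized_sphere


class TestVesicleDetection:
    def test_three_micron_sphere_is_enlarged_with_accurate_diameter(self):
        mask = voxelized_sphere(3.0, 0.1)
        calls = detect_vesicles(mask, (0.1, 0.1, 0.1))
        assert len(calls) == 1
        call = calls[0]
        assert abs(call.equivalent_diameter_um - 3.0) <= 0.1
        assert call.enlarged
        # oracle: analytic sphere volume
        assert call.volume_um3 == pytest.approx(4 / 3 * math.pi * 1.5**3, rel=0.05)

    def test_one_micron_sphere_is_not_enlarged(self):
        calls = detect_vesicles(voxelized_sphere(1.0, 0.1), (0.1, 0.1, 0.1))
        assert len(calls) == 1 and not calls[0].enlarged

    def test_boundary_spheres_straddle_the_two_micron_rule(self):
        for d, expect in ((1.9, False), (2.1, True)):
            call = detect_vesicles(voxelized_sphere(d, 0.1), (0.1, 0.1, 0.1))[0]
            assert call.enlarged is expect
            assert abs(call.equivalent_diameter_um - d) <= 0.1

    def test_separated_spheres_are_two_components(self):
        mask = np.zeros((20, 20, 40), bool)
        mask[8:12, 8:12, 5:9] = True
        mask[8:12, 8:12, 20:24] = True
        calls = detect_vesicles(mask, (0.1, 0.1, 0.1))
        assert len(calls) == 2

    def test_component_voxels_conserve_mask_voxels(self):
        rng = np.random.default_rng(3)
        mask = rng.random((15, 15, 15)) > 0.7
        calls = detect_vesicles(mask, (0.1, 0.1, 0.1))
        voxel_vol = 0.1**3
        assert sum(round(c.volume_um3 / voxel_vol) for c in calls) == mask.sum()

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(4)
        mask = rng.random((20, 20, 20)) > 0.6
        counts = [
            sum(c.enlarged for c in detect_vesicles(mask, (0.2, 0.2, 0.2), thr))
            for thr in (0.5, 1.0, 2.0, 4.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_equivalent_diameter_converges_with_voxel_size(self):
        errors = [
            abs(
                detect_vesicles(voxelized_sphere(3.0, v), (v, v, v))[0].equivalent_diameter_um
                - 3.0
            )
            for v in (0.2, 0.1, 0.05)
        ]
        assert errors[2] < errors[0]
        assert errors[2] < 0.01

    def test_empty_mask_gives_empty_list(self):
        assert detect_vesicles(np.zeros((5, 5, 5), bool), (0.1, 0.1, 0.1)) == []

    def test_estimator_params(self):
        det = VesicleDetector(diameter_threshold_um=1.5)
        assert det.get_params()["diameter_threshold_um"] == 1.5


class TestCellFlagging:
    def test_no_vesicles_leaves_all_cells_unflagged(self):
        masks = {0: np.zeros((4, 4, 4), bool), 1: np.zeros((4, 4, 4), bool)}
        masks[0][0] = True
        masks[1][2] = True
        flags, unassigned = flag_cells([], masks, (1.0, 1.0, 1.0))
        assert flags == {0: False, 1: False} and unassigned == []
        table = contingency_from_flags(flags.values(), [False])
        assert (table.a, table.c) == (0, 0)

    def test_centroid_outside_all_cells_is_unassigned(self):
        call = detect_vesicles(voxelized_sphere(3.0, 0.1), (0.1, 0.1, 0.1))[0]
        empty = {0: np.zeros(voxelized_sphere(3.0, 0.1).shape, bool)}
        flags, unassigned = flag_cells([call], empty, (0.1, 0.1, 0.1))
        assert unassigned == [call] and flags == {0: False}

    def test_overlapping_cell_masks_rejected(self):
        m = np.ones((3, 3, 3), bool)
        with pytest.raises(ValueError, match="overlap"):
            flag_cells([], {0: m, 1: m}, (1, 1, 1))

    def test_group_count_table_layout(self):
        # group sizes 184 and 236 with 39 and 134 flagged cells
        flags_wt = [True] * 39 + [False] * 145
        flags_mut = [True] * 134 + [False] * 102
        table = contingency_from_flags(flags_wt, flags_mut)
        assert table.to_array().tolist() == [[39, 145], [134, 102]]

    def test_enlarged_fraction_recovered_within_binomial_bounds(self):
        # phantom truth flags across 40 cells at enlarged_fraction 0.5;
        # binomial 95% bounds for n=40, p=0.5: 0.345..0.655
        spec = PhantomSpec(
            n_cells=40,
            enlarged_fraction=0.5,
            lysosomes_per_cell=0,
            voxel_size_um=(0.6, 0.45, 0.45),  # coarse grid keeps 40 cells cheap
            seed=21,
        )
        _, truth = simulate_stack(spec)
        frac = sum(c.has_enlarged for c in truth.cells) / len(truth.cells)
        assert 0.345 <= frac <= 0.655


class TestGroupTables:
    def test_one_table_per_group_pair(self):
        from bundlequant import assign_and_flag_cells

        shape = (6, 6, 6)
        vox = (1.0, 1.0, 1.0)
        big = np.zeros(shape, bool)
        big[1:5, 1:5, 1:5] = True  # 64 voxels -> eq diam ~4.9 um, enlarged
        calls = detect_vesicles(big, vox)
        assert calls[0].enlarged
        cell = np.zeros(shape, bool)
        cell[:, :, :] = True
        other = np.zeros(shape, bool)
        flags, tables = assign_and_flag_cells(
            calls,
            {"wt": {0: other}, "mut": {0: cell}},
            vox,
        )
        assert flags["mut"][0] and not flags["wt"][0]
        table = tables[("wt", "mut")]
        assert table.to_array().tolist() == [[0, 1], [1, 0]]


class TestBundleMeasure:
    def test_axis_aligned_rectangle(self):
        mask = np.zeros((80, 80), bool)
        mask[10:25, 10:60] = True  # 1.5 µm x 5.0 µm at 0.1 µm pixels
        res = measure_bundle(mask, (0.1, 0.1))
        assert res.length_um == pytest.approx(5.0, abs=1e-9)
        assert res.width_um == pytest.approx(1.5, abs=1e-9)

    def test_square_has_equal_length_and_width(self):
        mask = np.zeros((40, 40), bool)
        mask[10:30, 10:30] = True
        res = measure_bundle(mask, (0.1, 0.1))
        assert res.length_um == pytest.approx(res.width_um)

    def test_rotated_rectangle_within_five_percent(self):
        mask = np.zeros((100, 100), float)
        mask[40:55, 20:70] = 1.0
        rotated = sk_rotate(mask, 30, resize=True, order=0) > 0.5
        res = measure_bundle(rotated, (0.1, 0.1))
        assert res.length_um == pytest.approx(5.0, rel=0.05)
        assert res.width_um == pytest.approx(1.5, rel=0.05)

    def test_translation_invariance(self):
        mask = np.zeros((60, 60), bool)
        mask[5:15, 5:35] = True
        shifted = np.roll(mask, (20, 20), axis=(0, 1))
        r1 = measure_bundle(mask, (0.1, 0.1))
        r2 = measure_bundle(shifted, (0.1, 0.1))
        assert r1.length_um == pytest.approx(r2.length_um)
        assert r1.width_um == pytest.approx(r2.width_um)

    def test_multi_component_mask_rejected(self):
        mask = np.zeros((20, 20), bool)
        mask[2:5, 2:5] = True
        mask[10:13, 10:13] = True
        with pytest.raises(ValueError, match="label"):
            measure_bundle(mask, (0.1, 0.1))


class TestCountCells:
    def test_centroids_inside_region_are_counted(self):
        lab = np.zeros((700, 700), int)  # 70 x 70 µm at 0.1 µm pixels
        lab[200:210, 200:210] = 1
        lab[340:350, 340:350] = 2
        lab[400:410, 250:260] = 3
        assert count_cells(lab, (0.1, 0.1)) == 3

    def test_blob_overlapping_but_centroid_outside_is_excluded(self):
        lab = np.zeros((700, 700), int)
        # centroid at ~5.5 µm, outside the central 50 µm box ([10, 60) µm)
        lab[30:80, 300:310] = 1
        assert count_cells(lab, (0.1, 0.1)) == 0

    def test_full_field_region_counts_all_phantom_cells(self):
        spec = PhantomSpec(n_cells=5, seed=13)
        _, truth = simulate_stack(spec)
        labels = np.zeros(truth.spec.resolved_shape()[1:], int)
        for cell in truth.cells:
            proj = cell.stereocilia.any(axis=0)
            labels[proj] = cell.cell_id + 1
        h, w = labels.shape
        py = px = 0.15
        n = count_cells(labels, (py, px), region_size_um=(h * py, w * px))
        assert n == 5

    def test_region_outside_image_rejected(self):
        lab = np.ones((100, 100), int)
        with pytest.raises(ValueError, match="outside"):
            count_cells(lab, (0.1, 0.1), region_size_um=(50.0, 50.0))


def test_contingency_rejects_negative_counts():
    with pytest.raises(ValueError):
        ContingencyTable2x2(-1, 2, 3, 4)
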