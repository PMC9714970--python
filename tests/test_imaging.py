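"""Adaptive segmentation and fluorescence quantification."""

import numpy as np
import pytest

from bundlequant import (
    AdaptiveSegmenter,
    PhantomSpec,
    ProbeModel,
    RoiBox,
    VolumeStack,
    compartment_enrichment,
    fold_enrichment,
    quantify_group_stacks,
    quantify_roi,
    segment_adaptive,
    simulate_stack,
    total_and_recruited,
)
from bundlequant.imaging import split_mask_at_z

from conftest import voxelized_sphere


def _stack_from_array(arr, voxel=(0.5, 0.5, 0.5), names=None):
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:
        arr = arr[None]
    names = names or tuple(f"ch{i}" for i in range(arr.shape[0]))
    return VolumeStack(arr, voxel, names)


class TestAdaptiveSegmenter:
    def test_constant_stack_gives_empty_mask(self):
        stack = _stack_from_array(np.full((4, 20, 20), 7.0))
        mask = segment_adaptive(stack, 0, window_um=3.0, offset_frac=0.1)
        assert mask.voxel_count == 0

    def test_offset_monotonicity(self):
        rng = np.random.default_rng(1)
        stack = _stack_from_array(rng.random((4, 30, 30)))
        masks = [
            segment_adaptive(stack, 0, window_um=3.0, offset_frac=o).mask
            for o in (0.0, 0.1, 0.3, 0.8)
        ]
        for smaller, larger in zip(masks[1:], masks):
            assert not (smaller & ~larger).any()  # raising offset never adds voxels

    def test_sphere_on_dark_background_matches_truth(self):
        sphere = voxelized_sphere(3.0, 0.25, pad_um=2.0)
        stack = _stack_from_array(sphere.astype(float), voxel=(0.25, 0.25, 0.25))
        mask = segment_adaptive(stack, 0, window_um=5.0, offset_frac=0.1)
        inter = (mask.mask & sphere).sum()
        union = (mask.mask | sphere).sum()
        assert inter / union >= 0.9

    def test_idempotent_on_binarized_objects_smaller_than_window(self):
        sphere = voxelized_sphere(3.0, 0.25, pad_um=2.0)
        stack = _stack_from_array(sphere.astype(float), voxel=(0.25, 0.25, 0.25))
        seg = AdaptiveSegmenter(window_um=5.0, offset_frac=0.1)
        once = seg.transform(stack, 0).mask
        again = seg.transform(_stack_from_array(once.astype(float), (0.25, 0.25, 0.25)), 0).mask
        assert np.array_equal(once, again)

    def test_subvoxel_window_is_an_error(self):
        stack = _stack_from_array(np.zeros((2, 4, 4)), voxel=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError, match="less than one voxel"):
            segment_adaptive(stack, 0, window_um=0.2)

    def test_provenance_recorded(self):
        stack = _stack_from_array(np.zeros((2, 4, 4)))
        mask = segment_adaptive(stack, 0, window_um=2.0, offset_frac=0.25)
        assert mask.provenance["offset_frac"] == 0.25
        assert mask.provenance["method"] == "adaptive_local_mean"

    def test_sklearn_params_round_trip(self):
        seg = AdaptiveSegmenter(window_um=3.0)
        assert AdaptiveSegmenter(**seg.get_params()).window_um == 3.0


class TestQuantifyRoi:
    def test_uniform_roi_sum_and_mean(self):
        stack = _stack_from_array(np.ones((10, 10, 10)), voxel=(1.0, 1.0, 1.0))
        roi = RoiBox(origin=(0, 0, 0), extent=(10, 1, 1))  # 10 voxels
        s = quantify_roi(stack, roi)
        assert s.voxel_count == 10 and s.sum == 10.0 and s.mean == 1.0

    def test_empty_mask_intersection_flags_undefined_mean(self):
        stack = _stack_from_array(np.ones((4, 4, 4)), voxel=(1.0, 1.0, 1.0))
        roi = RoiBox(origin=(0, 0, 0), extent=(4, 4, 4))
        s = quantify_roi(stack, roi, mask=np.zeros((4, 4, 4), bool))
        assert s.sum == 0.0 and not s.mean_defined and np.isnan(s.mean)

    def test_sum_matches_brute_force_on_phantom(self, clean_phantom):
        _, stack, _ = clean_phantom
        roi = RoiBox(origin=(1.0, 1.0, 1.0), extent=(5.0, 4.0, 6.0))
        s = quantify_roi(stack, roi, channel="D4H")
        zs, ys, xs = roi.to_slices(stack.voxel_size, stack.shape)
        brute = 0.0
        img = stack.channel("D4H")
        for z in range(zs.start, zs.stop):
            for y in range(ys.start, ys.stop):
                for x in range(xs.start, xs.stop):
                    brute += img[z, y, x]
        assert s.sum == pytest.approx(brute, rel=1e-12)

    def test_mask_monotonicity(self, clean_phantom):
        _, stack, truth = clean_phantom
        roi = RoiBox(origin=(0, 0, 0), extent=tuple(
            n * v for n, v in zip(stack.shape, stack.voxel_size)
        ))
        small = truth.union("stereocilia")
        large = small | truth.union("basolateral")
        s_small = quantify_roi(stack, roi, mask=small, channel="PM")
        s_large = quantify_roi(stack, roi, mask=large, channel="PM")
        assert s_small.sum <= s_large.sum

    def test_roi_outside_stack_raises(self):
        stack = _stack_from_array(np.ones((4, 4, 4)), voxel=(1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="outside"):
            quantify_roi(stack, RoiBox(origin=(2, 0, 0), extent=(4, 4, 4)))


class TestTotalAndRecruited:
    def test_hand_computed_grid(self):
        # single-slice 3x3 field with values 1..9; marker over cells 2, 4, 6
        signal = np.arange(1.0, 10.0).reshape(1, 3, 3)
        marker = np.zeros((1, 3, 3), bool)
        marker[0, 0, 1] = marker[0, 1, 0] = marker[0, 1, 2] = True  # values 2, 4, 6
        stack = _stack_from_array(signal, voxel=(1, 1, 1))
        res = total_and_recruited(stack, 0, marker_mask=marker)
        assert res.total_sum == 45.0
        assert res.recruited_mean == pytest.approx(4.0)

    def test_marker_covering_field_gives_global_mean(self, clean_phantom):
        _, stack, _ = clean_phantom
        full = np.ones(stack.shape, bool)
        res = total_and_recruited(stack, "D4H", marker_mask=full)
        assert res.recruited_mean == pytest.approx(stack.channel("D4H").mean())

    def test_zero_signal(self):
        stack = _stack_from_array(
            np.stack([np.zeros((2, 3, 3)), np.ones((2, 3, 3))]), voxel=(1, 1, 1)
        )
        res = total_and_recruited(stack, 0, marker_mask=np.ones((2, 3, 3), bool))
        assert res.total_sum == 0.0 and res.recruited_mean == 0.0

    def test_empty_marker_mask_flags_undefined(self):
        stack = _stack_from_array(np.ones((2, 3, 3)), voxel=(1, 1, 1))
        res = total_and_recruited(stack, 0, marker_mask=np.zeros((2, 3, 3), bool))
        assert not res.recruited_defined and np.isnan(res.recruited_mean)


class TestCompartmentEnrichment:
    def test_printed_compartment_ratios_give_seven_point_seven_fold(self):
        # probe 567.7% vs reference 73.7% -> 7.7-fold at one decimal
        assert round(fold_enrichment(567.7, 73.7), 1) == 7.7

    def test_stack_with_those_ratios_reproduces_the_fold(self):
        probe = np.concatenate([np.full((1, 1, 10), 5.677), np.full((1, 1, 10), 1.0)], axis=1)
        ref = np.concatenate([np.full((1, 1, 10), 0.737), np.full((1, 1, 10), 1.0)], axis=1)
        stack = _stack_from_array(np.stack([ref, probe]), names=("ref", "probe"))
        stereo = np.zeros((1, 2, 10), bool)
        stereo[0, 0] = True
        baso = ~stereo
        res = compartment_enrichment(stack, stereo, baso, channels=("probe", "ref"))
        assert res.ratio_pct["probe"] == pytest.approx(567.7)
        assert res.ratio_pct["ref"] == pytest.approx(73.7)
        assert round(res.ratio_of_ratios, 1) == 7.7

    def test_equal_means_give_hundred_percent(self):
        stack = _stack_from_array(np.ones((2, 4, 4)), names=("a",))
        stereo = np.zeros((2, 4, 4), bool)
        stereo[0] = True
        res = compartment_enrichment(stack, stereo, ~stereo, channels=("a", "a"))
        assert res.ratio_pct["a"] == pytest.approx(100.0)

    def test_scale_invariance_per_channel(self, clean_phantom):
        _, stack, truth = clean_phantom
        stereo, baso = truth.union("stereocilia"), truth.union("basolateral")
        base = compartment_enrichment(stack, stereo, baso, channels=("D4H", "PM"))
        scaled = VolumeStack(
            np.stack([stack.voxels[0], stack.voxels[1] * 3.5]),
            stack.voxel_size,
            stack.channel_names,
        )
        res = compartment_enrichment(scaled, stereo, baso, channels=("D4H", "PM"))
        assert res.ratio_pct["D4H"] == pytest.approx(base.ratio_pct["D4H"])

    def test_channel_swap_inverts_fold(self, clean_phantom):
        _, stack, truth = clean_phantom
        stereo, baso = truth.union("stereocilia"), truth.union("basolateral")
        fwd = compartment_enrichment(stack, stereo, baso, channels=("D4H", "PM"))
        rev = compartment_enrichment(stack, stereo, baso, channels=("PM", "D4H"))
        assert fwd.ratio_of_ratios == pytest.approx(1.0 / rev.ratio_of_ratios)

    def test_overlapping_or_empty_masks_rejected(self, clean_phantom):
        _, stack, truth = clean_phantom
        stereo = truth.union("stereocilia")
        with pytest.raises(ValueError, match="overlap"):
            compartment_enrichment(stack, stereo, stereo)
        with pytest.raises(ValueError, match="non-empty"):
            compartment_enrichment(stack, np.zeros(stack.shape, bool), stereo)

    def test_split_at_z_partitions_mask(self, clean_phantom):
        spec, stack, truth = clean_phantom
        mask = truth.union("stereocilia") | truth.union("basolateral")
        apex = spec.margin_um + spec.stereocilium_length_um
        above, below = split_mask_at_z(mask, apex, stack.voxel_size)
        assert not (above & below).any()
        assert np.array_equal(above | below, mask)


class TestGroupQuantification:
    def test_identical_stacks_give_identical_rows(self, clean_phantom):
        _, stack, _ = clean_phantom
        table = quantify_group_stacks(
            [("s1", "wt", stack), ("s2", "wt", stack)], None, "PM"
        )
        assert table.iloc[0]["sum"] == table.iloc[1]["sum"]
        assert list(table["sample_id"]) == ["s1", "s2"]

    def test_half_density_group_ratio(self):
        def make(scale, seed):
            # read noise off: its clipping at zero adds a scale-independent
            # floor that is not part of the density ratio under test
            probes = (ProbeModel("AM143", membrane_density=scale, cytoplasm_density=0.05 * scale),)
            spec = PhantomSpec(n_cells=1, probes=probes, read_noise_sd=0.0, seed=seed)
            return simulate_stack(spec)[0]

        stacks = [(f"a{i}", "A", make(1.0, i)) for i in range(3)] + [
            (f"b{i}", "B", make(0.5, 10 + i)) for i in range(3)
        ]
        table = quantify_group_stacks(stacks, None, "AM143")
        means = table.groupby("group")["sum"].mean()
        assert means["B"] / means["A"] == pytest.approx(0.5, rel=0.05)

    def test_empty_batch_gives_empty_table(self):
        table = quantify_group_stacks([], None, "PM")
        assert len(table) == 0
        assert list(table.columns) == [
            "sample_id", "group", "channel", "voxel_count", "sum", "mean",
        ]

    def test_missing_channel_names_offending_stack(self, clean_phantom):
        _, stack, _ = clean_phantom
        with pytest.raises(KeyError, match="bad_sample"):
            quantify_group_stacks([("bad_sample", "g", stack)], None, "nope")
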