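"""Thorax localisation, cropping, clipping, and standardisation."""

import numpy as np
import pytest
from scipy import ndimage

from lymphdetect.errors import DegenerateDataError, SegmentationFailureError
from lymphdetect.preprocess import (
    IntensityStandardizer,
    PreprocessConfig,
    ThoraxCrop,
    _locate_lungs,
    apply_normalization,
    clip_intensities,
    crop_thorax,
    fit_normalization,
    invert_normalization,
    preprocess_scan,
    remove_border_components,
    segment_air,
    select_lungs,
)
from lymphdetect.regions import FACE_STRUCT
from lymphdetect.volume import Modality, PatientScan, Volume3D

RAW_CFG = PreprocessConfig(closing_iters=0, opening_iters=0)


def _scan(ct_values, pet_values=None, spacing=(1.0, 1.0, 1.0)):
    ct = Volume3D(np.asarray(ct_values, dtype=np.float32), spacing, modality=Modality.CT_HU)
    if pet_values is None:
        pet_values = np.zeros_like(ct.values)
    pet = Volume3D(np.asarray(pet_values, dtype=np.float32), spacing, modality=Modality.PET_SUV)
    return PatientScan("p", "scanner1", ct, pet)


def _crop_from(ct, pet=None):
    scan = _scan(ct, pet)
    return ThoraxCrop(
        ct=scan.ct, pet=scan.pet, z_range=(0, scan.ct.shape[0] - 1), xy_offset=(0, 0),
        patient_id="p",
    )


class TestSegmentAir:
    def test_threshold_boundary_is_inclusive_on_air_side(self):
        ct = np.full((3, 3, 3), 0.0)
        ct[0, 0, 0] = -500.0
        ct[1, 1, 1] = -400.0
        ct[2, 2, 2] = -300.0
        mask = segment_air(ct, RAW_CFG)
        assert mask[0, 0, 0] and mask[1, 1, 1] and not mask[2, 2, 2]

    def test_all_soft_tissue_gives_empty_mask(self):
        assert not segment_air(np.zeros((5, 5, 5)), PreprocessConfig()).any()

    def test_isolated_air_voxel_removed_by_opening(self):
        ct = np.zeros((20, 20, 20))
        ct[10, 10, 10] = -800.0
        mask = segment_air(ct, PreprocessConfig())
        assert not mask.any()
        # oracle: an opening is 7 erosions then 7 dilations
        raw = ct <= -400
        eroded = raw
        for _ in range(7):
            eroded = ndimage.binary_erosion(eroded, FACE_STRUCT)
        assert not eroded.any()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_morphology_equals_erosion_dilation_composition(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((20, 20, 20)) > 0.6
        ct = np.where(mask, -800.0, 0.0)
        got = segment_air(ct, PreprocessConfig())
        ref = mask
        for _ in range(2):
            ref = ndimage.binary_dilation(ref, FACE_STRUCT)
        for _ in range(2 + 7):
            ref = ndimage.binary_erosion(ref, FACE_STRUCT)
        for _ in range(7):
            ref = ndimage.binary_dilation(ref, FACE_STRUCT)
        np.testing.assert_array_equal(got, ref)

    def test_single_dilation_matches_brute_force_neighbourhood(self):
        rng = np.random.default_rng(3)
        mask = rng.random((12, 12, 12)) > 0.9
        got = ndimage.binary_dilation(mask, FACE_STRUCT)
        ref = mask.copy()
        for dz, dy, dx in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
            shifted = np.zeros_like(mask)
            src = tuple(
                slice(max(d, 0), None if d >= 0 else d) for d in (dz, dy, dx)
            )
            dst = tuple(
                slice(max(-d, 0), None if d <= 0 else -d) for d in (dz, dy, dx)
            )
            shifted[src] = mask[dst]
            ref |= shifted
        np.testing.assert_array_equal(got, ref)


class TestBorderComponents:
    def test_component_touching_x_border_deleted(self):
        mask = np.zeros((10, 80, 80), dtype=bool)
        mask[5, 40, 0:4] = True
        assert not remove_border_components(mask, 25).any()

    def test_interior_component_retained(self):
        mask = np.zeros((10, 80, 80), dtype=bool)
        mask[5, 40, 38:42] = True
        assert remove_border_components(mask, 25).sum() == 4

    def test_component_at_exactly_margin_distance_retained(self):
        mask = np.zeros((4, 60, 60), dtype=bool)
        mask[2, 25, 25] = True  # nearest border distance exactly 25
        assert remove_border_components(mask, 25).any()
        mask2 = np.zeros((4, 60, 60), dtype=bool)
        mask2[2, 24, 30] = True  # strictly inside the margin band
        assert not remove_border_components(mask2, 25).any()

    def test_z_axis_is_exempt(self):
        mask = np.zeros((10, 80, 80), dtype=bool)
        mask[0, 40, 40] = True
        assert remove_border_components(mask, 25).any()


class TestSelectLungs:
    def test_largest_component_wins(self):
        mask = np.zeros((6, 40, 40), dtype=bool)
        mask[1:4, 2:12, 2:12] = True  # 300 voxels
        mask[5, 20:24, 20:24] = True  # 16 voxels
        sel = select_lungs(mask)
        assert sel.sum() == 300
        assert sel[2, 5, 5]

    def test_tie_breaks_toward_scan_order(self):
        mask = np.zeros((4, 20, 20), dtype=bool)
        mask[0, 0:2, 0:2] = True  # first in scan order
        mask[3, 10:12, 10:12] = True  # same size
        sel = select_lungs(mask)
        assert sel[0, 0, 0] and not sel[3, 10, 10]

    def test_empty_mask_raises(self):
        with pytest.raises(SegmentationFailureError):
            select_lungs(np.zeros((3, 3, 3), dtype=bool))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_fused_path_matches_two_step_reference(self, seed):
        rng = np.random.default_rng(seed)
        mask = ndimage.binary_opening(rng.random((12, 70, 70)) > 0.45)
        try:
            ref = select_lungs(remove_border_components(mask, 25))
        except SegmentationFailureError:
            with pytest.raises(SegmentationFailureError):
                _locate_lungs(mask, 25)
            return
        np.testing.assert_array_equal(_locate_lungs(mask, 25), ref)

    def test_selected_lungs_cover_planted_lungs(self, small_phantom):
        from lymphdetect.volume import resample_isotropic

        scan, masks, _ = small_phantom
        ct1 = resample_isotropic(scan.ct)
        sel = _locate_lungs(segment_air(ct1), 25)
        centres = scan.ct.index_to_physical(np.argwhere(masks["lungs"]))
        idx = ct1.physical_to_nearest_index(centres)
        covered = sel[idx[:, 0], idx[:, 1], idx[:, 2]].mean()
        assert covered >= 0.95


class TestCropThorax:
    def test_z_slice_arithmetic(self):
        ct = np.zeros((200, 64, 64), dtype=np.float32)
        lungs = np.zeros_like(ct, dtype=bool)
        lungs[40:161, 30, 30] = True  # slices 40..160 inclusive
        crop = crop_thorax(_scan(ct), lungs, PreprocessConfig(crop_xy=64))
        assert crop.shape[0] == 121
        assert crop.z_range == (40, 160)

    def test_larger_slice_centre_cropped_with_symmetric_offset(self):
        ct = np.arange(2 * 300 * 300, dtype=np.float32).reshape(2, 300, 300)
        lungs = np.zeros_like(ct, dtype=bool)
        lungs[:, 150, 150] = True
        crop = crop_thorax(_scan(ct), lungs, PreprocessConfig())
        assert crop.xy_offset == (22, 22)
        np.testing.assert_array_equal(crop.ct.values, ct[:, 22:278, 22:278])

    def test_smaller_slice_padded_with_air_values(self):
        ct = np.full((2, 200, 200), 55.0, dtype=np.float32)
        pet = np.full((2, 200, 200), 3.0, dtype=np.float32)
        lungs = np.zeros_like(ct, dtype=bool)
        lungs[:, 100, 100] = True
        crop = crop_thorax(_scan(ct, pet), lungs, PreprocessConfig())
        assert crop.shape == (2, 256, 256)
        assert crop.xy_offset == (-28, -28)
        assert crop.ct.values[0, 0, 0] == -1000.0
        assert crop.pet.values[0, 0, 0] == 0.0
        assert crop.ct.values[0, 128, 128] == 55.0

    def test_physical_coordinates_survive_cropping(self):
        ct = np.zeros((30, 300, 300), dtype=np.float32)
        ct[15, 160, 170] = 99.0
        lungs = np.zeros_like(ct, dtype=bool)
        lungs[10:21, 150, 150] = True
        scan = _scan(ct)
        xyz = scan.ct.index_to_physical(np.array([15, 160, 170], dtype=float))
        crop = crop_thorax(scan, lungs, PreprocessConfig())
        idx = crop.ct.physical_to_nearest_index(xyz)
        assert crop.ct.values[tuple(idx)] == 99.0

    def test_empty_lung_mask_propagates_failure(self):
        ct = np.zeros((4, 64, 64), dtype=np.float32)
        with pytest.raises(SegmentationFailureError):
            crop_thorax(_scan(ct), np.zeros_like(ct, dtype=bool), PreprocessConfig())


class TestClipAndNormalise:
    def test_clip_bounds(self):
        ct = np.array([[[1500.0, -1500.0, 350.0, 0.0]]])
        pet = np.array([[[10.0, 4.0, 0.0, 7.9]]])
        crop = clip_intensities(_crop_from(ct, pet))
        np.testing.assert_array_equal(crop.ct.values, [[[1000.0, -1000.0, 350.0, 0.0]]])
        np.testing.assert_allclose(crop.pet.values, [[[8.0, 4.0, 0.0, 7.9]]], atol=1e-6)

    def test_constant_data_raises_degenerate(self):
        with pytest.raises(DegenerateDataError):
            fit_normalization([_crop_from(np.zeros((2, 4, 4)))])

    def test_pooled_mean_of_two_crops(self):
        a = _crop_from(np.zeros((1, 4, 4)), np.zeros((1, 4, 4)))
        b = _crop_from(np.full((1, 4, 4), 2.0), np.full((1, 4, 4), 4.0))
        stats = fit_normalization([a, b])
        assert stats.ct_mean == pytest.approx(1.0)
        assert stats.pet_mean == pytest.approx(2.0)

    def test_self_application_gives_zero_mean_unit_variance(self, small_phantom):
        scan, _, _ = small_phantom
        crop = preprocess_scan(scan)
        stats = fit_normalization([crop])
        out = apply_normalization(crop, stats)
        assert abs(float(out.ct.values.mean())) < 1e-4
        assert abs(float(out.ct.values.std()) - 1.0) < 1e-4
        assert abs(float(out.pet.values.mean())) < 1e-4

    def test_affine_and_order_preserving(self):
        a = _crop_from(np.array([[[10.0, 30.0]]]), np.array([[[1.0, 2.0]]]))
        b = _crop_from(np.array([[[20.0, 40.0]]]), np.array([[[1.5, 2.5]]]))
        stats = fit_normalization([a, b])
        na, nb = apply_normalization(a, stats), apply_normalization(b, stats)
        delta = (b.ct.values - a.ct.values) / stats.ct_sd
        np.testing.assert_allclose(nb.ct.values - na.ct.values, delta, rtol=1e-5)
        # value equal to the mean maps to zero
        mid = _crop_from(np.full((1, 1, 1), stats.ct_mean), np.full((1, 1, 1), stats.pet_mean))
        nm = apply_normalization(mid, stats)
        assert nm.ct.values[0, 0, 0] == pytest.approx(0.0)

    def test_round_trip_inverse(self):
        rng = np.random.default_rng(4)
        a = _crop_from(rng.normal(0, 100, (2, 8, 8)), rng.random((2, 8, 8)) * 8)
        stats = fit_normalization([a])
        back = invert_normalization(apply_normalization(a, stats), stats)
        np.testing.assert_allclose(back.ct.values, a.ct.values, atol=1e-9)
        np.testing.assert_allclose(back.pet.values, a.pet.values, atol=1e-9)

    def test_standardizer_persists_training_stats(self, tmp_path):
        a = _crop_from(np.array([[[0.0, 2.0]]]), np.array([[[0.0, 4.0]]]))
        std = IntensityStandardizer().fit([a])
        path = tmp_path / "stats.json"
        std.stats_.to_json(path)
        from lymphdetect.preprocess import NormalizationStats

        back = NormalizationStats.from_json(path)
        assert back == std.stats_


class TestFullPreprocess:
    def test_deterministic_and_automated(self, small_phantom):
        scan, _, _ = small_phantom
        a = preprocess_scan(scan)
        b = preprocess_scan(scan)
        np.testing.assert_array_equal(a.ct.values, b.ct.values)
        np.testing.assert_array_equal(a.pet.values, b.pet.values)
        assert a.z_range == b.z_range

    def test_all_planted_nodes_inside_crop(self):
        from lymphdetect.phantom import PhantomParams, SCANNER1, generate_cohort

        cohort = generate_cohort(3, PhantomParams(seed=31), SCANNER1, seed=31)
        for scan in cohort.scans:
            crop = preprocess_scan(scan)
            for node in scan.nodes:
                idx = crop.grid.physical_to_nearest_index(np.asarray(node.centre))
                assert all(0 <= i < s for i, s in zip(idx, crop.shape)), (
                    scan.patient_id,
                    node,
                )
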