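"""Volumetry: segmentation, diameters, the ABC/2 family, SAS, AVC, binning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haemquant import (
    CTVolume,
    DiameterTriple,
    LesionMask,
    PhantomSpec,
    SegmentationParams,
    abc2,
    avc_volume,
    c_modified,
    c_standard,
    generate_phantom,
    measure_A_B,
    sas_volume,
    segment_threshold,
    size_category,
    slice_areas,
)
from haemquant.volumetry import (
    NoLesionInWindowError,
    SeedNotInWindowError,
    VariableSliceThicknessError,
)

from conftest import MIDPOINT_PARAMS, binary_volume


class TestSegmentation:
    def test_sphere_mask_volume_within_two_percent(self, sphere_phantom):
        vol, truth = sphere_phantom
        mask = segment_threshold(vol, MIDPOINT_PARAMS)
        est = mask.n_voxels * vol.in_plane_spacing ** 2 * 1.0 / 1000.0
        assert est == pytest.approx(truth.true_volume_cm3, rel=0.02)

    def test_permissive_lower_bound_overestimates(self, sphere_phantom):
        # a lower bound well below the tissue midpoint admits boundary voxels
        # that are mostly background: volume biases upward
        vol, truth = sphere_phantom
        mask = segment_threshold(vol, SegmentationParams(40.0, 80.0))
        est = mask.n_voxels / 1000.0
        assert est > truth.true_volume_cm3 * 1.02

    def test_empty_window_raises_with_window(self, sphere_phantom):
        vol, _ = sphere_phantom
        with pytest.raises(NoLesionInWindowError) as exc:
            segment_threshold(vol, SegmentationParams(200.0, 300.0))
        assert exc.value.window == (200.0, 300.0)

    def test_seed_selects_component(self):
        values = np.full((3, 20, 20), 30.0, np.float32)
        values[1, 2:5, 2:5] = 65.0       # small lesion
        values[1, 10:18, 10:18] = 65.0   # large lesion
        vol = binary_volume(values)
        seeded = segment_threshold(
            vol, SegmentationParams(40, 80, seed_point=(1, 3, 3))
        )
        assert seeded.n_voxels == 9
        largest = segment_threshold(vol, SegmentationParams(40, 80))
        assert largest.n_voxels == 64

    def test_edit_masks_include_overrides_exclude(self):
        values = np.full((1, 10, 10), 30.0, np.float32)
        values[0, 2:6, 2:6] = 65.0
        vol = binary_volume(values)
        include = np.zeros_like(values, bool)
        include[0, 8, 8] = True
        exclude = np.zeros_like(values, bool)
        exclude[0, 2, 2] = True
        exclude[0, 8, 8] = True  # include wins on this voxel
        mask = segment_threshold(
            vol,
            SegmentationParams(40, 80, include_mask=include, exclude_mask=exclude),
        )
        assert not mask.voxels[0, 2, 2]
        assert mask.voxels[0, 8, 8]


class TestSliceAreas:
    def test_square_area_and_zeros_elsewhere(self):
        values = np.full((3, 20, 20), 30.0, np.float32)
        values[1, 5:15, 5:15] = 65.0
        vol = binary_volume(values)
        mask = segment_threshold(vol, SegmentationParams(40, 80))
        areas = slice_areas(mask, vol)
        assert areas[1] == pytest.approx(1.0)
        assert areas[0] == areas[2] == 0.0

    def test_sphere_area_profile_unimodal_with_equatorial_peak(self, sphere_phantom):
        vol, _ = sphere_phantom
        mask = segment_threshold(vol, MIDPOINT_PARAMS)
        areas = slice_areas(mask, vol)
        peak = int(np.argmax(areas))
        assert peak in (19, 20)
        nz = areas[areas > 0]
        rising = np.diff(nz[: len(nz) // 2])
        falling = np.diff(nz[len(nz) // 2 + 1 :])
        assert (rising >= 0).all() and (falling <= 0).all()


class TestDiameters:
    def test_axis_aligned_ellipsoid_within_one_voxel(self, ellipsoid_phantom):
        vol, _ = ellipsoid_phantom
        mask = segment_threshold(vol, MIDPOINT_PARAMS)
        a, b, k = measure_A_B(mask, vol)
        assert a == pytest.approx(4.0, abs=0.1)
        assert b == pytest.approx(3.0, abs=0.1)
        assert k in (19, 20)

    def test_single_voxel_has_extent_one_spacing(self):
        values = np.full((3, 7, 7), 30.0, np.float32)
        values[1, 3, 3] = 65.0
        vol = binary_volume(values)
        mask = LesionMask(values > 47.5)  # no provenance: count-based extent
        a, b, _ = measure_A_B(mask, vol)
        assert a == pytest.approx(0.1)
        assert b == pytest.approx(0.1)

    def test_rotated_lesion_long_axis_within_one_voxel(self):
        spec = PhantomSpec(
            ellipsoid_diameters=(40.0, 20.0, 16.0),
            centre=(35.0, 35.0, 20.0),
            grid_rows=70,
            grid_cols=70,
            slice_thicknesses=(1.0,) * 40,
            rotation_deg=45.0,
            noise_sd_hu=0.0,
            hetero_sd_hu=0.0,
        )
        vol, _ = generate_phantom(spec)
        mask = segment_threshold(vol, MIDPOINT_PARAMS)
        a, b, _ = measure_A_B(mask, vol)
        assert a == pytest.approx(4.0, abs=0.1)
        assert b == pytest.approx(2.0, abs=0.1)


class TestCExtent:
    def test_uniform_thickness_sums(self):
        values = np.full((8, 10, 10), 30.0, np.float32)
        values[1:6, 4:7, 4:7] = 65.0
        vol = CTVolume(values, 1.0, np.full(8, 4.0))
        mask = segment_threshold(vol, SegmentationParams(40, 80))
        assert c_standard(mask, vol) == pytest.approx(2.0)

    def test_variable_thickness_sums(self):
        values = np.full((3, 10, 10), 30.0, np.float32)
        values[:, 4:7, 4:7] = 65.0
        vol = CTVolume(values, 1.0, np.array([4.0, 4.0, 8.0]))
        mask = segment_threshold(vol, SegmentationParams(40, 80))
        assert c_standard(mask, vol) == pytest.approx(1.6)

    def test_empty_mask_rejected(self):
        values = np.full((3, 10, 10), 30.0, np.float32)
        vol = binary_volume(values)
        with pytest.raises(ValueError, match="empty"):
            c_standard(LesionMask(np.zeros_like(values, bool)), vol)

    def test_modified_weights_example(self):
        areas = np.array([1, 3, 8, 10, 8, 3, 1], float)
        thick = np.full(7, 10.0)  # 1 cm slices
        assert c_modified(areas, thick) == pytest.approx(4.0)

    def test_equal_areas_match_standard(self):
        areas = np.full(5, 2.0)
        thick = np.full(5, 4.0)
        assert c_modified(areas, thick) == pytest.approx(2.0)

    @given(
        st.lists(st.floats(0.0, 50.0), min_size=1, max_size=30).filter(
            lambda a: max(a) > 0
        ),
        st.floats(1.0, 10.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_modified_never_exceeds_standard(self, areas, thickness):
        areas = np.asarray(areas)
        thick = np.full(len(areas), thickness)
        c_mod = c_modified(areas, thick)
        c_std = float(thick[areas > 0].sum()) / 10.0
        assert c_mod <= c_std + 1e-9


class TestAbc2:
    def test_formula(self):
        assert abc2(DiameterTriple(4.0, 3.0, 2.0)) == pytest.approx(12.0)

    @pytest.mark.parametrize(
        "bad", [(0.0, 1.0, 1.0), (1.0, 0.0, 1.0), (1.0, 1.0, 0.0), (1.0, 2.0, 1.0)]
    )
    def test_invalid_triples_rejected(self, bad):
        with pytest.raises(ValueError):
            DiameterTriple(*bad)


class TestSas:
    def test_stack_of_squares(self):
        values = np.full((10, 14, 14), 30.0, np.float32)
        values[:, 2:12, 2:12] = 65.0
        vol = binary_volume(values)
        mask = segment_threshold(vol, SegmentationParams(40, 80))
        assert sas_volume(mask, vol).volume_cm3 == pytest.approx(1.0)

    def test_sphere_within_two_percent(self, sphere_phantom):
        vol, truth = sphere_phantom
        mask = segment_threshold(vol, MIDPOINT_PARAMS)
        assert sas_volume(mask, vol).volume_cm3 == pytest.approx(
            truth.true_volume_cm3, rel=0.02
        )

    def test_equals_voxel_count_when_thickness_uniform(self, sphere_phantom):
        vol, _ = sphere_phantom
        mask = segment_threshold(vol, MIDPOINT_PARAMS)
        assert sas_volume(mask, vol).volume_cm3 == pytest.approx(
            mask.n_voxels / 1000.0
        )

    def test_invariant_under_window_preserving_rescale(self, sphere_phantom):
        vol, _ = sphere_phantom
        mask1 = segment_threshold(vol, MIDPOINT_PARAMS)
        shifted = CTVolume(
            vol.values + 100.0, vol.in_plane_spacing, vol.slice_thicknesses
        )
        mask2 = segment_threshold(
            shifted,
            SegmentationParams(
                MIDPOINT_PARAMS.hu_low + 100.0, MIDPOINT_PARAMS.hu_high + 100.0
            ),
        )
        assert sas_volume(mask1, vol).volume_cm3 == pytest.approx(
            sas_volume(mask2, shifted).volume_cm3
        )


class TestAvc:
    def test_matches_sas_on_uniform_sphere(self, sphere_phantom):
        vol, _ = sphere_phantom
        params = SegmentationParams(
            MIDPOINT_PARAMS.hu_low, MIDPOINT_PARAMS.hu_high, seed_point=(20, 20, 20)
        )
        avc = avc_volume(vol, params)
        mask = segment_threshold(vol, params)
        assert avc.volume_cm3 == pytest.approx(
            sas_volume(mask, vol).volume_cm3, rel=0.01
        )

    def test_variable_thickness_refused(self):
        values = np.full((6, 20, 20), 30.0, np.float32)
        values[2:4, 8:12, 8:12] = 65.0
        vol = CTVolume(values, 1.0, np.array([4.0, 4.0, 4.0, 8.0, 8.0, 8.0]))
        with pytest.raises(VariableSliceThicknessError):
            avc_volume(vol, SegmentationParams(40, 80, seed_point=(2, 9, 9)))
        est = avc_volume(
            vol,
            SegmentationParams(40, 80, seed_point=(2, 9, 9)),
            allow_variable_thickness=True,
        )
        assert est.volume_cm3 > 0

    def test_seed_outside_window_raises(self, sphere_phantom):
        vol, _ = sphere_phantom
        with pytest.raises(SeedNotInWindowError):
            avc_volume(vol, SegmentationParams(40, 80, seed_point=(0, 0, 0)))


class TestSizeCategory:
    @pytest.mark.parametrize(
        "d,expected",
        [
            (2.9, "<3"),
            (3.0, "3-4.9"),
            (4.99, "3-4.9"),
            (5.0, "5-8"),
            (8.0, "5-8"),
            (8.01, ">8"),
        ],
    )
    def test_bins(self, d, expected):
        assert size_category(d) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            size_category(0.0)
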