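import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from osteoquant import morphometry as m

from oracles import (
    brute_bic,
    brute_bvtv,
    brute_class_count,
    brute_exposed_faces,
    random_labeled_grid,
)


class TestLabelVolume:
    def test_all_zero_grid_is_valid(self):
        vol = m.label_volume(np.zeros((4, 4, 4), dtype=np.uint8), 5.0)
        assert vol.labels.shape == (4, 4, 4)

    def test_unknown_code_rejected_with_value(self):
        labels = np.zeros((3, 3, 3), dtype=np.uint8)
        labels[1, 1, 1] = 4
        with pytest.raises(ValueError, match="4"):
            m.label_volume(labels, 5.0)

    def test_physical_extent(self):
        vol = m.label_volume(np.zeros((100, 100, 100), dtype=np.uint8), 5.0)
        extent_mm = vol.labels.shape[0] * vol.voxel_um * 1e-3
        assert extent_mm == pytest.approx(0.5)

    @pytest.mark.parametrize("voxel_um", [0.0, -1.0])
    def test_bad_voxel_size(self, voxel_um):
        with pytest.raises(ValueError):
            m.label_volume(np.zeros((2, 2, 2), dtype=np.uint8), voxel_um)


class TestClassVolume:
    def test_metal_count_at_10um(self):
        labels = np.zeros((10, 10, 10), dtype=np.uint8)
        labels.ravel()[:1000] = m.METAL
        vol = m.label_volume(labels, 10.0)
        assert m.class_volume(vol, m.METAL) == pytest.approx(1e-3)

    def test_absent_code_is_zero(self):
        vol = m.label_volume(np.zeros((5, 5, 5), dtype=np.uint8), 5.0)
        assert m.class_volume(vol, m.BONE) == 0.0

    def test_partition_sums_to_grid_volume(self, rng):
        labels = random_labeled_grid(rng)
        vol = m.label_volume(labels, 7.0)
        total = sum(m.class_volume(vol, c) for c in m.VALID_CODES)
        assert total == pytest.approx(labels.size * (7.0e-3) ** 3, rel=1e-12)

    def test_invalid_code_rejected(self, rng):
        vol = m.label_volume(np.zeros((3, 3, 3), dtype=np.uint8), 5.0)
        with pytest.raises(ValueError):
            m.class_volume(vol, 9)


class TestSurfaceArea:
    def test_single_voxel_six_faces(self):
        labels = np.zeros((3, 3, 3), dtype=np.uint8)
        labels[1, 1, 1] = m.METAL
        vol = m.label_volume(labels, 10.0)
        assert m.class_surface_area(vol, m.METAL) == pytest.approx(6e-4)

    def test_two_voxel_block_ten_faces(self):
        labels = np.zeros((3, 3, 4), dtype=np.uint8)
        labels[1, 1, 1:3] = m.METAL
        vol = m.label_volume(labels, 10.0)
        expected_faces = brute_exposed_faces(labels, m.METAL)
        assert expected_faces == 10
        assert m.class_surface_area(vol, m.METAL) == pytest.approx(10e-4)

    def test_sphere_face_count_vs_smooth_area(self):
        r = 20
        n = 2 * r + 5
        c = (n - 1) / 2
        zz, yy, xx = np.meshgrid(*(np.arange(n),) * 3, indexing="ij")
        labels = (
            (np.sqrt((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) <= r)
            .astype(np.uint8)
            * m.METAL
        )
        vol = m.label_volume(labels, 1.0)
        face_area = m.class_surface_area(vol, m.METAL)
        smooth = 4.0 * np.pi * (r * 1e-3) ** 2
        assert 1.0 <= face_area / smooth <= 1.6


class TestDegradationRate:
    def test_no_mass_loss(self):
        assert m.degradation_rate(5.0, 5.0, 10.0, 1.0) == 0.0

    def test_direct_arithmetic(self):
        assert m.degradation_rate(12.0, 9.0, 30.0, 0.5) == pytest.approx(0.2)

    def test_halving_t_doubles_dr(self):
        assert m.degradation_rate(12.0, 9.0, 30.0, 0.25) == pytest.approx(
            2 * m.degradation_rate(12.0, 9.0, 30.0, 0.5)
        )

    @pytest.mark.parametrize("ai,t", [(0.0, 1.0), (10.0, 0.0), (10.0, -1.0)])
    def test_invalid_denominators(self, ai, t):
        with pytest.raises(ValueError):
            m.degradation_rate(12.0, 9.0, ai, t)


def _encased_implant(surround_code):
    labels = np.full((5, 5, 5), surround_code, dtype=np.uint8)
    labels[2, 2, 2] = m.METAL
    return m.label_volume(labels, 5.0)


class TestBoneImplantContact:
    def test_fully_encased_in_bone(self):
        assert m.bone_implant_contact(_encased_implant(m.BONE)) == 100.0

    def test_fully_surrounded_by_background(self):
        assert m.bone_implant_contact(_encased_implant(m.BACKGROUND)) == 0.0

    def test_half_contact_constructed(self):
        labels = np.zeros((3, 3, 3), dtype=np.uint8)
        labels[1, 1, 1] = m.METAL
        # bone on 3 of the 6 faces of the single implant voxel
        labels[0, 1, 1] = labels[1, 0, 1] = labels[1, 1, 0] = m.BONE
        vol = m.label_volume(labels, 5.0)
        assert m.bone_implant_contact(vol) == pytest.approx(50.0)
        assert brute_bic(labels) == pytest.approx(50.0)

    def test_no_implant_raises(self):
        vol = m.label_volume(np.zeros((3, 3, 3), dtype=np.uint8), 5.0)
        with pytest.raises(ValueError, match="no implant"):
            m.bone_implant_contact(vol)


def _sphere_reference(r_vox, voxel_um=1.0, pad=30):
    n = 2 * (r_vox + pad) + 1
    c = (n - 1) / 2
    zz, yy, xx = np.meshgrid(*(np.arange(n),) * 3, indexing="ij")
    # half-voxel coverage: "radius r voxels" includes voxels the ball touches
    mask = np.sqrt((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) <= r_vox + 0.5
    vol_mm3 = mask.sum() * (voxel_um * 1e-3) ** 3
    return m.ScrewReference(mask=mask, voxel_um=voxel_um, Vi=vol_mm3, Ai=1.0)


class TestRoi:
    def test_zero_margin_empty(self):
        ref = _sphere_reference(5, pad=8)
        assert not m.make_roi(ref, margin_um=0).any()

    def test_shell_volume_matches_continuous(self):
        ref = _sphere_reference(10, voxel_um=1.0, pad=10)
        roi = m.make_roi(ref, margin_um=5.0)
        expected = 4.0 / 3.0 * np.pi * (15.0**3 - 10.0**3)
        assert roi.sum() == pytest.approx(expected, rel=0.05)

    def test_roi_disjoint_from_screw(self):
        ref = _sphere_reference(6, pad=8)
        roi = m.make_roi(ref, margin_um=4.0)
        assert not (roi & ref.mask).any()

    def test_subvoxel_margin_warns(self):
        ref = _sphere_reference(4, voxel_um=5.0, pad=4)
        with pytest.warns(UserWarning, match="margin"):
            m.make_roi(ref, margin_um=2.0)


class TestBvTv:
    def test_all_bone_is_100(self):
        labels = np.full((4, 4, 4), m.BONE, dtype=np.uint8)
        vol = m.label_volume(labels, 5.0)
        assert m.bv_tv(vol, np.ones_like(labels, dtype=bool)) == 100.0

    def test_direct_count(self, rng):
        labels = np.zeros((10, 10, 100), dtype=np.uint8)
        flat = labels.reshape(-1)
        flat[:4000] = m.BONE
        vol = m.label_volume(labels, 5.0)
        assert m.bv_tv(vol, np.ones_like(labels, dtype=bool)) == pytest.approx(40.0)

    def test_degradation_voxels_excluded(self):
        labels = np.zeros((4, 4, 4), dtype=np.uint8)
        labels[:2] = m.BONE
        labels[3] = m.DEGRADATION
        vol = m.label_volume(labels, 5.0)
        roi_without = np.ones_like(labels, dtype=bool)
        roi_without[3] = False
        roi_with = np.ones_like(labels, dtype=bool)
        # adding degradation-layer voxels to the ROI leaves BV/TV unchanged
        assert m.bv_tv(vol, roi_with) == m.bv_tv(vol, roi_without)

    def test_empty_denominator_raises(self):
        labels = np.full((3, 3, 3), m.METAL, dtype=np.uint8)
        vol = m.label_volume(labels, 5.0)
        with pytest.raises(ValueError, match="ROI"):
            m.bv_tv(vol, np.ones_like(labels, dtype=bool))


class TestReport:
    def test_phantom_recovery(self, small_screw_phantom):
        vol, ref, truth = small_screw_phantom
        res = m.morphometry_report(vol, ref, days=0.5 * m.DAYS_PER_YEAR)
        assert abs(res.dr - truth.dr_true) / truth.dr_true < 0.03
        assert abs(res.bic - truth.bic_true) < 2.0
        assert abs(res.bvtv - truth.bvtv_true) < 2.0

    def test_untouched_screw_zero_loss(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2:6, 2:6, 2:6] = True
        voxvol = (5e-3) ** 3
        ref = m.ScrewReference(
            mask=mask, voxel_um=5.0, Vi=mask.sum() * voxvol, Ai=0.01
        )
        labels = np.where(mask, m.METAL, m.BACKGROUND).astype(np.uint8)
        vol = m.label_volume(labels, 5.0)
        res = m.morphometry_report(vol, ref, days=123.0)
        assert res.dr == 0.0
        assert res.volume_loss == 0.0

    def test_misregistered_reference_rejected(self, small_screw_phantom):
        vol, ref, _ = small_screw_phantom
        bad = m.ScrewReference(
            mask=ref.mask[:-1], voxel_um=ref.voxel_um, Vi=ref.Vi, Ai=ref.Ai
        )
        with pytest.raises(ValueError, match="co-registered"):
            m.morphometry_report(vol, bad, days=61.0)


class TestOracleEquivalence:
    """Production counts vs exhaustive triple loops on small random grids."""

    @pytest.mark.parametrize("seed", range(5))
    def test_counts_and_faces_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        labels = random_labeled_grid(rng, max_side=10)
        vol = m.label_volume(labels, 5.0)
        for code in m.VALID_CODES:
            assert m.class_volume(vol, code) == pytest.approx(
                brute_class_count(labels, code) * (5e-3) ** 3, rel=1e-12
            )
            assert m.class_surface_area(vol, code) == pytest.approx(
                brute_exposed_faces(labels, code) * (5e-3) ** 2, rel=1e-12
            )
        assert m.bone_implant_contact(vol) == pytest.approx(brute_bic(labels))
        roi = ndimage.binary_dilation(np.isin(labels, m.IMPLANT_CODES)) & ~np.isin(
            labels, m.IMPLANT_CODES
        )
        if (labels[roi] < 2).any():
            assert m.bv_tv(vol, roi) == pytest.approx(brute_bvtv(labels, roi))


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_bic_bvtv_bounded(seed):
    rng = np.random.default_rng(seed)
    labels = random_labeled_grid(rng, max_side=8)
    vol = m.label_volume(labels, 5.0)
    assert 0.0 <= m.bone_implant_contact(vol) <= 100.0
    roi = np.ones_like(labels, dtype=bool)
    if np.isin(labels, (m.BONE, m.BACKGROUND)).any():
        assert 0.0 <= m.bv_tv(vol, roi) <= 100.0


def test_resample_labels_halves_extent(small_screw_phantom):
    vol, _, _ = small_screw_phantom
    out = m.resample_labels(vol, vol.voxel_um * 2)
    assert out.voxel_um == vol.voxel_um * 2
    assert abs(out.labels.shape[0] - vol.labels.shape[0] / 2) <= 1
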