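import numpy as np
import pytest
from scipy import ndimage

from ventmap.image import VolumetricImage
from ventmap.registration import (
    DisplacementField,
    RegistrationConfig,
    ingest_field,
    qc_misalignment,
    register_deformable,
    warp,
    write_field,
)


def _zero_field(shape, spacing=(1.0, 1.0, 1.0)):
    return DisplacementField(np.zeros((*shape, 3)), spacing)


class TestWarp:
    def test_zero_field_is_identity(self, ramp_image):
        out, valid = warp(ramp_image, _zero_field(ramp_image.shape))
        np.testing.assert_allclose(out.data, ramp_image.data, atol=1e-12)
        assert valid.all()

    def test_constant_shift_on_linear_ramp(self):
        # ramp along x with slope 2 HU/mm; shifting sample points by +3 mm
        # adds 6 HU everywhere inside the domain
        x = np.arange(20, dtype=float)
        data = np.broadcast_to(2.0 * x[:, None, None], (20, 8, 8)).copy()
        img = VolumetricImage(data, spacing=(1, 1, 1))
        u = np.zeros((20, 8, 8, 3))
        u[..., 0] = 3.0
        out, valid = warp(img, DisplacementField(u, (1, 1, 1)))
        interior = valid
        np.testing.assert_allclose(out.data[interior], data[interior] + 6.0, atol=1e-9)
        assert not valid[18:, :, :].any()  # shifted out of the domain

    def test_nearest_warp_of_labels_creates_no_new_values(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 4, size=(12, 12, 12)).astype(float)
        img = VolumetricImage(labels, spacing=(1, 1, 1))
        u = rng.normal(0, 1.2, size=(12, 12, 12, 3))
        out, _ = warp(img, DisplacementField(u, (1, 1, 1)), interpolation="nearest")
        assert set(np.unique(out.data)) <= set(np.unique(labels))

    def test_linear_interpolation_is_linear_in_intensity(self):
        rng = np.random.default_rng(1)
        a_img = rng.normal(size=(10, 10, 10))
        b_img = rng.normal(size=(10, 10, 10))
        u = rng.normal(0, 1.0, size=(10, 10, 10, 3))
        field = DisplacementField(u, (1, 1, 1))
        wa, _ = warp(VolumetricImage(a_img, (1, 1, 1)), field)
        wb, _ = warp(VolumetricImage(b_img, (1, 1, 1)), field)
        wab, _ = warp(VolumetricImage(2.0 * a_img - 3.0 * b_img, (1, 1, 1)), field)
        np.testing.assert_allclose(wab.data, 2.0 * wa.data - 3.0 * wb.data, atol=1e-10)


class TestFieldIO:
    def test_round_trip(self, tmp_path, ramp_image):
        rng = np.random.default_rng(2)
        f = DisplacementField(rng.normal(size=(16, 16, 16, 3)), (1, 1, 1))
        p = tmp_path / "field.nii.gz"
        write_field(f, p)
        back = ingest_field(p, ramp_image)
        np.testing.assert_allclose(back.vectors, f.vectors, atol=1e-5)

    def test_wrong_component_count_rejected(self, tmp_path, ramp_image):
        import nibabel as nib

        bad = nib.Nifti1Image(np.zeros((16, 16, 16, 2), dtype=np.float32), np.eye(4))
        p = tmp_path / "bad.nii.gz"
        nib.save(bad, p)
        with pytest.raises(ValueError, match="3-component"):
            ingest_field(p, ramp_image)

    def test_voxel_units_scaled_by_spacing(self, tmp_path):
        img = VolumetricImage(np.zeros((8, 8, 8)), spacing=(2.0, 2.0, 2.0))
        f = DisplacementField(np.ones((8, 8, 8, 3)), (2, 2, 2))
        p = tmp_path / "vox.nii.gz"
        write_field(f, p)
        back = ingest_field(p, img, units="voxels")
        np.testing.assert_allclose(back.vectors, 2.0, atol=1e-5)


class TestQC:
    def test_identical_masks_have_zero_distance(self):
        m = np.zeros((16, 16, 16), bool)
        m[4:12, 4:12, 4:12] = True
        rep = qc_misalignment(m, m, (1, 1, 1))
        assert rep.surface_misalignment_mean_mm == 0.0
        assert not rep.excluded

    def test_one_voxel_offset_is_about_one_mm(self):
        # brute-force expectation: shifting a box by one voxel at 1 mm
        # spacing moves most surface points by 1 mm (faces parallel to the
        # shift stay in place at their overlap, so the mean is slightly less)
        a = np.zeros((20, 20, 20), bool)
        a[5:15, 5:15, 5:15] = True
        b = np.roll(a, 1, axis=0)
        rep = qc_misalignment(a, b, (1, 1, 1))
        assert 0.2 < rep.surface_misalignment_mean_mm <= 1.0
        # brute-force oracle for the same quantity
        sa = a & ~ndimage.binary_erosion(a)
        sb = b & ~ndimage.binary_erosion(b)
        pa = np.argwhere(sa).astype(float)
        pb = np.argwhere(sb).astype(float)
        d_ab = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1)).min(1)
        d_ba = np.sqrt(((pb[:, None, :] - pa[None, :, :]) ** 2).sum(-1)).min(1)
        oracle = np.concatenate([d_ab, d_ba]).mean()
        np.testing.assert_allclose(rep.surface_misalignment_mean_mm, oracle, atol=1e-9)

    def test_flagged_exactly_when_above_two_mm(self):
        a = np.zeros((24, 24, 24), bool)
        a[6:18, 6:18, 6:18] = True
        b1 = np.roll(a, 1, axis=2)
        b6 = np.roll(a, 6, axis=2)
        assert not qc_misalignment(a, b1, (1, 1, 1)).excluded
        assert qc_misalignment(a, b6, (1, 1, 1)).excluded

    def test_empty_mask_rejected(self):
        m = np.zeros((8, 8, 8), bool)
        with pytest.raises(ValueError, match="empty"):
            qc_misalignment(m, m, (1, 1, 1))


class TestRegisterDeformable:
    def test_identity_registration_yields_negligible_field(self, small_phantom):
        spec, (insp, *_rest) = small_phantom
        cfg = RegistrationConfig(iterations=(40, 20, 10))
        field, report = register_deformable(insp, insp, cfg)
        mean_vox = field.magnitude().mean() / min(insp.spacing)
        assert mean_vox < 0.1
        assert not report.diverged

    def test_translation_recovered(self, small_phantom):
        # moving = fixed resampled 4 mm along x; recovered displacement in
        # the interior should be close to (+4, 0, 0)
        spec, (insp, *_rest) = small_phantom
        shift = np.zeros((*insp.shape, 3))
        shift[..., 0] = 4.0
        moving, _ = warp(insp, DisplacementField(shift, insp.spacing))
        # moving(x) = insp(x + 4): registering moving onto insp should find
        # u ≈ -4 mm; registering insp onto moving finds +4 mm
        cfg = RegistrationConfig(iterations=(80, 40, 20))
        field, _ = register_deformable(moving, insp, cfg)
        core = np.zeros(insp.shape, bool)
        core[6:-6, 6:-6, 6:-6] = True
        mean_u = field.vectors[core].mean(axis=0)
        assert abs(mean_u[0] - 4.0) < 0.5
        assert abs(mean_u[1]) < 0.5 and abs(mean_u[2]) < 0.5

    def test_phantom_field_recovery_beats_initialization(self, small_phantom):
        from ventmap.registration import _moments_init

        spec, (insp, exp, fu, truth) = small_phantom
        field, report = register_deformable(exp, insp)
        core = ndimage.binary_erosion(truth.lung_mask_exp, iterations=2)
        tv = truth.insp_to_exp_displacement.vectors
        epe = np.linalg.norm(field.vectors - tv, axis=-1)[core].mean()
        u0 = _moments_init(exp, np.asarray(insp.data, float), exp.shape, exp.spacing)
        epe0 = np.linalg.norm(u0 - tv, axis=-1)[core].mean()
        assert epe < epe0 / 1.5
        assert epe / min(exp.spacing) < 2.5  # within 2.5 voxels on average

    def test_non_overlapping_extents_rejected(self, ramp_image):
        far = VolumetricImage(ramp_image.data, (1, 1, 1), origin=(1000, 0, 0))
        with pytest.raises(ValueError, match="overlap"):
            register_deformable(ramp_image, far)
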