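import numpy as np
import pytest
from scipy import ndimage

from ventmap.deformation import jacobian_determinant
from ventmap.image import TissueClass, classify_tissue
from ventmap.phantom import (
    PhantomError,
    PhantomSpec,
    generate_phantom,
    make_cohort,
    mass_conservation,
)


class TestMassConservationModel:
    def test_closed_form_half_exhale(self):
        # β = 0.85, half the air exhaled → J = 0.575 and HU_exp = -739.13
        j, hu = mass_conservation(-850.0, 0.5)
        assert j == pytest.approx(0.575, abs=1e-12)
        assert hu == pytest.approx(-739.1304347826087, abs=1e-9)

    def test_complete_collapse_reaches_zero_hu(self):
        j, hu = mass_conservation(-850.0, 1.0)
        assert hu == pytest.approx(0.0, abs=1e-12)
        assert j == pytest.approx(0.15, abs=1e-12)

    def test_no_exhale_changes_nothing(self):
        j, hu = mass_conservation(-700.0, 0.0)
        assert j == 1.0 and hu == pytest.approx(-700.0)

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(PhantomError):
            mass_conservation(100.0, 0.5)
        with pytest.raises(PhantomError):
            mass_conservation(-800.0, 1.5)


class TestGeneratePhantom:
    def test_deterministic_given_seed(self):
        spec_a = PhantomSpec.default(grid_shape=(24, 24, 24), seed=5)
        spec_b = PhantomSpec.default(grid_shape=(24, 24, 24), seed=5)
        ia, ea, fa, ta = generate_phantom(spec_a)
        ib, eb, fb, tb = generate_phantom(spec_b)
        np.testing.assert_array_equal(ia.data, ib.data)
        np.testing.assert_array_equal(ea.data, eb.data)
        np.testing.assert_array_equal(fa.data, fb.data)
        np.testing.assert_array_equal(
            ta.insp_to_exp_displacement.vectors, tb.insp_to_exp_displacement.vectors
        )

    def test_zero_ventilation_gives_identical_breath_holds(self):
        spec = PhantomSpec.default(grid_shape=(24, 24, 24), seed=0)
        spec.hu_noise_sd = 0.0
        spec.exp_noise_sd = 0.0
        spec.progression.enabled = False
        spec.progression.density_noise_sd = 0.0
        v = spec.ventilation
        v.base = 0.0
        v.apicobasal_span = 0.0
        v.texture_sd = 0.0
        v.hotspots = []
        insp, exp, fu, truth = generate_phantom(spec)
        np.testing.assert_allclose(exp.data, insp.data, atol=1e-9)
        np.testing.assert_allclose(fu.data, insp.data, atol=1e-9)
        np.testing.assert_allclose(truth.insp_to_exp_jacobian, 1.0, atol=1e-12)
        assert np.abs(truth.insp_to_exp_displacement.vectors).max() < 1e-9

    def test_mass_conservation_identity_exact_on_noisefree_grids(self, noisefree_phantom):
        # 1 − J*·(HU_exp/HU_inspWarped) = v* voxel-exactly wherever the air
        # fraction is in the physical range and no clamping applies
        spec, (insp, exp, fu, truth) = noisefree_phantom
        hw = truth.insp_warped_noisefree
        beta = -hw / 1000.0
        sel = (
            truth.lung_mask_exp
            & (beta > 0.06)
            & (beta < 0.999)
            & (truth.ventilation_field < 1.0)
        )
        lhs = 1.0 - truth.insp_to_exp_jacobian[sel] * (
            truth.hu_exp_noisefree[sel] / hw[sel]
        )
        np.testing.assert_allclose(lhs, truth.ventilation_field[sel], atol=1e-10)

    def test_truth_jacobian_is_one_minus_v_beta(self, noisefree_phantom):
        spec, (insp, exp, fu, truth) = noisefree_phantom
        hw = truth.insp_warped_noisefree
        beta = np.clip(-hw / 1000.0, 0.0, 1.0)
        sel = truth.lung_mask_exp & (beta > 0.06) & (truth.ventilation_field < 1.0)
        np.testing.assert_allclose(
            truth.insp_to_exp_jacobian[sel],
            1.0 - truth.ventilation_field[sel] * beta[sel],
            atol=1e-10,
        )

    def test_displacement_realization_residual_small(self, noisefree_phantom):
        # finite-difference determinant of the realized field vs the target
        # J* over an interior lung core
        spec, (insp, exp, fu, truth) = noisefree_phantom
        assert truth.jacobian_fit_residual < 0.08
        det = jacobian_determinant(truth.insp_to_exp_displacement).values
        core = ndimage.binary_erosion(truth.lung_mask_exp, iterations=3)
        err = np.abs(1.0 / det[core] - truth.insp_to_exp_jacobian[core])
        assert err.mean() < 0.01  # pointwise max is looser at this scale

    def test_class_fractions_match_recorded_target(self, small_phantom):
        # classification of the noisy inspiration vs the generator's
        # noise-free class bookkeeping, within 2 percentage points
        spec, (insp, exp, fu, truth) = small_phantom
        cm = classify_tissue(insp, truth.lung_mask_insp)
        n = truth.lung_mask_insp.sum()
        for name in ("NAA", "HAA", "EXCLUDED_LOW", "EXCLUDED_HIGH"):
            measured = cm.counts[name] / n
            assert abs(measured - truth.class_fractions_insp[name]) < 0.02

    def test_truth_ventilation_in_unit_interval(self, small_phantom):
        spec, (insp, exp, fu, truth) = small_phantom
        v = truth.ventilation_field
        assert v.min() >= 0.0 and v.max() <= 1.0

    def test_infeasible_progression_rejected(self):
        spec = PhantomSpec.default(grid_shape=(24, 24, 24), seed=0)
        spec.progression.volume_change_pct = {"C2": -150.0, "C3": -150.0, "C4": -150.0}
        with pytest.raises(PhantomError, match="progression"):
            generate_phantom(spec)

    def test_small_grid_rejected(self):
        with pytest.raises(PhantomError, match="grid_shape"):
            PhantomSpec(grid_shape=(8, 8, 8))

    def test_oversized_lung_rejected(self):
        with pytest.raises(PhantomError, match="margin"):
            PhantomSpec(grid_shape=(24, 24, 24), lung_semi_axes_mm=(30.0, 10.0, 10.0))


class TestMakeCohort:
    def test_bit_identical_for_same_seed(self):
        spec = PhantomSpec.stats_default(grid_shape=(20, 20, 20))
        a = make_cohort(spec, 3, coupling_strength=10.0, seed=7)
        b = make_cohort(spec, 3, coupling_strength=10.0, seed=7)
        for (ia, _, fa, _), (ib, _, fb, _) in zip(a, b):
            np.testing.assert_array_equal(ia.data, ib.data)
            np.testing.assert_array_equal(fa.data, fb.data)

    def test_minimum_cohort_size(self):
        spec = PhantomSpec.stats_default()
        with pytest.raises(PhantomError, match="2 subjects"):
            make_cohort(spec, 1)

    def test_geometry_varies_across_subjects(self):
        spec = PhantomSpec.stats_default(grid_shape=(20, 20, 20))
        cohort = make_cohort(spec, 3, seed=1)
        sizes = [t.lung_mask_insp.sum() for (_, _, _, t) in cohort]
        assert len(set(sizes)) > 1
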