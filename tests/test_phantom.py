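"""Phantom generator: determinism, analytic volumes, cohort variation."""

import numpy as np
import pytest

from pmbrainvol.core import BRAINSTEM, CEREBELLUM, CEREBRUM, CLASS_LABELS, CSF
from pmbrainvol.phantom import (Ellipsoid, PhantomGeometryError, PhantomSpec,
                                atlas_from_truth, default_geometry,
                                generate_cohort, generate_phantom)


def test_identical_seed_gives_bit_identical_output():
    a_img, a_truth = generate_phantom(PhantomSpec(seed=5))
    b_img, b_truth = generate_phantom(PhantomSpec(seed=5))
    np.testing.assert_array_equal(a_img.data, b_img.data)
    np.testing.assert_array_equal(a_truth.label_map.data, b_truth.label_map.data)


def test_different_seed_same_labels_different_noise():
    a_img, a_truth = generate_phantom(PhantomSpec(seed=1))
    b_img, b_truth = generate_phantom(PhantomSpec(seed=2))
    np.testing.assert_array_equal(a_truth.label_map.data, b_truth.label_map.data)
    assert not np.array_equal(a_img.data, b_img.data)


def test_zero_noise_unit_bias_gives_piecewise_constant_image(clean_phantom):
    img, truth = clean_phantom
    for lbl, mean in PhantomSpec().class_mean_intensities.items():
        region = truth.label_map.data == lbl
        if region.any():
            assert np.all(img.data[region] == mean)


@pytest.mark.parametrize("region_name", ["cerebellum", "brainstem"])
def test_voxelized_volume_matches_analytic_ellipsoid(region_name, clean_phantom):
    """Voxel-count volume agrees with 4/3*pi*a*b*c within one voxel shell."""
    spec = PhantomSpec()
    _, truth = clean_phantom
    region = next(r for r in default_geometry() if r.name == region_name)
    analytic_mL = region.analytic_volume_mm3(spec.grid_shape, spec.spacing) / 1000.0
    measured_mL = truth.true_volumes_mL[region.label]
    # one-voxel-shell bound: surface area x voxel size
    semi_vox = np.array(region.semiaxes) * np.array(spec.grid_shape)
    r_eff = semi_vox.prod() ** (1 / 3)
    shell_mL = 4 * np.pi * r_eff ** 2 * spec.voxel_size_mm ** 3 / 1000.0
    assert abs(measured_mL - analytic_mL) < shell_mL


def test_true_volumes_equal_label_counts(phantom):
    img, truth = phantom
    for lbl in CLASS_LABELS:
        expected = truth.label_map.count(lbl) * img.voxel_volume_mm3 / 1000.0
        assert truth.true_volumes_mL[lbl] == pytest.approx(expected)


def test_region_volumes_sum_to_head_volume(phantom):
    img, truth = phantom
    head_mL = truth.head_mask.sum() * img.voxel_volume_mm3 / 1000.0
    assert sum(truth.true_volumes_mL.values()) == pytest.approx(head_mL)


def test_bias_amplitude_is_peak_to_trough_ratio():
    spec = PhantomSpec(seed=3, bias_amplitude=1.4, class_noise_sd=0)
    _, truth = generate_phantom(spec)
    b = truth.true_bias_field.data
    assert b.max() / b.min() == pytest.approx(1.4, rel=1e-6)
    assert (b > 0).all()


def test_degenerate_geometry_reports_region_name():
    bad = (Ellipsoid("head", CSF, (0.0, 0.0, 0.0), (0.8, 0.8, 0.8)),)
    with pytest.raises(PhantomGeometryError, match="head"):
        generate_phantom(PhantomSpec(region_geometry=bad))


def test_spec_invariants_rejected():
    with pytest.raises(ValueError):
        PhantomSpec(bias_amplitude=0.9)
    with pytest.raises(ValueError):
        PhantomSpec(class_noise_sd=-1)
    with pytest.raises(ValueError):
        PhantomSpec(voxel_size_mm=0)


# -- cohorts ---------------------------------------------------------------

def test_zero_deformation_cohort_matches_base():
    base_img, base_truth = generate_phantom(PhantomSpec(seed=4, deform_sd=0.0,
                                                        class_noise_sd=0, bias_amplitude=1.0))
    cohort = generate_cohort(PhantomSpec(seed=4, deform_sd=0.0,
                                         class_noise_sd=0, bias_amplitude=1.0), 3)
    for img, truth in cohort:
        np.testing.assert_array_equal(truth.label_map.data, base_truth.label_map.data)
        np.testing.assert_array_equal(img.data, base_img.data)


def test_cohort_reproducible_and_subjects_differ():
    a = generate_cohort(PhantomSpec(seed=9, deform_sd=1.5), 3)
    b = generate_cohort(PhantomSpec(seed=9, deform_sd=1.5), 3)
    for (ia, ta), (ib, tb) in zip(a, b):
        np.testing.assert_array_equal(ia.data, ib.data)
    assert not np.array_equal(a[0][1].label_map.data, a[1][1].label_map.data)


def test_cohort_volume_spread_grows_with_deformation():
    """Coefficient of variation of cerebrum volume increases with deform_sd."""
    def cov(sd):
        cohort = generate_cohort(PhantomSpec(seed=21, deform_sd=sd, class_noise_sd=0), 8)
        v = np.array([t.true_volumes_mL[CEREBRUM] for _, t in cohort])
        return v.std() / v.mean()
    assert cov(0.5) < cov(2.5)


def test_cohort_size_validated():
    with pytest.raises(ValueError):
        generate_cohort(PhantomSpec(), 0)


# -- truth-derived atlas ---------------------------------------------------

def test_single_truth_no_smoothing_gives_one_hot(clean_phantom):
    _, truth = clean_phantom
    atlas = atlas_from_truth([truth], smoothing_mm=0.0)
    inside = atlas.mask.data > 0
    stack = atlas.prior_stack()
    np.testing.assert_allclose(stack.sum(axis=0)[inside], 1.0)
    assert set(np.unique(stack[:, inside])) <= {0.0, 1.0}


def test_priors_sum_to_one_inside_mask(truth_atlas):
    inside = truth_atlas.mask.data > 0
    total = truth_atlas.prior_stack().sum(axis=0)
    np.testing.assert_allclose(total[inside], 1.0, atol=1e-9)


def test_smoothing_never_sharpens_priors(clean_phantom):
    _, truth = clean_phantom
    maxima = []
    for s in (0.0, 1.2, 3.0):
        atlas = atlas_from_truth([truth], smoothing_mm=s)
        maxima.append(atlas.priors[CEREBELLUM].max())
    assert maxima[0] >= maxima[1] >= maxima[2]
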