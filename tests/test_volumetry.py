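"""Threshold exclusion, unit conversion, weight formula, cohort tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pmbrainvol.core import CEREBRUM, CSF, LabelMap, VolumeImage
from pmbrainvol.volumetry import (BRAIN_DENSITY_G_PER_ML, apply_csf_threshold,
                                  compute_volume, load_fetal_table,
                                  load_newborn_table, load_subject_table,
                                  suggest_csf_threshold, volume_to_weight)


@pytest.fixture()
def bimodal_region():
    """Cerebrum at 600, fluid at 900 inside one merged region."""
    rng = np.random.default_rng(3)
    shape = (24, 24, 24)
    labels = np.zeros(shape, np.int16)
    labels[4:20, 4:20, 4:20] = CEREBRUM
    fluid = np.zeros(shape, bool)
    fluid[4:20, 4:20, 14:20] = True
    y = np.where(fluid, 900.0, 600.0) + rng.normal(0, 20.0, shape)
    img = VolumeImage(y, spacing=(0.6, 0.6, 0.6))
    region = LabelMap((labels > 0).astype(np.int16), spacing=img.spacing)
    return img, region, fluid


def test_infinite_threshold_keeps_region(bimodal_region):
    img, region, _ = bimodal_region
    out = apply_csf_threshold(img, region, np.inf)
    np.testing.assert_array_equal(out.data, region.data)


def test_minus_infinite_threshold_empties_region(bimodal_region, caplog):
    img, region, _ = bimodal_region
    with caplog.at_level("WARNING"):
        out = apply_csf_threshold(img, region, -np.inf)
    assert out.data.sum() == 0


def test_threshold_separates_modes_within_three_percent(bimodal_region):
    img, region, fluid = bimodal_region
    out = apply_csf_threshold(img, region, 750.0)
    true_cerebrum = (region.data > 0) & ~fluid
    got = compute_volume(out)
    want = true_cerebrum.sum() * 0.6 ** 3 / 1000.0
    assert got == pytest.approx(want, rel=0.03)


def test_boundary_voxels_at_threshold_are_retained():
    img = VolumeImage(np.full((2, 2, 2), 700.0), spacing=(1, 1, 1))
    region = LabelMap(np.ones((2, 2, 2), np.int16), spacing=(1, 1, 1))
    assert apply_csf_threshold(img, region, 700.0).data.sum() == 8


def test_threshold_monotonicity(bimodal_region):
    img, region, _ = bimodal_region
    vols = [compute_volume(apply_csf_threshold(img, region, t))
            for t in (500.0, 650.0, 800.0, 950.0)]
    assert vols == sorted(vols)


def test_suggested_threshold_lies_between_modes(bimodal_region):
    img, region, _ = bimodal_region
    t = suggest_csf_threshold(img, region)
    assert 650.0 < t < 880.0


def test_volume_unit_conversion():
    mask = LabelMap(np.ones((10, 10, 10), np.int16), spacing=(1, 1, 1))
    assert compute_volume(mask) == pytest.approx(1.0)
    single = np.zeros((3, 3, 3), np.int16)
    single[1, 1, 1] = 1
    one = LabelMap(single, spacing=(0.6, 0.6, 0.6))
    assert compute_volume(one) == pytest.approx(2.16e-4)
    assert compute_volume(LabelMap(np.zeros((3, 3, 3), np.int16), spacing=(1, 1, 1))) == 0.0


def test_volume_rejects_bad_spacing():
    mask = LabelMap(np.ones((2, 2, 2), np.int16), spacing=(1, 1, 1))
    with pytest.raises(ValueError):
        compute_volume(mask, voxel_size_mm=0.0)


@pytest.mark.parametrize("volume_mL, weight_g", [(213.39, 230.46), (113.70, 122.80)])
def test_weight_formula_matches_printed_rows(volume_mL, weight_g):
    """Two cohort-table rows where volume x 1.08 reproduces the printed
    weight exactly at 2 decimals."""
    assert round(volume_to_weight(volume_mL), 2) == weight_g


def test_weight_of_zero_volume_is_zero():
    assert volume_to_weight(0.0) == 0.0
    with pytest.raises(ValueError):
        volume_to_weight(-1.0)
    with pytest.raises(ValueError):
        volume_to_weight(1.0, density_g_per_mL=0.0)


@settings(max_examples=50, deadline=None)
@given(a=st.floats(0, 1e4), b=st.floats(0, 1e4))
def test_weight_is_linear_in_volume(a, b):
    assert volume_to_weight(a + b) == pytest.approx(
        volume_to_weight(a) + volume_to_weight(b), rel=1e-12, abs=1e-9)


# -- cohort tables ---------------------------------------------------------

def test_newborn_table_counts():
    records = load_newborn_table()
    assert len(records) == 17
    assert sum(r.has_autopsy for r in records) == 15


def test_fetal_table_counts():
    records = load_fetal_table()
    assert len(records) == 17
    assert sum(r.has_autopsy for r in records) == 13


def test_missing_values_are_none():
    records = {r.subject_id: r for r in load_newborn_table()}
    assert records["274"].autopsy_weight_g is None
    assert records["256"].manual_weight_g is None
    assert records["193"].manual_weight_g == pytest.approx(446.08)


def test_empty_table_rejected(tmp_path):
    p = tmp_path / "empty.csv"
    p.write_text("subject_id,gestational_age_weeks,csf_threshold,mri_volume_mL,mri_weight_g\n")
    with pytest.raises(ValueError, match="empty"):
        load_subject_table(p)


def test_malformed_row_reported_with_number(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("subject_id,gestational_age_weeks,csf_threshold,mri_volume_mL,mri_weight_g\n"
                 "a,40,600,100.0,108.0\n"
                 "b,not-a-number,600,100.0,108.0\n")
    with pytest.raises(ValueError, match="row 3"):
        load_subject_table(p)


def test_missing_columns_rejected(tmp_path):
    p = tmp_path / "cols.csv"
    p.write_text("subject_id,mri_volume_mL\n1,10\n")
    with pytest.raises(ValueError, match="missing columns"):
        load_subject_table(p)
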