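"""End-to-end cohort pipelines and the printed-table reproduction check.

Per-subject chain (both cohorts): register the subject image to the prior
atlas, propagate the brain mask, estimate and correct the bias field,
resample the class priors, run the EM-MRF segmentation, merge cerebrum
with CSF, then threshold out fluid and convert the retained volume to a
weight.  The newborn pipeline additionally builds a groupwise average
atlas from the cohort segmentations; the fetal pipeline consumes that
atlas (optionally comparing two prior sources).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import validation, volumetry
from .atlas_builder import DEFAULT_SCHEDULE, GroupwiseResult, build_groupwise_atlas
from .core import CEREBRUM, LabelMap, ProbabilisticAtlas, VolumeImage
from .em import DEFAULT_MERGE_GROUPS, EMParams, SegmentationResult, em_segment, merge_classes
from .preprocess import (apply_mask_edits, correct_bias, estimate_bias_field,
                         propagate_mask, refine_mask)
from .registration import RegistrationParams, register, resample_priors
from .volumetry import SubjectRecord

log = logging.getLogger(__name__)

#: Published cohort aggregates that `reproduce_tables` asserts, in integer
#: grams: mean MRI, mean autopsy, mean absolute difference, LoA low/high.
EXPECTED_AGGREGATES = {
    "newborn": {"mean_test_g": 418, "mean_reference_g": 434,
                "mean_absolute_difference_g": 20, "loa_low_g": -32, "loa_high_g": 65},
    "fetal": {"mean_test_g": 310, "mean_reference_g": 312,
              "mean_absolute_difference_g": 5, "loa_low_g": -7, "loa_high_g": 12},
}


@dataclass
class PipelineConfig:
    cohort: str = "newborn"
    em: EMParams = dc_field(default_factory=EMParams)
    registration: RegistrationParams = dc_field(default_factory=RegistrationParams)
    schedule: tuple[str, ...] = DEFAULT_SCHEDULE
    registration_kind: str = "demons"       # subject-to-atlas prior propagation
    csf_thresholds: dict[str, float] = dc_field(default_factory=dict)
    density_g_per_mL: float = volumetry.BRAIN_DENSITY_G_PER_ML
    bias_order: int = 5
    mask_refine_fraction: float = 0.3       # 0 disables intensity-based mask cleanup
    build_atlas: bool = True
    out_dir: Path | None = None
    seed: int = 0

    def digest(self) -> str:
        blob = json.dumps({k: str(v) for k, v in self.__dict__.items()},
                          sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class SubjectOutput:
    subject_id: str
    segmentation: SegmentationResult
    merged_labels: LabelMap
    corrected_image: VolumeImage
    mask: LabelMap
    record: SubjectRecord


@dataclass
class CohortOutput:
    subjects: list[SubjectOutput]
    atlas: ProbabilisticAtlas | None
    groupwise: GroupwiseResult | None
    skipped: list[str]


def segment_subject(subject_id: str, image: VolumeImage,
                    atlas: ProbabilisticAtlas, config: PipelineConfig,
                    mask_edits: LabelMap | None = None) -> SubjectOutput:
    """Run the per-subject chain against a prior atlas."""
    t = register(image, atlas.template, config.registration_kind, config.registration)
    mask = propagate_mask(atlas, t, image)
    if mask_edits is not None:
        mask = apply_mask_edits(mask, mask_edits)
    if config.mask_refine_fraction > 0:
        mask = refine_mask(image, mask, config.mask_refine_fraction)
    # noise can push isolated mask-edge voxels non-positive; the log-domain
    # bias fit is restricted to positive intensities
    fit_mask = LabelMap(((mask.data > 0) & (image.data > 0)).astype(np.int16),
                        spacing=mask.spacing, origin=mask.origin)
    bias = estimate_bias_field(image, fit_mask, order=config.bias_order)
    corrected = correct_bias(image, bias)
    priors = resample_priors(atlas.priors, atlas.template, t, image)
    seg = em_segment(corrected, priors, mask, config.em)
    merged, _ = merge_classes(seg, DEFAULT_MERGE_GROUPS)

    region = LabelMap((merged.data == CEREBRUM).astype(np.int16),
                      spacing=merged.spacing, origin=merged.origin)
    threshold = config.csf_thresholds.get(subject_id, float("inf"))
    kept = volumetry.apply_csf_threshold(corrected, region, threshold)
    vol = volumetry.compute_volume(kept)
    weight = volumetry.volume_to_weight(vol, config.density_g_per_mL)
    record = SubjectRecord(
        subject_id=subject_id, gestational_age_weeks=0,
        gestational_age_extra_days=None, postnatal_age_days=None,
        csf_threshold=threshold, mri_volume_mL=vol, mri_weight_g=weight,
        manual_weight_g=None, autopsy_weight_g=None)
    return SubjectOutput(subject_id, seg, merged, corrected, mask, record)


def _run_cohort(config: PipelineConfig,
                subjects: Sequence[tuple[str, VolumeImage]],
                atlas: ProbabilisticAtlas,
                build_atlas: bool) -> CohortOutput:
    outputs: list[SubjectOutput] = []
    skipped: list[str] = []
    for sid, image in subjects:
        try:
            outputs.append(segment_subject(sid, image, atlas, config))
        except Exception as e:              # noqa: BLE001 - per-subject robustness
            log.warning("subject %s skipped: %s", sid, e)
            skipped.append(sid)
    if build_atlas and len(outputs) < 2:
        raise RuntimeError("cohort stages need at least 2 surviving subjects")
    gw = None
    new_atlas = None
    if build_atlas:
        gw = build_groupwise_atlas(
            [o.corrected_image for o in outputs],
            [o.segmentation for o in outputs],
            [o.mask for o in outputs],
            schedule=config.schedule, params=config.registration)
        new_atlas = gw.atlas
    out = CohortOutput(outputs, new_atlas, gw, skipped)
    if config.out_dir is not None:
        _write_outputs(out, config)
    return out


def run_newborn_pipeline(config: PipelineConfig,
                         subjects: Sequence[tuple[str, VolumeImage]],
                         initial_atlas: ProbabilisticAtlas) -> CohortOutput:
    """Newborn cohort: segment with an external prior atlas, then build the
    cohort-average atlas from the results."""
    return _run_cohort(config, subjects, initial_atlas, config.build_atlas)


def run_fetal_pipeline(config: PipelineConfig,
                       subjects: Sequence[tuple[str, VolumeImage]],
                       atlas: ProbabilisticAtlas,
                       compare_atlas: ProbabilisticAtlas | None = None
                       ) -> CohortOutput | tuple[CohortOutput, CohortOutput]:
    """Fetal cohort: same chain with the supplied (cohort-built) atlas.

    With ``compare_atlas`` the cohort is segmented twice, once per prior
    source, and both outputs are returned (primary first) so per-class
    Dice against a reference can be tabulated."""
    primary = _run_cohort(config, subjects, atlas, build_atlas=False)
    if compare_atlas is None:
        return primary
    secondary = _run_cohort(config, subjects, compare_atlas, build_atlas=False)
    return primary, secondary


def _write_outputs(out: CohortOutput, config: PipelineConfig) -> None:
    d = Path(config.out_dir)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for o in out.subjects:
        o.merged_labels.to_nifti(d / f"{o.subject_id}_labels.nii.gz")
        rows.append({"subject_id": o.subject_id,
                     "csf_threshold": o.record.csf_threshold,
                     "voxels_retained": int(round(o.record.mri_volume_mL * 1000
                                                  / o.merged_labels.voxel_volume_mm3)),
                     "volume_mL": round(o.record.mri_volume_mL, 2),
                     "weight_g": round(o.record.mri_weight_g, 2)})
    volumetry.volumetry_report(rows, d / "volumetry.csv")
    if out.atlas is not None:
        out.atlas.save(d / "atlas")
    (d / "provenance.json").write_text(json.dumps(
        {"config_digest": config.digest(), "skipped": out.skipped,
         "cohort": config.cohort, "seed": config.seed}, indent=2))


# -- printed-table reproduction -------------------------------------------

def reproduce_tables(tables_dir: str | Path | None = None) -> dict:
    """Recompute the cohort aggregate statistics from the packaged tables
    and check them against the expected printed values.

    Returns a report dict with per-cohort statistics, the row-level weight
    round-trip (volume x density vs printed weight), and an overall ``ok``
    flag that is False if any rounded aggregate deviates.
    """
    if tables_dir is None:
        paths = {"newborn": volumetry.NEWBORN_TABLE, "fetal": volumetry.FETAL_TABLE}
    else:
        tables_dir = Path(tables_dir)
        paths = {"newborn": tables_dir / "newborn_cohort.csv",
                 "fetal": tables_dir / "fetal_cohort.csv"}
    report: dict = {"cohorts": {}, "ok": True}
    for cohort, path in paths.items():
        records = volumetry.load_subject_table(path)
        stats, plot = validation.cohort_summary(records)
        rounded = stats.rounded()
        expected = EXPECTED_AGGREGATES[cohort]
        mismatches = {k: (rounded[k], v) for k, v in expected.items()
                      if rounded[k] != v}
        roundtrip = [{
            "subject_id": r.subject_id,
            "printed_weight_g": r.mri_weight_g,
            "computed_weight_g": round(volumetry.volume_to_weight(r.mri_volume_mL), 2),
            "abs_error_g": round(abs(volumetry.volume_to_weight(r.mri_volume_mL)
                                     - r.mri_weight_g), 3),
        } for r in records]
        report["cohorts"][cohort] = {
            "n_records": len(records),
            "n_complete_pairs": stats.n,
            "aggregates_g": rounded,
            "expected_g": expected,
            "mismatches": mismatches,
            "mean_difference_g": stats.mean_difference_g,
            "sd_difference_g": stats.sd_difference_g,
            "max_relative_error_fraction": stats.max_relative_error_fraction,
            "weight_roundtrip": roundtrip,
            "plot_data": plot.to_dict(orient="records"),
        }
        if mismatches:
            report["ok"] = False
            log.error("%s cohort aggregates deviate: %s", cohort, mismatches)
    return report
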