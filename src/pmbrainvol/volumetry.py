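"""CSF-threshold exclusion, volume computation and weight estimation.

The merged cerebrum+CSF segmentation still contains free fluid that does
not contribute to the cerebrum weight measured at autopsy (fluid largely
leaks out before weighing).  On heavily T2-weighted post-mortem images
fluid is bright, so a per-subject intensity threshold removes it: voxels
*strictly above* the threshold are excluded, boundary voxels equal to it
are retained.  Volume is voxel count x voxel volume; weight is volume
times a literature brain density of 1.08 g/mL.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import LabelMap, VolumeImage

log = logging.getLogger(__name__)

#: Literature cerebrum density used to convert mL to g.
BRAIN_DENSITY_G_PER_ML = 1.08

DATA_DIR = Path(__file__).parent / "data"
NEWBORN_TABLE = DATA_DIR / "newborn_cohort.csv"
FETAL_TABLE = DATA_DIR / "fetal_cohort.csv"


@dataclass
class SubjectRecord:
    """One cohort-table row: identifiers, ages, threshold, volume, weights.

    Missing values (manual or autopsy weight not available) are ``None``.
    """

    subject_id: str
    gestational_age_weeks: int
    gestational_age_extra_days: int | None
    postnatal_age_days: int | None
    csf_threshold: float
    mri_volume_mL: float
    mri_weight_g: float
    manual_weight_g: float | None
    autopsy_weight_g: float | None

    def __post_init__(self) -> None:
        for name in ("mri_volume_mL", "mri_weight_g"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.subject_id}: {name} must be >= 0")

    @property
    def has_autopsy(self) -> bool:
        return self.autopsy_weight_g is not None


def apply_csf_threshold(image: VolumeImage, region: LabelMap,
                        threshold: float) -> LabelMap:
    """Exclude fluid voxels from the merged cerebrum+CSF region.

    Voxels with intensity strictly greater than ``threshold`` are removed;
    voxels equal to it are retained.
    """
    image.require_same_grid(region, "apply_csf_threshold")
    if math.isnan(threshold):
        raise ValueError("threshold must be a number")
    reg = region.data > 0
    kept = reg & (image.data <= threshold)
    excluded = int(np.count_nonzero(reg) - np.count_nonzero(kept))
    log.info("CSF threshold %s: %d voxels excluded, %d retained",
             threshold, excluded, int(np.count_nonzero(kept)))
    if reg.any() and not kept.any():
        log.warning("threshold %s is below the region minimum; result is empty",
                    threshold)
    return LabelMap(kept.astype(np.int16), spacing=region.spacing, origin=region.origin)


def compute_volume(mask: LabelMap, voxel_size_mm=None) -> float:
    """Volume in mL: voxel count x voxel volume (mm^3) x 1e-3."""
    if voxel_size_mm is None:
        spacing = mask.spacing
    elif np.isscalar(voxel_size_mm):
        spacing = (float(voxel_size_mm),) * 3
    else:
        spacing = tuple(float(s) for s in voxel_size_mm)
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive voxel spacing {spacing}")
    n = int(np.count_nonzero(mask.data))
    return n * float(np.prod(spacing)) / 1000.0


def volume_to_weight(volume_mL: float,
                     density_g_per_mL: float = BRAIN_DENSITY_G_PER_ML) -> float:
    """Weight in g from volume in mL (report at 2 decimals)."""
    if volume_mL < 0:
        raise ValueError("volume must be >= 0")
    if density_g_per_mL <= 0:
        raise ValueError("density must be > 0")
    return volume_mL * density_g_per_mL


def suggest_csf_threshold(image: VolumeImage, region: LabelMap,
                          bins: int = 64) -> float:
    """Experimental: propose a threshold at the histogram valley between
    the two highest modes of the cerebrum+CSF intensity distribution."""
    vals = image.data[region.data > 0]
    if vals.size == 0:
        raise ValueError("region is empty")
    raw, edges = np.histogram(vals, bins=bins)
    from scipy.ndimage import gaussian_filter1d
    hist = gaussian_filter1d(raw.astype(float), 2.0)
    # modes = two largest local maxima of the smoothed histogram
    peaks = [i for i in range(1, bins - 1) if hist[i] >= hist[i - 1] and hist[i] >= hist[i + 1]]
    peaks = sorted(peaks, key=lambda i: hist[i], reverse=True)[:2]
    if len(peaks) < 2 or abs(peaks[0] - peaks[1]) < 3:
        return float(np.median(vals))
    lo, hi = sorted(peaks)
    valley = lo + int(np.argmin(hist[lo:hi + 1]))
    return float(0.5 * (edges[valley] + edges[valley + 1]))


# -- cohort tables ---------------------------------------------------------

def _opt(v) -> float | None:
    if pd.isna(v) or (isinstance(v, str) and v.strip().upper() in ("N/A", "NA", "")):
        return None
    return float(v)


def load_subject_table(path: str | Path) -> list[SubjectRecord]:
    """Load a cohort CSV into typed records ("N/A" marks missing values)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty:
        raise ValueError(f"{path}: table is empty")
    required = {"subject_id", "gestational_age_weeks", "csf_threshold",
                "mri_volume_mL", "mri_weight_g"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(SubjectRecord(
                subject_id=str(row["subject_id"]),
                gestational_age_weeks=int(row["gestational_age_weeks"]),
                gestational_age_extra_days=(int(row["gestational_age_extra_days"])
                                            if "gestational_age_extra_days" in df.columns
                                            and row["gestational_age_extra_days"] != "" else None),
                postnatal_age_days=(int(row["postnatal_age_days"])
                                    if "postnatal_age_days" in df.columns
                                    and row["postnatal_age_days"] != "" else None),
                csf_threshold=float(row["csf_threshold"]),
                mri_volume_mL=float(row["mri_volume_mL"]),
                mri_weight_g=float(row["mri_weight_g"]),
                manual_weight_g=_opt(row.get("manual_weight_g")),
                autopsy_weight_g=_opt(row.get("autopsy_weight_g")),
            ))
        except (KeyError, ValueError, TypeError) as e:
            raise ValueError(f"{path}: malformed row {i + 2}: {e}") from e
    return records


def load_newborn_table() -> list[SubjectRecord]:
    return load_subject_table(NEWBORN_TABLE)


def load_fetal_table() -> list[SubjectRecord]:
    return load_subject_table(FETAL_TABLE)


def volumetry_report(entries: list[dict], path: str | Path | None = None) -> pd.DataFrame:
    """Per-run report: id, threshold, voxels retained, volume mL, weight g."""
    df = pd.DataFrame(entries, columns=["subject_id", "csf_threshold",
                                        "voxels_retained", "volume_mL", "weight_g"])
    if path is not None:
        df.to_csv(path, index=False)
    return df
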