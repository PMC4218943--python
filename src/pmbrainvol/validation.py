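"""Dice overlap and Bland–Altman agreement statistics.

Dice is the number of voxels on which two segmentations agree for a
label, divided by the average number of voxels carrying that label —
algebraically 2|A∩B|/(|A|+|B|).

Method agreement between the MRI-derived weight and the autopsy scale
follows Bland & Altman: differences are taken as *reference − test*
(autopsy − MRI), their sample standard deviation uses the n−1
denominator, and the 95% limits of agreement are mean ± 1.96·SD.
Aggregates are reported rounded to the nearest gram (half away from
zero).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CLASS_NAMES, LabelMap
from .volumetry import SubjectRecord

log = logging.getLogger(__name__)


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


@dataclass
class AgreementStats:
    """Bland–Altman summary for paired reference/test measurements (g)."""

    n: int
    mean_reference_g: float
    mean_test_g: float
    mean_difference_g: float
    sd_difference_g: float
    loa_low_g: float
    loa_high_g: float
    mean_absolute_difference_g: float
    max_relative_error_fraction: float

    def rounded(self) -> dict[str, int]:
        """Integer-gram report, matching how cohort aggregates are printed."""
        return {
            "mean_reference_g": _round_half_away(self.mean_reference_g),
            "mean_test_g": _round_half_away(self.mean_test_g),
            "mean_absolute_difference_g": _round_half_away(self.mean_absolute_difference_g),
            "loa_low_g": _round_half_away(self.loa_low_g),
            "loa_high_g": _round_half_away(self.loa_high_g),
        }


def dice(a: LabelMap, b: LabelMap, label: int) -> float:
    """Dice overlap of one label between two maps on a common grid.

    Defined as |A∩B| / ((|A|+|B|)/2).  If the label is absent from both
    maps the score is 1.0 by convention (logged as a warning).
    """
    a.require_same_grid(b, "dice")
    ma = a.data == label
    mb = b.data == label
    na, nb = int(ma.sum()), int(mb.sum())
    if na + nb == 0:
        log.warning("dice: label %s absent from both maps; returning 1.0", label)
        return 1.0
    inter = int(np.count_nonzero(ma & mb))
    return inter / ((na + nb) / 2.0)


def bland_altman(pairs) -> AgreementStats:
    """Agreement statistics for (reference, test) weight pairs.

    Differences are reference − test; SD uses the n−1 denominator; limits
    of agreement are mean ± 1.96·SD.
    """
    arr = np.asarray(list(pairs), dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (reference, test) tuples")
    if len(arr) < 2:
        raise ValueError("need at least 2 pairs for agreement statistics")
    if np.isnan(arr).any():
        raise ValueError("pairs contain missing values")
    ref, test = arr[:, 0], arr[:, 1]
    d = ref - test
    mean_d = float(d.mean())
    sd = float(d.std(ddof=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(d) / np.where(ref != 0, ref, np.nan)
    return AgreementStats(
        n=len(arr),
        mean_reference_g=float(ref.mean()),
        mean_test_g=float(test.mean()),
        mean_difference_g=mean_d,
        sd_difference_g=sd,
        loa_low_g=mean_d - 1.96 * sd,
        loa_high_g=mean_d + 1.96 * sd,
        mean_absolute_difference_g=float(np.abs(d).mean()),
        max_relative_error_fraction=float(np.nanmax(rel)),
    )


def cohort_summary(records: list[SubjectRecord]
                   ) -> tuple[AgreementStats, pd.DataFrame]:
    """Cohort agreement of MRI weight vs autopsy weight, plus plot data.

    Only records with an autopsy weight contribute.  The plot frame holds
    per-pair (mean, difference) coordinates for a Bland–Altman plot.
    """
    complete = [r for r in records if r.has_autopsy]
    if not complete:
        raise ValueError("no complete (autopsy, MRI) pairs in the cohort")
    pairs = [(r.autopsy_weight_g, r.mri_weight_g) for r in complete]
    stats = bland_altman(pairs)
    plot = pd.DataFrame({
        "subject_id": [r.subject_id for r in complete],
        "mean_g": [(a + m) / 2.0 for a, m in pairs],
        "difference_g": [a - m for a, m in pairs],
    })
    return stats, plot


def compare_prior_sources(seg_a: LabelMap, seg_b: LabelMap,
                          truth: LabelMap,
                          labels: tuple[int, ...] | None = None) -> pd.DataFrame:
    """Per-class Dice of two segmentations against a common truth.

    Typical use: column A from matched-contrast atlas priors, column B
    from a mismatched atlas; on contrast-collapsed phantoms A is expected
    to be at least as good for every class.
    """
    seg_a.require_same_grid(truth, "compare_prior_sources")
    seg_b.require_same_grid(truth, "compare_prior_sources")
    if labels is None:
        labels = tuple(sorted(set(np.unique(truth.data)) - {0}))
    present = set(np.unique(seg_a.data)) | set(np.unique(seg_b.data)) | set(np.unique(truth.data))
    unknown = set(labels) - present
    if unknown == set(labels):
        raise ValueError(f"label schemes do not overlap: {labels} vs {sorted(present)}")
    rows = []
    for lbl in labels:
        rows.append({
            "label": lbl,
            "name": CLASS_NAMES.get(lbl, str(lbl)),
            "dice_a": dice(seg_a, truth, lbl),
            "dice_b": dice(seg_b, truth, lbl),
        })
    return pd.DataFrame(rows)
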