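"""Groupwise average-atlas construction.

The cohort template is built by registering every subject to an evolving
average image through a schedule of increasing degrees of freedom —
by default one rigid, four affine and four non-rigid (cubic B-spline FFD)
rounds — re-averaging the resampled intensities after each round.  The
final per-subject transforms then propagate the individual posterior
segmentations and brain masks into the average space, where they are
voxelwise-averaged into class priors and a majority mask.

The schedule is configurable because how many rounds are needed depends
on how diverse the cohort is; a convergence diagnostic (mean absolute
template change between the last two rounds) is recorded in provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import LabelMap, ProbabilisticAtlas, VolumeImage
from .em import SegmentationResult
from .registration import (RegistrationParams, Transform, register, resample,
                           resample_priors)

log = logging.getLogger(__name__)

#: Default schedule: 1 rigid, 4 affine, 4 non-rigid rounds.
DEFAULT_SCHEDULE = ("rigid",) + ("affine",) * 4 + ("demons",) * 4


def parse_schedule(text: str) -> tuple[str, ...]:
    """Parse compact schedule strings like ``r1a4n4``."""
    kinds = {"r": "rigid", "a": "affine", "n": "demons", "b": "bspline"}
    out: list[str] = []
    i = 0
    while i < len(text):
        k = text[i]
        if k not in kinds:
            raise ValueError(f"bad schedule token {k!r} in {text!r}")
        j = i + 1
        while j < len(text) and text[j].isdigit():
            j += 1
        count = int(text[i + 1:j] or "1")
        out.extend([kinds[k]] * count)
        i = j
    return tuple(out)


@dataclass
class GroupwiseResult:
    atlas: ProbabilisticAtlas
    transforms: list[Transform | None]      # native -> average (pull-back), per subject
    template_change: float                  # mean |Δ| between last two rounds
    failed_subjects: list[int]


def build_groupwise_atlas(images: Sequence[VolumeImage],
                          segmentations: Sequence[SegmentationResult],
                          masks: Sequence[LabelMap],
                          schedule: Sequence[str] = DEFAULT_SCHEDULE,
                          params: RegistrationParams | None = None
                          ) -> GroupwiseResult:
    """Build the cohort-average atlas and propagate segmentations into it.

    A failed registration flags that subject and the run continues, as long
    as at least two subjects survive.
    """
    n = len(images)
    if n < 2:
        raise ValueError("groupwise atlas needs at least 2 subjects")
    if not (len(segmentations) == len(masks) == n):
        raise ValueError("images, segmentations and masks must align")
    if not schedule:
        raise ValueError("schedule must be nonempty")
    params = params or RegistrationParams()

    grid = images[0]
    average = grid.with_data(np.mean([im.data for im in images], axis=0))
    transforms: list[Transform | None] = [None] * n
    failed: set[int] = set()
    prev_template = average.data.copy()

    for round_no, kind in enumerate(schedule):
        resampled = []
        for i, im in enumerate(images):
            if i in failed:
                continue
            try:
                t = register(average, im, kind, params)
            except Exception as e:          # noqa: BLE001 - subject-level robustness
                log.warning("round %d: registration of subject %d failed (%s)",
                            round_no, i, e)
                failed.add(i)
                if n - len(failed) < 2:
                    raise RuntimeError("fewer than 2 subjects survived registration") from e
                continue
            transforms[i] = t
            resampled.append(resample(im, t, average, "linear").data)
        prev_template = average.data
        average = grid.with_data(np.mean(resampled, axis=0))
    template_change = float(np.abs(average.data - prev_template).mean())
    log.info("groupwise: template change over final round = %.4g", template_change)

    # propagate posteriors and masks through the final transforms
    alive = [i for i in range(n) if i not in failed]
    prior_sum: dict[int, np.ndarray] = {}
    mask_votes = np.zeros(grid.shape)
    for i in alive:
        t = transforms[i]
        seg = segmentations[i]
        priors_i = {lbl: seg.posteriors[j] for j, lbl in enumerate(seg.class_labels)}
        moved = resample_priors(priors_i, images[i], t, average)
        for lbl, p in moved.items():
            prior_sum[lbl] = prior_sum.get(lbl, 0) + p
        mvol = VolumeImage((masks[i].data > 0).astype(np.float64),
                           spacing=masks[i].spacing, origin=masks[i].origin)
        mask_votes += resample(mvol, t, average, "linear").data
    priors = {lbl: p / len(alive) for lbl, p in prior_sum.items()}
    mask = LabelMap((mask_votes >= len(alive) / 2.0).astype(np.int16),
                    spacing=grid.spacing, origin=grid.origin)
    atlas = ProbabilisticAtlas(
        average, priors, mask,
        provenance={"schedule": list(schedule), "n_subjects": len(alive),
                    "failed_subjects": sorted(failed),
                    "template_change": template_change}).normalized()
    return GroupwiseResult(atlas, transforms, template_change, sorted(failed))


def propagate_to_average(item, native_grid: VolumeImage, transform: Transform,
                         atlas: ProbabilisticAtlas):
    """Carry a label map or posterior stack from native to average space.

    Label maps are moved with nearest-neighbour interpolation; posterior
    dicts/stacks linearly, renormalized to per-voxel sum <= 1.
    """
    if isinstance(item, LabelMap):
        return resample(item, transform, atlas.template, "nearest")
    if isinstance(item, dict):
        return resample_priors(item, native_grid, transform, atlas.template)
    raise TypeError(f"cannot propagate object of type {type(item).__name__}")
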