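"""Atlas-prior EM segmentation with prior relaxation and an MRF.

Stage 1 classifies brain voxels into four classes — cerebrum, cerebellum,
brainstem, CSF — with a Gaussian intensity model per class:

* **E-step** responsibilities combine the Gaussian likelihood, the
  per-voxel effective prior and a mean-field Potts term over the
  6-connected neighbourhood, ``exp(beta * sum_neighbours q_k)``.
* **M-step** re-estimates class means and variances from responsibilities.
* **Prior relaxation** blends the atlas prior with a spatially smoothed
  copy of the current posterior, ``(1-alpha)*prior + alpha*smooth(q)``, so
  the segmentation can drift away from an imperfect atlas.

With ``mrf_beta = 0`` and ``relaxation_alpha = 0`` this reduces exactly to
textbook EM for a Gaussian mixture with per-voxel mixing proportions, and
its log-likelihood is non-decreasing.

Stage 2 merges cerebrum and CSF: post-mortem relaxation-time convergence
makes these two classes inseparable by intensity, but keeping CSF as a
separate class in stage 1 stabilizes the cerebellum/brainstem boundaries,
which are surrounded by fluid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import BRAINSTEM, CEREBELLUM, CEREBRUM, CSF, LabelMap, VolumeImage

log = logging.getLogger(__name__)

DEFAULT_CLASS_ORDER = (CEREBRUM, CEREBELLUM, BRAINSTEM, CSF)
#: Stage-2 grouping: cerebrum+CSF merged; cerebellum, brainstem kept.
DEFAULT_MERGE_GROUPS = ((CEREBRUM, CSF), (CEREBELLUM,), (BRAINSTEM,))

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class EMParams:
    max_iterations: int = 100
    convergence_tolerance: float = 1e-5   # relative objective change
    mrf_beta: float = 0.5                 # Potts coupling, >= 0
    relaxation_alpha: float = 0.2         # prior-relaxation weight in [0, 1]
    relaxation_sigma: float = 2.0         # smoothing of relaxed priors, voxels

    def __post_init__(self) -> None:
        if self.mrf_beta < 0:
            raise ValueError("mrf_beta must be >= 0")
        if not 0.0 <= self.relaxation_alpha <= 1.0:
            raise ValueError("relaxation_alpha must be in [0, 1]")


@dataclass
class SegmentationResult:
    posteriors: np.ndarray                # (K, nz, ny, nx)
    hard_labels: LabelMap
    class_labels: tuple[int, ...]
    means: np.ndarray                     # (K,)
    variances: np.ndarray                 # (K,)
    mixing: np.ndarray                    # effective priors after relaxation
    n_iterations: int = 0
    converged: bool = False
    objective_trace: list[float] = field(default_factory=list)


def _neighbour_sum(q: np.ndarray) -> np.ndarray:
    """Sum of each voxel's 6-connected neighbours, per class (zero-padded)."""
    out = np.zeros_like(q)
    for axis in range(1, 4):
        for shift in (1, -1):
            rolled = np.roll(q, shift, axis=axis)
            # zero out the wrap-around face before accumulating
            face = [slice(None)] * 4
            face[axis] = 0 if shift == 1 else -1
            rolled[tuple(face)] = 0.0
            out += rolled
    return out


def _hard_labels(posteriors: np.ndarray, class_labels: Sequence[int],
                 mask: np.ndarray, grid: VolumeImage) -> LabelMap:
    labels = np.zeros(mask.shape, dtype=np.int16)
    arg = np.argmax(posteriors, axis=0)   # ties -> lowest class index
    labels[mask] = np.asarray(class_labels, dtype=np.int16)[arg[mask]]
    return LabelMap(labels, spacing=grid.spacing, origin=grid.origin)


def em_segment(image: VolumeImage, priors: dict[int, np.ndarray],
               mask: LabelMap, params: EMParams | None = None) -> SegmentationResult:
    """Run the EM-MRF segmentation on one masked image.

    ``priors`` maps class label to an atlas prior probability volume on the
    image grid; the per-voxel prior sum must be positive inside the mask.
    Initialization is deterministic: class parameters start from
    prior-weighted intensity moments.
    """
    params = params or EMParams()
    image.require_same_grid(mask, "em_segment mask")
    class_labels = tuple(k for k in DEFAULT_CLASS_ORDER if k in priors)
    class_labels += tuple(k for k in sorted(priors) if k not in class_labels)
    if len(class_labels) < 2:
        raise ValueError("need at least 2 classes")
    y = np.asarray(image.data, dtype=np.float64)
    if not np.isfinite(y).all():
        raise ValueError("image contains non-finite intensities")
    m = mask.data > 0
    if not m.any():
        raise ValueError("mask is empty")

    atlas_prior = np.stack([np.asarray(priors[k], dtype=np.float64) for k in class_labels])
    total = atlas_prior.sum(axis=0)
    if (total[m] <= 0).any():
        raise ValueError("prior sum must be positive everywhere inside the mask")
    atlas_prior[:, m] /= total[m]
    atlas_prior[:, ~m] = 0.0
    eff_prior = atlas_prior.copy()

    K = len(class_labels)
    # deterministic init from prior-weighted moments
    w = atlas_prior[:, m]
    ym = y[m]
    wsum = w.sum(axis=1)
    means = (w @ ym) / np.maximum(wsum, 1e-12)
    variances = (w @ ym ** 2) / np.maximum(wsum, 1e-12) - means ** 2
    var_floor = max(1e-12, 1e-6 * float(ym.var()))
    variances = np.maximum(variances, var_floor)
    # flat (uninformative) priors collapse the moment init onto one point —
    # a symmetric fixed point of EM; break it with deterministic quantiles
    spread = float(ym.std())
    if spread > 0 and np.ptp(means) < 1e-3 * spread:
        qs = (np.arange(K) + 0.5) / K
        means = np.quantile(ym, qs)
        variances = np.maximum(np.full(K, ym.var() / K ** 2), var_floor)

    q = eff_prior.copy()                  # mean-field posterior estimate
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, params.max_iterations + 1):
        # E-step
        log_lik = np.empty((K,) + y.shape)
        for k in range(K):
            log_lik[k] = -0.5 * (_LOG_2PI + np.log(variances[k])
                                 + (y - means[k]) ** 2 / variances[k])
        log_num = np.log(np.maximum(eff_prior, 1e-300)) + log_lik
        if params.mrf_beta > 0:
            log_num = log_num + params.mrf_beta * _neighbour_sum(q)
        log_num[:, ~m] = -np.inf
        mx = log_num.max(axis=0)
        with np.errstate(invalid="ignore"):
            num = np.exp(log_num - mx)
        den = num.sum(axis=0)
        q = np.zeros_like(num)
        q[:, m] = num[:, m] / den[m]
        objective = float((mx[m] + np.log(den[m])).sum())
        trace.append(objective)

        # M-step
        r = q[:, m]
        rsum = r.sum(axis=1)
        small = rsum < 1e-8
        if small.any():
            log.warning("classes with vanishing responsibility: %s",
                        [class_labels[i] for i in np.where(small)[0]])
        rsum = np.maximum(rsum, 1e-12)
        means = (r @ ym) / rsum
        variances = np.maximum((r @ (ym ** 2)) / rsum - means ** 2, var_floor)

        # prior relaxation
        if params.relaxation_alpha > 0:
            smoothed = np.stack([
                ndimage.gaussian_filter(q[k], params.relaxation_sigma) for k in range(K)])
            eff_prior = ((1.0 - params.relaxation_alpha) * atlas_prior
                         + params.relaxation_alpha * smoothed)
            s = eff_prior.sum(axis=0)
            eff_prior[:, m] /= np.maximum(s[m], 1e-12)
            eff_prior[:, ~m] = 0.0

        if len(trace) >= 2:
            rel = abs(trace[-1] - trace[-2]) / max(abs(trace[-2]), 1e-12)
            if rel < params.convergence_tolerance:
                converged = True
                break

    result = SegmentationResult(
        posteriors=q, hard_labels=_hard_labels(q, class_labels, m, image),
        class_labels=class_labels, means=means, variances=variances,
        mixing=eff_prior, n_iterations=it, converged=converged,
        objective_trace=trace)
    log.info("em_segment: %d iterations, converged=%s, objective=%.6g",
             it, converged, trace[-1])
    return result


def merge_classes(result: SegmentationResult,
                  groups: Sequence[Sequence[int]] = DEFAULT_MERGE_GROUPS
                  ) -> tuple[LabelMap, np.ndarray]:
    """Stage 2: sum posteriors within groups and re-argmax.

    ``groups`` must partition the class set; each merged region takes the
    label of its first member (so cerebrum+CSF keeps the cerebrum label).
    Returns the merged label map and the (G, ...) merged posterior stack.
    """
    flat = [lbl for g in groups for lbl in g]
    if sorted(flat) != sorted(result.class_labels) or len(set(flat)) != len(flat):
        raise ValueError(f"groups {groups!r} do not partition classes {result.class_labels}")
    idx = {lbl: i for i, lbl in enumerate(result.class_labels)}
    merged = np.stack([
        sum(result.posteriors[idx[lbl]] for lbl in g) for g in groups])
    rep_labels = tuple(g[0] for g in groups)
    mask = result.hard_labels.data > 0
    labels = _hard_labels(merged, rep_labels, mask, result.hard_labels)
    return labels, merged
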