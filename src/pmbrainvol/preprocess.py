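"""Bias-field correction and brain-mask handling.

MR intensity non-uniformity is modelled as a smooth multiplicative gain
field.  The estimator fits a low-order 3-D tensor-polynomial to the
within-mask log-intensities by least squares, alternating with a crude
tissue-class demeaning step (k-means on corrected intensities) so that
genuine anatomy is not absorbed into the field.  The field is normalized
to unit mean inside the mask, so correction preserves mean brightness —
required for CSF thresholds to stay comparable across subjects.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .core import LabelMap, ProbabilisticAtlas, VolumeImage
from .registration import Transform, resample

log = logging.getLogger(__name__)


@dataclass
class BiasField:
    """Multiplicative gain field (dimensionless, strictly positive)."""

    field: VolumeImage
    model_order: int

    def __post_init__(self) -> None:
        if (self.field.data <= 0).any():
            raise ValueError("bias field must be strictly positive")


def _poly_basis(shape: tuple[int, int, int], order: int) -> np.ndarray:
    """Tensor polynomial basis on [-1, 1]^3, columns = monomials of total
    degree <= order, evaluated on the full grid; shape (nvox, nbasis)."""
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    cols = []
    for i, j, k in itertools.product(range(order + 1), repeat=3):
        if i + j + k <= order:
            cols.append((zz ** i * yy ** j * xx ** k).ravel())
    return np.stack(cols, axis=1)


def estimate_bias_field(image: VolumeImage, mask: LabelMap, order: int = 5,
                        n_classes: int = 4, n_outer: int = 8) -> BiasField:
    """Estimate a smooth multiplicative bias field inside ``mask``.

    Alternates (a) k-means tissue clustering of the corrected intensities
    and (b) a least-squares polynomial fit to the class-demeaned
    log-intensities.  Returns a field with mean 1 inside the mask.
    """
    image.require_same_grid(mask, "estimate_bias_field")
    m = (mask.data > 0).ravel()
    if not m.any():
        raise ValueError("estimate_bias_field: mask is empty")
    y = np.asarray(image.data, dtype=np.float64).ravel()
    if (y[m] <= 0).any():
        raise ValueError("estimate_bias_field: non-positive intensities inside mask "
                         "(log-domain fit undefined)")
    logy = np.log(y[m])
    basis = _poly_basis(image.shape, order)
    A = basis[m]
    coef = np.zeros(A.shape[1])
    for _ in range(n_outer):
        resid_field = A @ coef
        corrected = logy - resid_field
        km = KMeans(n_clusters=min(n_classes, len(np.unique(np.round(corrected, 6)))),
                    n_init=3, random_state=0).fit(corrected[:, None])
        class_mean = km.cluster_centers_[km.labels_, 0]
        target = logy - class_mean          # log-residual attributed to bias
        coef, *_ = np.linalg.lstsq(A, target, rcond=None)
    logfield = (basis @ coef).reshape(image.shape)
    field = np.exp(logfield)
    field /= field[mask.data > 0].mean()    # unit mean inside the mask
    log.info("bias field estimated: order=%d, range [%.4f, %.4f] in mask",
             order, field[mask.data > 0].min(), field[mask.data > 0].max())
    return BiasField(VolumeImage(field, spacing=image.spacing, origin=image.origin),
                     model_order=order)


def correct_bias(image: VolumeImage, field: BiasField) -> VolumeImage:
    """Divide out the multiplicative field; metadata preserved."""
    image.require_same_grid(field.field, "correct_bias")
    return image.with_data(image.data / field.field.data)


def propagate_mask(atlas: ProbabilisticAtlas, transform: Transform,
                   target_grid: VolumeImage) -> LabelMap:
    """Resample the atlas brain mask onto a subject grid.

    ``transform`` must map target space to atlas space (pull-back);
    nearest-neighbour interpolation keeps the mask binary.
    """
    return resample(atlas.mask, transform, target_grid, "nearest")


def refine_mask(image: VolumeImage, mask: LabelMap,
                fraction_of_median: float = 0.3) -> LabelMap:
    """Drop non-brain voxels from a propagated mask by intensity.

    Registration leaves a thin ring of dark non-brain voxels inside the
    atlas-propagated intracranial mask; they would survive the CSF
    threshold and inflate the cerebrum volume.  This removes in-mask
    voxels darker than ``fraction_of_median`` times the median in-mask
    intensity — an automated counterpart of manually excluding non-brain
    tissue from the mask.
    """
    image.require_same_grid(mask, "refine_mask")
    m = mask.data > 0
    if not m.any():
        raise ValueError("refine_mask: mask is empty")
    cutoff = fraction_of_median * float(np.median(image.data[m]))
    kept = m & (image.data >= cutoff)
    log.info("refine_mask: removed %d of %d voxels below %.1f",
             int(m.sum() - kept.sum()), int(m.sum()), cutoff)
    return LabelMap(kept.astype(np.int16), spacing=mask.spacing, origin=mask.origin)


def apply_mask_edits(mask: LabelMap, edits: LabelMap) -> LabelMap:
    """Ingest an externally edited mask (stands in for manual correction).

    The edited mask replaces the original; the voxel diff is logged so the
    volumetry audit trail records what manual editing changed.
    """
    mask.require_same_grid(edits, "apply_mask_edits")
    before = mask.data > 0
    after = edits.data > 0
    added = int(np.count_nonzero(after & ~before))
    removed = int(np.count_nonzero(before & ~after))
    if not after.any():
        log.warning("apply_mask_edits: edited mask is empty")
    log.info("mask edits: %d voxels added, %d removed", added, removed)
    return LabelMap(after.astype(np.int16), spacing=mask.spacing, origin=mask.origin)
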