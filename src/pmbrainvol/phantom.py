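"""Synthetic 3-D brain phantoms with known ground truth.

The phantom emulates heavily T2-weighted post-mortem scans of the
fetal/newborn brain: ~0.6 mm isotropic voxels, bright fluid, and —
crucially — low cerebrum/CSF contrast, because after death the tissue
relaxation times converge toward free-water values.  Geometry is a family
of nested ellipsoids (head fluid shell, cerebrum with ventricular pockets,
cerebellum, brainstem) so that every region has an analytic volume to
check voxel counts against.  On top of the piecewise-constant class image
the generator applies a smooth multiplicative bias field and additive
Gaussian noise; cohorts are produced by smooth random warps of the base
anatomy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import (BACKGROUND, BRAINSTEM, CEREBELLUM, CEREBRUM, CLASS_LABELS,
                   CSF, LabelMap, ProbabilisticAtlas, VolumeImage)

log = logging.getLogger(__name__)


class PhantomGeometryError(ValueError):
    """A phantom region is degenerate (empty or clipped by the grid)."""


@dataclass(frozen=True)
class Ellipsoid:
    """One painted region: axis-aligned ellipsoid in grid fractions.

    ``center`` and ``semiaxes`` are fractions of the grid size per axis
    (z, y, x); ``center`` is relative to the grid centre.  Regions are
    painted in list order, so later (smaller) structures override earlier
    ones: fluid shell first, then cerebrum, ventricular pockets, cerebellum
    and brainstem last.
    """

    name: str
    label: int
    center: tuple[float, float, float]
    semiaxes: tuple[float, float, float]

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        grids = np.ogrid[tuple(slice(0, n) for n in shape)]
        q = np.zeros(shape)
        for g, n, c, a in zip(grids, shape, self.center, self.semiaxes):
            if a <= 0:
                raise PhantomGeometryError(f"region '{self.name}': non-positive semiaxis")
            q = q + ((g - (n - 1) / 2.0 - c * n) / (a * n)) ** 2
        return q <= 1.0

    def analytic_volume_mm3(self, shape, spacing) -> float:
        semi_mm = [a * n * s for a, n, s in zip(self.semiaxes, shape, spacing)]
        return 4.0 / 3.0 * np.pi * float(np.prod(semi_mm))


def default_geometry() -> tuple[Ellipsoid, ...]:
    """Nested-ellipsoid anatomy: fluid shell, cerebrum with two ventricular
    pockets, cerebellum posterior-inferior, brainstem inferior."""
    return (
        Ellipsoid("head", CSF, (0.0, 0.0, 0.0), (0.42, 0.42, 0.40)),
        Ellipsoid("cerebrum", CEREBRUM, (0.03, -0.02, 0.0), (0.33, 0.34, 0.32)),
        Ellipsoid("ventricle_left", CSF, (0.06, -0.04, -0.10), (0.07, 0.10, 0.045)),
        Ellipsoid("ventricle_right", CSF, (0.06, -0.04, 0.10), (0.07, 0.10, 0.045)),
        Ellipsoid("cerebellum", CEREBELLUM, (-0.24, 0.16, 0.0), (0.09, 0.13, 0.14)),
        Ellipsoid("brainstem", BRAINSTEM, (-0.27, -0.02, 0.0), (0.11, 0.05, 0.05)),
    )


@dataclass
class PhantomSpec:
    """Parameters of one phantom realization.

    ``class_mean_intensities`` defaults to a post-mortem-like contrast:
    fluid bright (900), cerebrum 600, cerebellum 450, brainstem 400 —
    dimensionless CISS-like signal.  Setting the cerebrum mean equal to the
    CSF mean reproduces the post-mortem contrast collapse that motivates
    the merged cerebrum+CSF class.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 0.6
    region_geometry: Sequence[Ellipsoid] = field(default_factory=default_geometry)
    class_mean_intensities: dict[int, float] = field(default_factory=lambda: {
        BACKGROUND: 40.0, CEREBRUM: 600.0, CEREBELLUM: 450.0,
        BRAINSTEM: 400.0, CSF: 900.0})
    class_noise_sd: float = 25.0
    bias_amplitude: float = 1.2
    deform_sd: float = 1.0          # RMS displacement in voxels for cohorts
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.class_noise_sd < 0:
            raise ValueError("class_noise_sd must be >= 0")
        if self.bias_amplitude < 1:
            raise ValueError("bias_amplitude must be >= 1 (peak-to-trough ratio)")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (self.voxel_size_mm,) * 3


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    label_map: LabelMap
    true_volumes_mL: dict[int, float]
    true_bias_field: VolumeImage
    clean_image: VolumeImage

    @property
    def head_mask(self) -> np.ndarray:
        return self.label_map.data > 0


def _volumes_from_labels(labels: np.ndarray, voxel_volume_mm3: float) -> dict[int, float]:
    return {int(lbl): float(np.count_nonzero(labels == lbl) * voxel_volume_mm3 / 1000.0)
            for lbl in CLASS_LABELS}


def _paint_labels(spec: PhantomSpec) -> np.ndarray:
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    for region in spec.region_geometry:
        m = region.mask(spec.grid_shape)
        if not m.any():
            raise PhantomGeometryError(f"region '{region.name}' is empty on this grid")
        edge = np.zeros(spec.grid_shape, bool)
        edge[[0, -1], :, :] = edge[:, [0, -1], :] = edge[:, :, [0, -1]] = True
        if (m & edge).any():
            raise PhantomGeometryError(f"region '{region.name}' is clipped by the grid")
        labels[m] = region.label
    return labels


def _smooth_random_field(shape, rng, coarse: int = 4) -> np.ndarray:
    """Zero-mean smooth field from a coarse Gaussian lattice upsampled with
    cubic interpolation; only low frequencies survive."""
    coarse_field = rng.standard_normal((coarse,) * 3)
    zoom = [n / coarse for n in shape]
    f = ndimage.zoom(coarse_field, zoom, order=3, mode="nearest", grid_mode=True)
    return f - f.mean()


def _make_bias_field(spec: PhantomSpec, rng, head: np.ndarray) -> np.ndarray:
    if spec.bias_amplitude == 1.0:
        return np.ones(spec.grid_shape)
    g = _smooth_random_field(spec.grid_shape, rng)
    span = g.max() - g.min()
    g = g * (np.log(spec.bias_amplitude) / span)
    g -= g[head].mean()            # geometric mean 1 inside the head
    return np.exp(g)


def generate_phantom(spec: PhantomSpec,
                     rng: np.random.Generator | None = None
                     ) -> tuple[VolumeImage, PhantomTruth]:
    """Generate one noisy, biased phantom plus its ground truth.

    The same spec (including seed) always yields bit-identical output.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    labels = _paint_labels(spec)
    clean = np.zeros(spec.grid_shape, dtype=np.float64)
    for lbl, mean in spec.class_mean_intensities.items():
        clean[labels == lbl] = mean
    head = labels > 0
    bias = _make_bias_field(spec, rng, head)
    noisy = clean * bias
    if spec.class_noise_sd > 0:
        noisy = noisy + rng.normal(0.0, spec.class_noise_sd, spec.grid_shape)
    image = VolumeImage(noisy, spacing=spec.spacing)
    truth = PhantomTruth(
        label_map=LabelMap(labels, spacing=spec.spacing),
        true_volumes_mL=_volumes_from_labels(labels, image.voxel_volume_mm3),
        true_bias_field=VolumeImage(bias, spacing=spec.spacing),
        clean_image=VolumeImage(clean, spacing=spec.spacing),
    )
    return image, truth


# -- cohort generation ----------------------------------------------------

def _random_displacement(shape, sd_voxels, rng, coarse: int = 5) -> np.ndarray:
    disp = np.stack([_smooth_random_field(shape, rng, coarse) for _ in range(3)])
    rms = np.sqrt((disp ** 2).sum(axis=0).mean())
    if rms > 0:
        disp *= sd_voxels / rms
    return disp


def _jacobian_positive(disp: np.ndarray) -> bool:
    grads = [[np.gradient(disp[i], axis=j) for j in range(3)] for i in range(3)]
    jac = np.zeros(disp.shape[1:] + (3, 3))
    for i in range(3):
        for j in range(3):
            jac[..., i, j] = (1.0 if i == j else 0.0) + grads[i][j]
    return bool(np.linalg.det(jac).min() > 0)


def _warp(volume: np.ndarray, disp: np.ndarray, order: int) -> np.ndarray:
    idx = np.indices(volume.shape, dtype=np.float64)
    coords = idx + disp           # pull-back sampling
    return ndimage.map_coordinates(volume, coords, order=order, mode="nearest")


def generate_cohort(spec: PhantomSpec, n: int
                    ) -> list[tuple[VolumeImage, PhantomTruth]]:
    """Generate ``n`` phantoms as smooth random warps of the base anatomy.

    Each subject gets an independent deformation of RMS magnitude
    ``spec.deform_sd`` voxels (rejection-sampled to keep a positive
    Jacobian), its own bias field and its own noise realization.  Truths
    carry the warped labels and recomputed volumes.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    base_labels = _paint_labels(spec)
    base_clean = np.zeros(spec.grid_shape, dtype=np.float64)
    for lbl, mean in spec.class_mean_intensities.items():
        base_clean[base_labels == lbl] = mean
    streams = np.random.SeedSequence(spec.seed).spawn(n)
    cohort = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        labels, clean = base_labels, base_clean
        if spec.deform_sd > 0:
            sd = spec.deform_sd
            for _ in range(20):
                disp = _random_displacement(spec.grid_shape, sd, rng)
                if _jacobian_positive(disp):
                    break
                sd *= 0.8
                log.warning("subject %d: deformation folded, retrying at sd=%.3f", i, sd)
            labels = np.round(_warp(base_labels.astype(np.float64), disp, order=0)).astype(np.int16)
            # keep the image piecewise-constant: the warp moves geometry,
            # the intensity model stays "class mean + noise"
            clean = np.zeros(spec.grid_shape, dtype=np.float64)
            for lbl, mean in spec.class_mean_intensities.items():
                clean[labels == lbl] = mean
        head = labels > 0
        bias = _make_bias_field(spec, rng, head) if head.any() else np.ones(spec.grid_shape)
        noisy = clean * bias
        if spec.class_noise_sd > 0:
            noisy = noisy + rng.normal(0.0, spec.class_noise_sd, spec.grid_shape)
        image = VolumeImage(noisy, spacing=spec.spacing)
        truth = PhantomTruth(
            label_map=LabelMap(labels, spacing=spec.spacing),
            true_volumes_mL=_volumes_from_labels(labels, image.voxel_volume_mm3),
            true_bias_field=VolumeImage(bias, spacing=spec.spacing),
            clean_image=VolumeImage(clean, spacing=spec.spacing),
        )
        cohort.append((image, truth))
    return cohort


# -- truth-derived atlas ---------------------------------------------------

def atlas_from_truth(truths: Sequence[PhantomTruth], smoothing_mm: float = 1.2
                     ) -> ProbabilisticAtlas:
    """Build a probabilistic atlas directly from ground-truth labels.

    Per-class priors are the (optionally Gaussian-smoothed) average of the
    one-hot truth volumes, renormalized to sum to 1 inside the majority
    head mask.  Plays the role of an external prior atlas in tests.
    """
    if not truths:
        raise ValueError("need at least one truth")
    ref = truths[0].label_map
    for t in truths[1:]:
        ref.require_same_grid(t.label_map, "atlas_from_truth")
    n = len(truths)
    priors = {}
    empty = []
    for lbl in CLASS_LABELS:
        avg = np.zeros(ref.shape, dtype=np.float64)
        for t in truths:
            avg += (t.label_map.data == lbl)
        avg /= n
        if avg.max() == 0:
            empty.append(lbl)
        elif smoothing_mm > 0:
            sigma = [smoothing_mm / s for s in ref.spacing]
            avg = ndimage.gaussian_filter(avg, sigma)
        priors[lbl] = avg
    head_votes = np.zeros(ref.shape)
    for t in truths:
        head_votes += (t.label_map.data > 0)
    mask = LabelMap((head_votes >= n / 2.0).astype(np.int16),
                    spacing=ref.spacing, origin=ref.origin)
    template = VolumeImage(np.mean([t.clean_image.data for t in truths], axis=0),
                           spacing=ref.spacing, origin=ref.origin)
    if empty:
        log.warning("empty classes across all truths: %s", empty)
    atlas = ProbabilisticAtlas(template, priors, mask,
                               provenance={"source": "truth", "n_subjects": n,
                                           "smoothing_mm": smoothing_mm,
                                           "empty_classes": empty})
    return atlas.normalized()
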