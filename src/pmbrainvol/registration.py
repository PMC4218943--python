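"""Rigid, affine and non-rigid registration plus resampling.

Backed by SimpleITK's registration framework.  Conventions:

* Transforms map **fixed (target) physical space to moving (source)
  physical space** — the pull-back convention used for resampling.
* Similarity defaults to normalized cross-correlation (the phantom work is
  single-modality); Mattes mutual information is available via params.
* A 3-level multiresolution pyramid with full or regular-grid metric
  sampling keeps runs deterministic for identical inputs.
* Two non-rigid models: cubic B-spline free-form deformation (default
  control spacing 8 voxels, coarse-to-fine lattice) and — the default
  engine for schedules — a Gaussian-regularized dense displacement field
  from symmetric-forces Demons.  Folding is detectable from the
  displacement-field Jacobian determinant.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .core import LabelMap, VolumeImage

log = logging.getLogger(__name__)

KINDS = ("rigid", "affine", "bspline", "demons", "composite")


@dataclass
class RegistrationParams:
    """Knobs of the registration engine (defaults are desk-scale)."""

    metric: str = "correlation"            # correlation | mutual_information | mean_squares
    pyramid_shrink: tuple[int, ...] = (4, 2, 1)
    pyramid_smooth_sigmas: tuple[float, ...] = (2.0, 1.0, 0.0)
    iterations: int = 100
    bspline_spacing_voxels: float = 8.0
    sampling_fraction: float = 1.0         # <1 uses regular subsampling of the metric
    learning_rate: float = 1.0
    demons_iterations: int = 60
    demons_smoothing_sigma: float = 1.0    # Gaussian regularization of the field (voxels)


@dataclass
class Transform:
    """A spatial mapping from target space to source space."""

    kind: str
    sitk_transform: sitk.Transform
    converged: bool = True
    info: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown transform kind {self.kind!r}")

    def apply_point(self, point_zyx: tuple[float, float, float]) -> tuple[float, float, float]:
        """Map one physical point (z, y, x ordering, mm)."""
        out = self.sitk_transform.TransformPoint(tuple(point_zyx[::-1]))
        return tuple(out[::-1])

    def inverse(self) -> "Transform":
        inv = self.sitk_transform.GetInverse()
        return Transform(self.kind if self.kind != "bspline" else "composite", inv)

    # -- JSON serialization ----------------------------------------------
    def to_json(self, path: str | Path | None = None) -> dict:
        t = self.sitk_transform
        payload = {
            "kind": self.kind,
            "class": t.GetName(),
            "fixed_parameters": list(t.GetFixedParameters()),
            "parameters": list(t.GetParameters()),
            "converged": self.converged,
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload))
        return payload

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "Transform":
        if not isinstance(source, dict):
            source = json.loads(Path(source).read_text())
        ctor = {
            "Euler3DTransform": sitk.Euler3DTransform,
            "AffineTransform": lambda: sitk.AffineTransform(3),
            "BSplineTransform": lambda: sitk.BSplineTransform(3, 3),
            "TranslationTransform": lambda: sitk.TranslationTransform(3),
            "DisplacementFieldTransform": lambda: sitk.DisplacementFieldTransform(3),
        }[source["class"]]
        t = ctor()
        t.SetFixedParameters(tuple(source["fixed_parameters"]))
        t.SetParameters(tuple(source["parameters"]))
        return cls(source["kind"], t, converged=source.get("converged", True))


def identity_transform() -> Transform:
    return Transform("rigid", sitk.Euler3DTransform())


def _metric(reg: sitk.ImageRegistrationMethod, name: str) -> None:
    if name == "correlation":
        reg.SetMetricAsCorrelation()
    elif name == "mutual_information":
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    elif name == "mean_squares":
        reg.SetMetricAsMeanSquares()
    else:
        raise ValueError(f"unknown metric {name!r}")


def register(fixed: VolumeImage, moving: VolumeImage, kind: str,
             params: RegistrationParams | None = None,
             initial: Transform | None = None) -> Transform:
    """Estimate the transform aligning ``moving`` onto ``fixed``.

    Returns the transform that maps fixed-space points into moving space,
    ready for pull-back resampling.  Non-convergence within the iteration
    budget returns the best-so-far transform with ``converged=False``.
    """
    params = params or RegistrationParams()
    if kind not in ("rigid", "affine", "bspline", "demons"):
        raise ValueError(f"cannot estimate transform of kind {kind!r}")
    f_img, m_img = fixed.to_sitk(), moving.to_sitk()

    if kind == "demons":
        return _register_demons(f_img, m_img, params, initial)

    reg = sitk.ImageRegistrationMethod()
    _metric(reg, params.metric)
    if params.sampling_fraction >= 1.0:
        reg.SetMetricSamplingStrategy(reg.NONE)     # full sampling
    else:
        reg.SetMetricSamplingStrategy(reg.REGULAR)  # regular grid: deterministic
        reg.SetMetricSamplingPercentage(params.sampling_fraction, 12345)
    reg.SetInterpolator(sitk.sitkLinear)
    levels = len(params.pyramid_shrink)
    reg.SetShrinkFactorsPerLevel(list(params.pyramid_shrink))
    reg.SetSmoothingSigmasPerLevel(list(params.pyramid_smooth_sigmas[:levels]))
    reg.SetSmoothingSigmasAreSpecifiedInPhysicalUnits(False)

    if kind == "bspline":
        spacing_mm = [params.bspline_spacing_voxels * s for s in fixed.spacing[::-1]]
        mesh_final = [max(1, int(round(sz * sp / gs))) for sz, sp, gs in
                      zip(f_img.GetSize(), f_img.GetSpacing(), spacing_mm)]
        # coarse-to-fine control lattice: scaleFactors multiply the initial
        # (coarse) mesh per pyramid level, so start at mesh_final / 2^(L-1)
        scale_factors = [2 ** i for i in range(levels)]
        mesh0 = [max(1, int(np.ceil(mf / scale_factors[-1]))) for mf in mesh_final]
        tx = sitk.BSplineTransformInitializer(f_img, mesh0, order=3)
        if initial is not None:
            reg.SetMovingInitialTransform(initial.sitk_transform)
        reg.SetInitialTransformAsBSpline(tx, inPlace=True,
                                         scaleFactors=scale_factors)
        reg.SetOptimizerAsGradientDescentLineSearch(
            learningRate=params.learning_rate, numberOfIterations=params.iterations,
            convergenceMinimumValue=1e-6, convergenceWindowSize=5)
        reg.SetOptimizerScalesFromPhysicalShift()
    else:
        if kind == "rigid":
            tx = sitk.CenteredTransformInitializer(
                f_img, m_img, sitk.Euler3DTransform(),
                sitk.CenteredTransformInitializerFilter.GEOMETRY)
        else:
            tx = sitk.CenteredTransformInitializer(
                f_img, m_img, sitk.AffineTransform(3),
                sitk.CenteredTransformInitializerFilter.GEOMETRY)
        if initial is not None:
            reg.SetMovingInitialTransform(initial.sitk_transform)
        reg.SetInitialTransform(tx, inPlace=True)
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=params.learning_rate, minStep=1e-4,
            numberOfIterations=params.iterations, relaxationFactor=0.6)
        reg.SetOptimizerScalesFromPhysicalShift()

    trace: list[float] = []
    reg.AddCommand(sitk.sitkIterationEvent,
                   lambda: trace.append(reg.GetMetricValue()))
    final = reg.Execute(f_img, m_img)
    if initial is not None:
        composite = sitk.CompositeTransform(3)
        composite.AddTransform(initial.sitk_transform)   # applied second
        composite.AddTransform(final)                    # applied first
        final = composite
        kind_out = "composite"
    else:
        kind_out = kind
    stop = reg.GetOptimizerStopConditionDescription()
    converged = "maximum number of iterations" not in stop.lower()
    if not converged:
        log.warning("registration hit iteration budget: %s", stop)
    log.debug("register(%s): %d metric evaluations, final=%.6g", kind,
              len(trace), reg.GetMetricValue())
    return Transform(kind_out, final, converged=converged,
                     info={"metric_trace": trace, "stop": stop})


def _register_demons(f_img: sitk.Image, m_img: sitk.Image,
                     params: RegistrationParams,
                     initial: Transform | None) -> Transform:
    """Non-rigid registration as a Gaussian-regularized dense displacement
    field (symmetric-forces Demons).  Fast and accurate for the smooth,
    same-modality warps this pipeline needs; the field maps fixed space to
    moving space like every other transform here."""
    moving = m_img
    if initial is not None:
        moving = sitk.Resample(m_img, f_img, initial.sitk_transform, sitk.sitkLinear, 0.0)
    d = sitk.FastSymmetricForcesDemonsRegistrationFilter()
    d.SetNumberOfIterations(params.demons_iterations)
    d.SetStandardDeviations(params.demons_smoothing_sigma)
    field = d.Execute(f_img, moving)
    tx = Transform("demons", sitk.DisplacementFieldTransform(field),
                   info={"rms_change": d.GetRMSChange(),
                         "metric": d.GetMetric()})
    if initial is not None:
        return compose(initial, tx)
    return tx


def min_displacement_jacobian(transform: Transform) -> float:
    """Minimum Jacobian determinant of a dense displacement field; values
    <= 0 indicate folding."""
    t = transform.sitk_transform
    if not isinstance(t, sitk.DisplacementFieldTransform):
        raise TypeError("expected a displacement-field transform")
    jac = sitk.DisplacementFieldJacobianDeterminant(t.GetDisplacementField())
    return float(sitk.GetArrayFromImage(jac).min())


def resample(source: VolumeImage | LabelMap, transform: Transform,
             target_grid: VolumeImage, interpolation: str = "linear",
             default_value: float = 0.0):
    """Resample ``source`` onto ``target_grid`` through ``transform``.

    Label maps must use nearest-neighbour interpolation.
    """
    is_labels = isinstance(source, LabelMap)
    if is_labels and interpolation != "nearest":
        raise ValueError("label maps must be resampled with nearest-neighbour interpolation")
    interp = {"linear": sitk.sitkLinear, "nearest": sitk.sitkNearestNeighbor,
              "bspline": sitk.sitkBSpline}[interpolation]
    out = sitk.Resample(source.to_sitk(), target_grid.to_sitk(),
                        transform.sitk_transform, interp, float(default_value))
    if is_labels:
        return LabelMap.from_sitk(out)
    return VolumeImage.from_sitk(out)


def resample_priors(priors: dict[int, np.ndarray], grid: VolumeImage,
                    transform: Transform, target_grid: VolumeImage) -> dict[int, np.ndarray]:
    """Resample prior probability volumes (linear) and cap the per-voxel
    sum at 1 where interpolation pushed it above."""
    out = {}
    for lbl, p in priors.items():
        r = resample(grid.with_data(p), transform, target_grid, "linear")
        out[lbl] = np.clip(r.data, 0.0, 1.0)
    total = np.sum(list(out.values()), axis=0)
    over = total > 1.0
    if over.any():
        for lbl in out:
            out[lbl][over] /= total[over]
    return out


def compose(outer: Transform, inner: Transform) -> Transform:
    """Composite acting as ``outer(inner(x))``."""
    c = sitk.CompositeTransform(3)
    c.AddTransform(outer.sitk_transform)   # applied last… (sitk applies in reverse order)
    c.AddTransform(inner.sitk_transform)
    return Transform("composite", c)
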