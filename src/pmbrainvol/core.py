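"""Core grid containers shared by every stage of the pipeline.

A :class:`VolumeImage` is a 3-D scalar grid with voxel spacing (mm) and a
world origin; a :class:`LabelMap` is an integer-coded segmentation on the
same kind of grid.  Arrays are stored in ``(z, y, x)`` index order, the
convention used by ``SimpleITK.GetArrayFromImage``; spacing and origin are
stored per numpy axis (i.e. also ``(z, y, x)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import SimpleITK as sitk

# Fixed label coding used throughout (tie-breaks favour the lower index).
BACKGROUND = 0
CEREBRUM = 1
CEREBELLUM = 2
BRAINSTEM = 3
CSF = 4

#: EM class order: cerebrum, cerebellum, brainstem, CSF.
CLASS_LABELS = (CEREBRUM, CEREBELLUM, BRAINSTEM, CSF)
CLASS_NAMES = {CEREBRUM: "cerebrum", CEREBELLUM: "cerebellum",
               BRAINSTEM: "brainstem", CSF: "csf"}


class GridMismatchError(ValueError):
    """Two volumes expected on the same grid are not."""


@dataclass
class VolumeImage:
    """3-D scalar image with voxel spacing metadata.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Voxel intensities.
    spacing : tuple of float
        Voxel size in mm per numpy axis.
    origin : tuple of float
        World coordinate of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    # -- grid bookkeeping -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "VolumeImage | LabelMap") -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing)
                and np.allclose(self.origin, other.origin))

    def require_same_grid(self, other: "VolumeImage | LabelMap", what: str = "volume") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"{what}: grids differ (shape {self.shape} vs {other.shape}, "
                f"spacing {self.spacing} vs {other.spacing})")

    def with_data(self, data: np.ndarray) -> "VolumeImage":
        return replace(self, data=np.asarray(data))

    # -- SimpleITK bridge --------------------------------------------------
    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data, dtype=np.float64))
        img.SetSpacing(tuple(self.spacing[::-1]))
        img.SetOrigin(tuple(self.origin[::-1]))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "VolumeImage":
        return cls(sitk.GetArrayFromImage(img),
                   spacing=tuple(img.GetSpacing())[::-1],
                   origin=tuple(img.GetOrigin())[::-1])

    # -- NIfTI I/O ---------------------------------------------------------
    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag(list(self.spacing[::-1]) + [1.0])
        affine[:3, 3] = self.origin[::-1]
        nib.save(nib.Nifti1Image(np.asarray(self.data.T, dtype=np.float32), affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "VolumeImage":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        origin = img.affine[:3, 3]
        return cls(np.asanyarray(img.dataobj).T.astype(np.float64),
                   spacing=tuple(zooms)[::-1], origin=tuple(origin)[::-1])


@dataclass
class LabelMap(VolumeImage):
    """Integer-coded segmentation sharing the :class:`VolumeImage` grid."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.allclose(self.data, np.round(self.data)):
                raise ValueError("label map has non-integer values")
            self.data = np.round(self.data).astype(np.int16)

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data, dtype=np.int16))
        img.SetSpacing(tuple(self.spacing[::-1]))
        img.SetOrigin(tuple(self.origin[::-1]))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "LabelMap":
        return cls(sitk.GetArrayFromImage(img).astype(np.int16),
                   spacing=tuple(img.GetSpacing())[::-1],
                   origin=tuple(img.GetOrigin())[::-1])

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag(list(self.spacing[::-1]) + [1.0])
        affine[:3, 3] = self.origin[::-1]
        nib.save(nib.Nifti1Image(np.asarray(self.data.T, dtype=np.int16), affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "LabelMap":
        v = VolumeImage.from_nifti(path)
        return cls(np.round(v.data).astype(np.int16), spacing=v.spacing, origin=v.origin)

    def count(self, label: int) -> int:
        return int(np.count_nonzero(self.data == label))


@dataclass
class ProbabilisticAtlas:
    """Template image + per-class prior probability volumes + brain mask.

    All components share the template grid.  ``priors`` maps class label to
    a probability volume; within the mask the per-voxel prior sum is 1.
    """

    template: VolumeImage
    priors: Mapping[int, np.ndarray]
    mask: LabelMap
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.priors = {int(k): np.asarray(v, dtype=np.float64) for k, v in self.priors.items()}
        for lbl, p in self.priors.items():
            if p.shape != self.template.shape:
                raise GridMismatchError(f"prior for class {lbl} not on template grid")
        self.template.require_same_grid(self.mask, "atlas mask")

    @property
    def class_labels(self) -> tuple[int, ...]:
        return tuple(sorted(self.priors))

    def prior_stack(self, order: tuple[int, ...] | None = None) -> np.ndarray:
        order = order or self.class_labels
        return np.stack([self.priors[k] for k in order], axis=0)

    def normalized(self) -> "ProbabilisticAtlas":
        """Renormalize priors to sum to 1 inside the mask, 0 outside."""
        stack = self.prior_stack()
        total = stack.sum(axis=0)
        inside = (self.mask.data > 0) & (total > 0)
        out = np.zeros_like(stack)
        out[:, inside] = stack[:, inside] / total[inside]
        priors = {k: out[i] for i, k in enumerate(self.class_labels)}
        return ProbabilisticAtlas(self.template, priors, self.mask, dict(self.provenance))

    # -- directory layout: template.nii.gz, prior_<name>.nii.gz, mask.nii.gz
    def save(self, directory: str | Path) -> None:
        import json
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.template.to_nifti(d / "template.nii.gz")
        self.mask.to_nifti(d / "mask.nii.gz")
        for lbl, p in self.priors.items():
            name = CLASS_NAMES.get(lbl, f"class{lbl}")
            self.template.with_data(p).to_nifti(d / f"prior_{name}.nii.gz")
        (d / "provenance.json").write_text(json.dumps(self.provenance, indent=2, default=str))

    @classmethod
    def load(cls, directory: str | Path) -> "ProbabilisticAtlas":
        import json
        d = Path(directory)
        template = VolumeImage.from_nifti(d / "template.nii.gz")
        mask = LabelMap.from_nifti(d / "mask.nii.gz")
        name_to_label = {v: k for k, v in CLASS_NAMES.items()}
        priors = {}
        for f in sorted(d.glob("prior_*.nii.gz")):
            name = f.name[len("prior_"):-len(".nii.gz")]
            lbl = name_to_label.get(name)
            if lbl is None:
                lbl = int(name.replace("class", ""))
            priors[lbl] = VolumeImage.from_nifti(f).data
        prov_file = d / "provenance.json"
        provenance = json.loads(prov_file.read_text()) if prov_file.exists() else {}
        return cls(template, priors, mask, provenance)
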