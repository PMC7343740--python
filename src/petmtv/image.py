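"""Core image containers for SUV volumes and binary volumes of interest.

The substrate of every measurement in this package is a 3D grid of
standardized uptake values (SUV, body-weight normalized, unitless g/ml
convention) with anisotropic voxel spacing in mm.  Segmentations are binary
masks aligned voxel-for-voxel to their parent SUV volume.  Index order is
(i, j, k) -> (x, y, z); all voxel coordinates are 0-based and axial crops
use half-open index intervals [z_lo, z_hi).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger("petmtv")

__all__ = [
    "SuvVolume",
    "VoiMask",
    "SeedClick",
    "AlignmentError",
    "load_suv_volume",
    "save_suv_volume",
    "save_mask",
    "load_mask",
    "crop_axial_range",
]


class AlignmentError(ValueError):
    """Raised when a mask and a volume (or two masks) are not on the same grid."""


def _as_spacing(spacing) -> tuple[float, float, float]:
    dx, dy, dz = (float(s) for s in spacing)
    if dx <= 0 or dy <= 0 or dz <= 0:
        raise ValueError(f"voxel spacing must be positive, got {(dx, dy, dz)}")
    return (dx, dy, dz)


@dataclass
class SuvVolume:
    """A 3D grid of SUV values.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        SUV per voxel, finite and >= 0.  Stored as float32.
    spacing : (dx, dy, dz)
        Voxel spacing in mm along (x, y, z); all components > 0.
    origin : (x0, y0, z0)
        Physical offset of voxel (0, 0, 0) in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float32)
        if arr.ndim != 3:
            raise ValueError(f"SUV volume must be 3D, got {arr.ndim}D")
        if not np.all(np.isfinite(arr)):
            raise ValueError("SUV volume contains non-finite values")
        if arr.min() < 0:
            raise ValueError("SUV volume contains negative values")
        self.values = arr
        self.spacing = _as_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def suv_at(self, index: tuple[int, int, int]) -> float:
        return float(self.values[tuple(index)])

    def contains_index(self, index) -> bool:
        return all(0 <= int(c) < n for c, n in zip(index, self.shape))


@dataclass
class VoiMask:
    """A binary volume of interest aligned to a parent :class:`SuvVolume`.

    Provenance (segmentation method, observer, free-text note) rides along so
    results remain attributable when masks are unioned, voted or edited.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    method: str | None = None
    observer: str | None = None
    note: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got {arr.ndim}D")
        self.values = arr.astype(bool)
        self.spacing = _as_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @classmethod
    def from_volume(cls, volume: SuvVolume, values: np.ndarray, **prov) -> "VoiMask":
        values = np.asarray(values)
        if values.shape != volume.shape:
            raise AlignmentError(
                f"mask shape {values.shape} differs from volume shape {volume.shape}"
            )
        return cls(values, volume.spacing, volume.origin, **prov)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.values))

    @property
    def voxel_volume_ml(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    @property
    def volume_ml(self) -> float:
        return self.voxel_count * self.voxel_volume_ml

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def check_aligned(self, other) -> None:
        if self.shape != other.shape:
            raise AlignmentError(f"shape mismatch: {self.shape} vs {other.shape}")
        if not np.allclose(self.spacing, other.spacing):
            raise AlignmentError(f"spacing mismatch: {self.spacing} vs {other.spacing}")

    def union(self, other: "VoiMask") -> "VoiMask":
        self.check_aligned(other)
        return replace(self, values=self.values | other.values)

    def intersection(self, other: "VoiMask") -> "VoiMask":
        self.check_aligned(other)
        return replace(self, values=self.values & other.values)

    def difference(self, other: "VoiMask") -> "VoiMask":
        self.check_aligned(other)
        return replace(self, values=self.values & ~other.values)


@dataclass(frozen=True)
class SeedClick:
    """A single observer click, as a 0-based voxel index in the hottest part
    of a lesion."""

    index: tuple[int, int, int]
    observer_id: str = ""
    patient_id: str = ""

    def validate(self, volume: SuvVolume) -> None:
        if len(self.index) != 3:
            raise ValueError(f"click index must have 3 components: {self.index}")
        if not volume.contains_index(self.index):
            raise ValueError(
                f"click {self.index} outside volume bounds {volume.shape}"
            )


# ---------------------------------------------------------------------------
# NIfTI I/O


def load_suv_volume(path) -> SuvVolume:
    """Load a 3D NIfTI image as an SUV volume.

    Spacing is taken from the header; negative voxels (interpolation or
    reconstruction artifacts) are clipped to zero with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {data.ndim}D")
    data = np.asarray(data, dtype=np.float32)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: image contains non-finite values")
    n_neg = int(np.count_nonzero(data < 0))
    if n_neg:
        msg = f"{path}: clipped {n_neg} negative voxel(s) to 0"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
        data = np.clip(data, 0, None)
    zooms = img.header.get_zooms()[:3]
    spacing = _as_spacing(zooms)
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return SuvVolume(data, spacing, origin)


def save_suv_volume(volume: SuvVolume, path) -> None:
    """Write an SUV volume as float32 NIfTI."""
    img = nib.Nifti1Image(volume.values.astype(np.float32), volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def save_mask(mask: VoiMask, path, parent: SuvVolume | None = None) -> None:
    """Write a mask as an unsigned 8-bit 0/1 NIfTI label image.

    A JSON sidecar (``<path minus extensions>.json``) records provenance.
    Round-trip load reproduces the voxel count exactly (integer labels).
    """
    if parent is not None:
        if mask.shape != parent.shape:
            raise AlignmentError(
                f"mask shape {mask.shape} differs from parent shape {parent.shape}"
            )
    img = nib.Nifti1Image(mask.values.astype(np.uint8), mask.affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
    sidecar = _sidecar_path(path)
    sidecar.write_text(
        json.dumps(
            {"method": mask.method, "observer": mask.observer, "note": mask.note},
            indent=2,
        )
    )


def _sidecar_path(path) -> Path:
    p = Path(path)
    name = p.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            name = name[: -len(ext)]
            break
    return p.with_name(name + ".json")


def load_mask(path) -> VoiMask:
    """Load a 0/1 NIfTI label image (and its JSON sidecar, if present)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D label image, got {data.ndim}D")
    spacing = _as_spacing(img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    prov: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        raw = json.loads(sidecar.read_text())
        prov = {
            "method": raw.get("method"),
            "observer": raw.get("observer"),
            "note": raw.get("note") or "",
        }
    return VoiMask(data > 0, spacing, origin, **prov)


# ---------------------------------------------------------------------------
# Axial cropping ("slider" field-of-view restriction)


def crop_axial_range(obj, z_lo: int, z_hi: int):
    """Zero out voxels outside the axial slice range [z_lo, z_hi).

    Works on either an :class:`SuvVolume` (voxels zeroed) or a
    :class:`VoiMask` (voxels removed).  The grid shape is unchanged so
    alignment with other objects is preserved.  Used to exclude, e.g.,
    superior slices containing the brain or inferior slices containing the
    bladder before totalling tumor burden.
    """
    nz = obj.shape[2]
    z_lo, z_hi = int(z_lo), int(z_hi)
    if not (0 <= z_lo < z_hi <= nz):
        raise ValueError(
            f"invalid axial range [{z_lo}, {z_hi}) for {nz} slices "
            "(need 0 <= z_lo < z_hi <= nz)"
        )
    keep = np.zeros(obj.shape, dtype=bool)
    keep[:, :, z_lo:z_hi] = True
    if isinstance(obj, SuvVolume):
        return SuvVolume(np.where(keep, obj.values, 0.0), obj.spacing, obj.origin)
    if isinstance(obj, VoiMask):
        return replace(obj, values=obj.values & keep)
    raise TypeError(f"cannot crop object of type {type(obj).__name__}")
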