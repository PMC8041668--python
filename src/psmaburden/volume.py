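"""NIfTI-backed voxel-grid data model for quantitative PET volumes.

An :class:`SUVVolume` is a 3D scalar grid of standardized uptake values with
physical voxel spacing in mm; a :class:`RegionMask` is a boolean grid
congruent with its reference volume.  All physical measurements (lesion
volumes in ml, SUVpeak sphere radii) derive from the spacing stored here, so
the voxel volume computed by :meth:`SUVVolume.voxel_volume_ml` is the single
source of truth for the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "SUVVolume",
    "RegionMask",
    "VolumeError",
    "CongruenceError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
]


class VolumeError(ValueError):
    """Invalid volume data or header (non-3D image, bad spacing, NaNs)."""


class CongruenceError(ValueError):
    """Mask and reference volume do not share the same grid."""


_SPACING_RTOL = 1e-4


@dataclass(frozen=True)
class SUVVolume:
    """3D grid of SUV values with physical spacing.

    Parameters
    ----------
    values
        3D float array of SUV, finite and non-negative.
    spacing
        Voxel edge lengths ``(dx, dy, dz)`` in mm, strictly positive.
    origin
        Physical coordinate of voxel ``(0, 0, 0)`` in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise VolumeError(f"expected 3D volume, got {values.ndim}D array")
        if not np.all(np.isfinite(values)):
            raise VolumeError("SUV values must be finite")
        if np.any(values < 0):
            raise VolumeError("SUV values must be non-negative")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise VolumeError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in ml (spacing is in mm; 1 ml = 1000 mm^3)."""
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0


@dataclass(frozen=True)
class RegionMask:
    """Boolean region on the grid of a paired :class:`SUVVolume`."""

    values: np.ndarray
    label: str = "region"
    spacing: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise VolumeError(f"expected 3D mask, got {values.ndim}D array")
        object.__setattr__(self, "values", values.astype(bool))
        if self.spacing is not None:
            object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def check_congruent(self, reference: SUVVolume) -> None:
        """Raise :class:`CongruenceError` unless mask and volume share a grid."""
        if self.shape != reference.shape:
            raise CongruenceError(
                f"mask shape {self.shape} does not match volume shape {reference.shape}"
            )
        if self.spacing is not None and not np.allclose(
            self.spacing, reference.spacing, rtol=_SPACING_RTOL
        ):
            raise CongruenceError(
                f"mask spacing {self.spacing} does not match volume spacing {reference.spacing}"
            )


def _affine(spacing: tuple[float, float, float], origin: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag([*spacing, 1.0])
    aff[:3, 3] = origin
    return aff


def read_volume(path) -> SUVVolume:
    """Read a 3D NIfTI-1 image as an :class:`SUVVolume`.

    Spacing is taken from the header pixdim; the origin from the affine
    translation.  Raises :class:`VolumeError` for non-3D images or
    non-positive header spacing, naming the offending field.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeError(f"expected 3D volume, got {data.ndim}D image in {path}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise VolumeError(f"header pixdim must be strictly positive, got {zooms} in {path}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return SUVVolume(values=data.astype(np.float64), spacing=tuple(float(z) for z in zooms), origin=origin)


def write_volume(volume: SUVVolume, path) -> None:
    """Write an :class:`SUVVolume` to a NIfTI-1 file (round-trip safe)."""
    img = nib.Nifti1Image(volume.values.astype(np.float64), _affine(volume.spacing, volume.origin))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_mask(path, reference: SUVVolume, label: str = "region") -> RegionMask:
    """Read a NIfTI mask congruent with ``reference``; nonzero voxels are True."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeError(f"expected 3D mask, got {data.ndim}D image in {path}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    mask = RegionMask(values=data != 0, label=label, spacing=zooms)
    mask.check_congruent(reference)
    return mask


def write_mask(mask: RegionMask, path, reference: SUVVolume | None = None) -> None:
    """Write a mask as a 0/1 uint8 NIfTI volume."""
    spacing = mask.spacing or (reference.spacing if reference is not None else (1.0, 1.0, 1.0))
    origin = reference.origin if reference is not None else (0.0, 0.0, 0.0)
    img = nib.Nifti1Image(mask.values.astype(np.uint8), _affine(tuple(spacing), tuple(origin)))
    img.header.set_zooms(tuple(spacing))
    nib.save(img, str(path))
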