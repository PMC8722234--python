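"""Scalar volumes, voxel masks and NIfTI round-trip I/O.

All stages of the pipeline operate on pairs of co-registered 3D grids: a
scalar image (FET-PET activity in SUV, or an ADC map in 10^-6 mm^2/s) and
boolean masks aligned to it. Inputs are assumed already rigidly aligned;
grids that disagree in shape or voxel spacing are rejected rather than
resampled — registration/resampling is upstream tooling, not part of this
package.

Coordinates are 0-based voxel indices; physical positions derive from the
voxel spacing only. NIfTI headers are written with a diagonal affine that
encodes the spacing, which is all that round-trip fidelity requires here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import EmptyMaskError, GridMismatchError, IOFailure, ValidationError

MODALITIES = ("FET_SUV", "ADC")


def _as_spacing(spacing) -> tuple[float, float, float]:
    sp = tuple(float(s) for s in spacing)
    if len(sp) != 3 or any(s <= 0 for s in sp):
        raise ValidationError(f"voxel spacing must be a positive triple, got {spacing!r}")
    return sp


@dataclass(frozen=True)
class ScalarVolume:
    """A 3D scalar image with voxel spacing, modality tag and units.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Finite voxel values.
    voxel_spacing_mm : tuple of 3 floats
        Voxel edge lengths in millimetres.
    modality : {"FET_SUV", "ADC"}
    units : str
        e.g. "SUV" or "1e-6 mm^2/s".
    """

    values: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    modality: str = "FET_SUV"
    units: str = ""

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 3:
            raise ValidationError(f"scalar volume must be 3D, got ndim={arr.ndim}")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("scalar volume contains NaN or Inf voxels")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "voxel_spacing_mm", _as_spacing(self.voxel_spacing_mm))
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_spacing_mm))


@dataclass(frozen=True)
class VoxelMask:
    """A boolean grid congruent with a companion :class:`ScalarVolume`."""

    flags: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]

    def __post_init__(self):
        arr = np.asarray(self.flags)
        if arr.ndim != 3:
            raise ValidationError(f"mask must be 3D, got ndim={arr.ndim}")
        object.__setattr__(self, "flags", arr.astype(bool))
        object.__setattr__(self, "voxel_spacing_mm", _as_spacing(self.voxel_spacing_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.flags.shape

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.flags))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_spacing_mm))

    @property
    def volume_mm3(self) -> float:
        """Mask volume: voxel count times voxel volume."""
        return self.n_voxels * self.voxel_volume_mm3

    def intersect(self, other: "VoxelMask") -> "VoxelMask":
        check_congruent(self, other)
        return VoxelMask(self.flags & other.flags, self.voxel_spacing_mm)

    def subtract(self, other: "VoxelMask") -> "VoxelMask":
        check_congruent(self, other)
        return VoxelMask(self.flags & ~other.flags, self.voxel_spacing_mm)


def check_congruent(a, b) -> None:
    """Raise :class:`GridMismatchError` unless grids share shape and spacing."""
    if a.shape != b.shape:
        raise GridMismatchError(f"grid shapes differ: {a.shape} vs {b.shape}")
    if not np.allclose(a.voxel_spacing_mm, b.voxel_spacing_mm, rtol=1e-6, atol=1e-6):
        raise GridMismatchError(
            f"voxel spacings differ: {a.voxel_spacing_mm} vs {b.voxel_spacing_mm}"
        )


def mask_statistics(volume: ScalarVolume, mask: VoxelMask) -> dict:
    """Moments of a scalar volume over a voxel mask.

    Returns a dict with ``mean, sd, max, min, n, volume_mm3``; ``sd`` uses
    the n-1 denominator (NaN for a single voxel). Raises
    :class:`EmptyMaskError` on an empty mask — callers decide policy.
    """
    check_congruent(volume, mask)
    vals = volume.values[mask.flags]
    if vals.size == 0:
        raise EmptyMaskError("statistics requested over an empty mask")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan")
    return {
        "mean": float(np.mean(vals)),
        "sd": sd,
        "max": float(np.max(vals)),
        "min": float(np.min(vals)),
        "n": int(vals.size),
        "volume_mm3": mask.volume_mm3,
    }


def _load_nifti(path):
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # malformed header, missing file, ...
        raise IOFailure(path, f"failed to read NIfTI ({exc})") from None
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected a 3D volume, got ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def read_volume(path, modality: str = "FET_SUV", units: str = "") -> ScalarVolume:
    """Read a 3D NIfTI scalar volume; 4D series and non-finite voxels are rejected."""
    data, spacing = _load_nifti(path)
    return ScalarVolume(data.astype(float), spacing, modality=modality, units=units)


def write_volume(volume: ScalarVolume, path) -> None:
    affine = np.diag(list(volume.voxel_spacing_mm) + [1.0])
    img = nib.Nifti1Image(volume.values.astype(np.float64), affine)
    img.header.set_zooms(volume.voxel_spacing_mm)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise IOFailure(path, f"failed to write NIfTI ({exc})") from None


def read_mask(path) -> VoxelMask:
    data, spacing = _load_nifti(path)
    return VoxelMask(data > 0, spacing)


def write_mask(mask: VoxelMask, path) -> None:
    affine = np.diag(list(mask.voxel_spacing_mm) + [1.0])
    img = nib.Nifti1Image(mask.flags.astype(np.uint8), affine)
    img.header.set_zooms(mask.voxel_spacing_mm)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise IOFailure(path, f"failed to write NIfTI ({exc})") from None
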