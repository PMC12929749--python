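"""Volume/mask data model, geometry-aware volume computation, Dice, NIfTI I/O.

Arrays are indexed ``(z, y, x)`` throughout the package: ``z`` is the axial
slice index (inferior–superior stack), ``y`` runs anterior→posterior and
``x`` left→right.  An axial slice is the plane at fixed ``z``, a coronal
slice at fixed ``y``, a sagittal slice at fixed ``x``.  Voxel spacing is the
matching triple ``(dz, dy, dx)`` in millimetres; neck MRI of the kind this
package targets is strongly anisotropic (~0.5 mm in plane, ~4.8 mm between
axial slices), which is why physical volumes must always be computed through
the spacing and never from voxel counts alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "GeometryError",
    "FormatError",
    "ImageVolume",
    "BinaryMask3D",
    "VolumeEstimate",
    "mask_volume_mm3",
    "dice_coefficient",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
]


class GeometryError(ValueError):
    """Shape or spacing of paired grids is inconsistent."""


class FormatError(ValueError):
    """An on-disk image does not satisfy the package's data model."""


def _check_spacing(spacing) -> tuple[float, float, float]:
    dz, dy, dx = (float(s) for s in spacing)
    if not (dz > 0 and dy > 0 and dx > 0):
        raise GeometryError(f"spacing must be strictly positive, got {(dz, dy, dx)}")
    return (dz, dy, dx)


@dataclass
class ImageVolume:
    """A 3D scalar image with physical voxel spacing.

    Parameters
    ----------
    id : str
        Patient / case identifier.
    data : ndarray, shape (nz, ny, nx)
        Scalar intensities, ``(z, y, x)`` indexed. Stored as float32.
    spacing : tuple of float
        ``(dz, dy, dx)`` voxel edge lengths in mm, all strictly positive.
    """

    id: str
    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise GeometryError(f"volume must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("volume intensities must be finite")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_mm3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx


@dataclass
class BinaryMask3D:
    """A {0,1} grid congruent to an :class:`ImageVolume` (truth or prediction)."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise GeometryError(f"mask must be 3D, got shape {arr.shape}")
        if not np.isin(arr, (0, 1)).all():
            raise FormatError("mask values must be exactly {0, 1}")
        self.data = arr.astype(np.uint8)
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def positive_count(self) -> int:
        return int(self.data.sum())

    def check_congruent(self, other) -> None:
        if self.shape != other.shape:
            raise GeometryError(f"shape mismatch: {self.shape} vs {other.shape}")


@dataclass
class VolumeEstimate:
    """A lesion volume as a voxel count plus its physical size in mm³."""

    voxel_count: int
    mm3: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.voxel_count < 0:
            raise ValueError("voxel_count must be nonnegative")
        if (self.mm3 == 0.0) != (self.voxel_count == 0):
            if self.voxel_count > 0 and self.mm3 <= 0.0:
                raise ValueError("positive voxel_count requires positive mm3")
            if self.voxel_count == 0 and self.mm3 != 0.0:
                raise ValueError("empty mask must have mm3 == 0")


def mask_volume_mm3(mask: BinaryMask3D) -> VolumeEstimate:
    """Physical volume of a binary mask: ``count × dz·dy·dx`` mm³."""
    count = mask.positive_count()
    dz, dy, dx = mask.spacing
    return VolumeEstimate(voxel_count=count, mm3=count * dz * dy * dx)


def dice_coefficient(pred: BinaryMask3D, truth: BinaryMask3D) -> float:
    """Dice similarity ``2|X∩Y| / (|X|+|Y|)`` between prediction and truth.

    ``truth`` must contain at least one positive voxel (only lesion-positive
    patients are segmented); an all-zero truth raises :class:`ValueError`.
    An empty *prediction* against a nonempty truth scores 0.
    """
    pred.check_congruent(truth)
    y = truth.positive_count()
    if y == 0:
        raise ValueError("Dice is undefined for an empty ground-truth mask")
    x = pred.positive_count()
    inter = int(np.logical_and(pred.data, truth.data).sum())
    return 2.0 * inter / (x + y)


# ---------------------------------------------------------------------------
# NIfTI-1 I/O.  On disk, NIfTI data is (x, y, z)-ordered (fastest axis first);
# in memory we use (z, y, x), so arrays are transposed on the way through and
# spacing maps to header zooms reversed.

def _read_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    if img.ndim != 3:
        raise FormatError(f"{path}: expected a 3D image, got {img.ndim}D")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(s) or s <= 0 for s in zooms):
        raise FormatError(f"{path}: missing or invalid voxel spacing {zooms}")
    data = np.asanyarray(img.dataobj).transpose(2, 1, 0)
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return data, spacing


def _affine(spacing) -> np.ndarray:
    dz, dy, dx = spacing
    return np.diag([dx, dy, dz, 1.0])


def read_volume(path, id: str | None = None) -> ImageVolume:
    """Read a 3D NIfTI volume into the package's ``(z, y, x)`` convention."""
    data, spacing = _read_nifti(path)
    return ImageVolume(id=id or Path(str(path)).name.split(".")[0],
                       data=data.astype(np.float32), spacing=spacing)


def write_volume(volume: ImageVolume, path) -> None:
    arr = volume.data.transpose(2, 1, 0).astype(np.float32)
    nib.save(nib.Nifti1Image(arr, _affine(volume.spacing)), str(path))


def read_mask(path) -> BinaryMask3D:
    """Read a binary NIfTI mask; values other than {0,1} are rejected."""
    data, spacing = _read_nifti(path)
    if not np.isin(data, (0, 1)).all():
        raise FormatError(f"{path}: mask values outside {{0, 1}}")
    return BinaryMask3D(data=data.astype(np.uint8), spacing=spacing)


def write_mask(mask: BinaryMask3D, path) -> None:
    arr = mask.data.transpose(2, 1, 0).astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, _affine(mask.spacing)), str(path))
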