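"""The 3D positive region ("bounding region") from per-view slice labels.

A voxel (z, y, x) is inside the region iff its axial slice z, coronal slice
y, and sagittal slice x were all classified positive — the product of the
three positive index sets.  Gapped label runs are kept as-is (a set product,
not a filled box), matching that definition literally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BinaryMask3D, GeometryError

__all__ = ["PositiveRegion", "build_region", "region_mask"]


@dataclass(frozen=True)
class PositiveRegion:
    """Product-of-index-sets region with derived bookkeeping."""

    z_set: tuple[int, ...]
    y_set: tuple[int, ...]
    x_set: tuple[int, ...]

    @property
    def is_empty(self) -> bool:
        return not (self.z_set and self.y_set and self.x_set)

    @property
    def voxel_count(self) -> int:
        return len(self.z_set) * len(self.y_set) * len(self.x_set)

    def contains(self, z: int, y: int, x: int) -> bool:
        return z in self.z_set and y in self.y_set and x in self.x_set

    @property
    def bounding_box(self):
        """Tight per-axis (min, max) bounds, or None if empty."""
        if self.is_empty:
            return None
        return tuple((min(s), max(s)) for s in (self.z_set, self.y_set, self.x_set))


def _indices(labels) -> tuple[int, ...]:
    arr = np.asarray(labels)
    if arr.ndim != 1:
        raise GeometryError("label lists must be 1D")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("labels must be binary")
    return tuple(int(i) for i in np.flatnonzero(arr))


def build_region(axial_labels, coronal_labels, sagittal_labels,
                 shape: tuple[int, int, int] | None = None) -> PositiveRegion:
    """Region from the three views' binary slice labels.

    ``shape``, when given, must match the label list lengths (axial ↔ z,
    coronal ↔ y, sagittal ↔ x).
    """
    if shape is not None:
        lens = tuple(len(np.asarray(l)) for l in
                     (axial_labels, coronal_labels, sagittal_labels))
        if lens != tuple(shape):
            raise GeometryError(f"label lengths {lens} do not match shape {shape}")
    return PositiveRegion(_indices(axial_labels), _indices(coronal_labels),
                          _indices(sagittal_labels))


def region_mask(region: PositiveRegion, shape: tuple[int, int, int],
                spacing=(1.0, 1.0, 1.0)) -> BinaryMask3D:
    """Materialize the region as a binary mask of the given shape."""
    data = np.zeros(shape, dtype=np.uint8)
    if not region.is_empty:
        for s, n, name in zip((region.z_set, region.y_set, region.x_set),
                              shape, "zyx"):
            if max(s) >= n or min(s) < 0:
                raise GeometryError(f"region {name}-indices exceed shape {shape}")
        data[np.ix_(region.z_set, region.y_set, region.x_set)] = 1
    return BinaryMask3D(data=data, spacing=spacing)
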