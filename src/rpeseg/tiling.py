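"""64×64 tile sampling around the predicted region, axial stretching, and
reassembly of tile predictions into 3D score maps.

Tiles are sampled on a stride-32 lattice over each slice that meets the
region, with one edge-clamped square added per axis when the slice size is
not a lattice multiple.  A square is kept iff the number of region pixels it
contains reaches ⅓ of the region's cross-section on that slice, or an
absolute minimum count (1,000 at the native 288–640 px scale; scale this
down with (in_plane/512)² for smaller phantoms).  Coronal and sagittal
slices of volumes with fewer than 64 axial slices are first stretched along
z to 64 rows so a 64×64 square fits; the stretch is inverted after
reassembly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GeometryError
from .planes import PlaneView

__all__ = ["Tile", "stretch_axial", "unstretch_axial", "sample_tiles",
           "reassemble", "lattice_offsets", "TILE_SIZE", "TILE_STRIDE",
           "ABS_MIN_REFERENCE"]

TILE_SIZE = 64
TILE_STRIDE = 32
ABS_MIN_REFERENCE = 1000  # tuned to the native in-plane scale (288-640 px)


@dataclass(frozen=True)
class Tile:
    """A 64×64 patch with provenance sufficient for exact reinsertion."""

    pixels: np.ndarray     # float16 values in [0, 1]
    view: PlaneView
    slice_index: int       # index along the view axis (stretched space for
                           # coronal/sagittal when stretching was applied)
    row_off: int
    col_off: int
    stretch_factor: float = 1.0


def _resample_axis0(arr: np.ndarray, new_len: int, order: int) -> np.ndarray:
    """Center-aligned resampling along axis 0 (order 0 nearest, 1 linear)."""
    old = arr.shape[0]
    if new_len == old:
        return arr.copy()
    c = (np.arange(new_len) + 0.5) * old / new_len - 0.5
    if order == 0:
        idx = np.clip(np.round(c).astype(int), 0, old - 1)
        return arr[idx]
    lo = np.floor(c).astype(int)
    frac = (c - lo).reshape((-1,) + (1,) * (arr.ndim - 1))
    lo0 = np.clip(lo, 0, old - 1)
    hi = np.clip(lo + 1, 0, old - 1)
    out = (1.0 - frac) * arr[lo0].astype(np.float64) + frac * arr[hi].astype(np.float64)
    return out


def stretch_axial(arr, min_len: int = TILE_SIZE, order: int = 1):
    """Resample axis 0 (the axial stack) up to ``min_len`` if shorter.

    Returns ``(resampled, factor)`` with ``factor = new_len / original``;
    volumes already long enough pass through with factor 1.  Use ``order=0``
    for masks (keeps them binary), ``order=1`` for intensities.
    """
    a = np.asarray(arr)
    old = a.shape[0]
    if old >= min_len:
        return a.copy(), 1.0
    out = _resample_axis0(a, min_len, order)
    if order == 0:
        out = out.astype(a.dtype)
    return out, min_len / old


def unstretch_axial(arr, original_len: int, order: int = 1) -> np.ndarray:
    """Inverse of :func:`stretch_axial`: resample axis 0 back to
    ``original_len`` (exact under nearest-neighbor for integer factors)."""
    return _resample_axis0(np.asarray(arr), original_len, order)


def lattice_offsets(length: int, size: int = TILE_SIZE,
                    stride: int = TILE_STRIDE) -> list[int]:
    """Stride-lattice start offsets covering ``[0, length)``, edge-clamped."""
    if length < size:
        raise GeometryError(f"slice extent {length} smaller than tile size {size}")
    offs = list(range(0, length - size + 1, stride))
    if offs[-1] != length - size:
        offs.append(length - size)
    return offs


def sample_tiles(slice2d: np.ndarray, region_footprint: np.ndarray,
                 view: PlaneView, index: int, *, stride: int = TILE_STRIDE,
                 size: int = TILE_SIZE, frac_min: float = 1.0 / 3.0,
                 abs_min: int = ABS_MIN_REFERENCE,
                 stretch_factor: float = 1.0) -> list[Tile]:
    """Tiles on the stride lattice that satisfy the region-coverage rule.

    ``region_footprint`` is the region's binary cross-section on this slice
    (congruent with ``slice2d``).  A square is kept iff the region pixels it
    contains are ≥ ``frac_min`` × (region pixels on the whole slice) or
    ≥ ``abs_min``.  An empty footprint yields no tiles.
    """
    img = np.asarray(slice2d)
    fp = np.asarray(region_footprint)
    if img.shape != fp.shape:
        raise GeometryError(f"slice {img.shape} vs footprint {fp.shape}")
    total = int(fp.sum())
    if total == 0:
        return []
    tiles = []
    need = frac_min * total
    # cumulative 2D sum for O(1) window counts
    cs = np.zeros((img.shape[0] + 1, img.shape[1] + 1), dtype=np.int64)
    cs[1:, 1:] = np.cumsum(np.cumsum(fp, axis=0), axis=1)
    for r in lattice_offsets(img.shape[0], size, stride):
        for c in lattice_offsets(img.shape[1], size, stride):
            inside = int(cs[r + size, c + size] - cs[r, c + size]
                         - cs[r + size, c] + cs[r, c])
            if inside >= need or inside >= abs_min:
                tiles.append(Tile(
                    pixels=img[r:r + size, c:c + size].astype(np.float16),
                    view=view, slice_index=index, row_off=r, col_off=c,
                    stretch_factor=stretch_factor))
    return tiles


def _tile_slab(shape, view, idx, r, c, size):
    """Index triple selecting a tile's voxels inside a 3D array."""
    rows, cols = slice(r, r + size), slice(c, c + size)
    if view is PlaneView.AXIAL:        # slice plane (y, x)
        return (idx, rows, cols)
    if view is PlaneView.CORONAL:      # slice plane (z, x)
        return (rows, idx, cols)
    return (rows, cols, idx)           # sagittal: (z, y)


def reassemble(tiles: list[Tile], predictions: list[np.ndarray],
               shape: tuple[int, int, int], fusion: str = "mean") -> np.ndarray:
    """Insert per-tile predictions into a zero-initialized 3D score map.

    Overlapping tiles are fused per voxel (mean by default, or max); voxels
    covered by no tile stay 0, so "no tiles" means "no edema".  ``shape`` is
    the (possibly stretched) grid the tile offsets refer to; apply
    :func:`unstretch_axial` afterwards if stretching was used.
    """
    if fusion not in ("mean", "max"):
        raise ValueError(f"unknown fusion {fusion!r}")
    if len(tiles) != len(predictions):
        raise ValueError("one prediction per tile required")
    acc = np.zeros(shape, dtype=np.float64)
    cnt = np.zeros(shape, dtype=np.int32)
    for tile, pred in zip(tiles, predictions):
        p = np.asarray(pred, dtype=np.float64)
        if p.shape != tile.pixels.shape:
            raise ValueError("prediction shape must match tile shape")
        size = p.shape[0]
        axis = tile.view.axis
        plane_dims = tuple(d for a, d in enumerate(shape) if a != axis)
        if not (0 <= tile.slice_index < shape[axis]
                and 0 <= tile.row_off <= plane_dims[0] - size
                and 0 <= tile.col_off <= plane_dims[1] - size):
            raise GeometryError(f"tile provenance outside shape {shape}")
        slab = _tile_slab(shape, tile.view, tile.slice_index,
                          tile.row_off, tile.col_off, size)
        if fusion == "mean":
            acc[slab] += p
        else:
            acc[slab] = np.maximum(acc[slab], p)
        cnt[slab] += 1
    if fusion == "mean":
        out = np.divide(acc, cnt, out=np.zeros_like(acc), where=cnt > 0)
    else:
        out = acc
    return out
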