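"""Slice extraction per anatomical view, classifier-input preprocessing,
and ground-truth slice labels.

The three orthogonal views index the volume's axes exactly once each:
axial slices sit at fixed ``z`` (shape ``ny × nx``), coronal at fixed ``y``
(``nz × nx``), sagittal at fixed ``x`` (``nz × ny``).  Every slice of every
view is resized to 128×128 and min–max normalized with the *whole-volume*
intensity extrema, so the between-slice brightness cue that marks edematous
slices survives preprocessing.  Normalized pixels are stored at half
precision; computation may run at higher precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from skimage.transform import resize

from .core import BinaryMask3D, ImageVolume

__all__ = ["PlaneView", "SliceImage", "extract_slices", "preprocess_slice",
           "preprocess_view", "slice_label", "CLASSIFIER_INPUT_SIZE"]

CLASSIFIER_INPUT_SIZE = 128


class PlaneView(str, Enum):
    """One of the three orthogonal anatomical viewing planes."""

    AXIAL = "axial"        # fixed z
    CORONAL = "coronal"    # fixed y
    SAGITTAL = "sagittal"  # fixed x

    @property
    def axis(self) -> int:
        return {"axial": 0, "coronal": 1, "sagittal": 2}[self.value]


@dataclass(frozen=True)
class SliceImage:
    """A 128×128 normalized slice with provenance for bookkeeping."""

    pixels: np.ndarray           # float16, values in [0, 1]
    patient_id: str
    view: PlaneView
    index: int

    def __post_init__(self):
        if self.pixels.shape != (CLASSIFIER_INPUT_SIZE, CLASSIFIER_INPUT_SIZE):
            raise ValueError(f"slice image must be 128×128, got {self.pixels.shape}")


def extract_slices(volume: ImageVolume, view: PlaneView) -> list[np.ndarray]:
    """All 2D slices of ``volume`` along ``view``, in ascending index order."""
    axis = view.axis
    return [np.take(volume.data, k, axis=axis) for k in range(volume.shape[axis])]


def _resize_bilinear(img: np.ndarray, size: int) -> np.ndarray:
    if img.shape == (size, size):
        return img.astype(np.float64)
    return resize(img.astype(np.float64), (size, size), order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True)


def preprocess_slice(slice2d: np.ndarray, volume_min: float, volume_max: float,
                     *, size: int = CLASSIFIER_INPUT_SIZE) -> np.ndarray:
    """Bilinear resize to ``size``², then map ``[volume_min, volume_max] → [0, 1]``.

    A constant volume (``max == min``) maps everywhere to 0.  Returns float16.
    """
    if volume_max < volume_min:
        raise ValueError("volume_max must be >= volume_min")
    out = _resize_bilinear(np.asarray(slice2d), size)
    if volume_max == volume_min:
        return np.zeros((size, size), dtype=np.float16)
    out = (out - volume_min) / (volume_max - volume_min)
    return np.clip(out, 0.0, 1.0).astype(np.float16)


def preprocess_view(volume: ImageVolume, view: PlaneView) -> np.ndarray:
    """Stack of all preprocessed slices for one view, shape ``(n, 128, 128)``.

    Normalization uses the whole-volume extrema, shared across the stack.
    """
    vmin = float(volume.data.min())
    vmax = float(volume.data.max())
    stack = [preprocess_slice(s, vmin, vmax) for s in extract_slices(volume, view)]
    return np.stack(stack, axis=0)


def slice_label(mask: BinaryMask3D, view: PlaneView, index: int) -> int:
    """1 iff the mask's 2D sub-grid at ``view``/``index`` has a positive voxel."""
    axis = view.axis
    n = mask.shape[axis]
    if not 0 <= index < n:
        raise IndexError(f"slice index {index} out of range for axis of length {n}")
    return int(np.take(mask.data, index, axis=axis).any())


def view_labels(mask: BinaryMask3D, view: PlaneView) -> np.ndarray:
    """Ground-truth labels for every slice of a view, shape ``(n,)``."""
    axes = tuple(a for a in range(3) if a != view.axis)
    return (mask.data.any(axis=axes)).astype(np.int8)
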