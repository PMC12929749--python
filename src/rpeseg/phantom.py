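"""Synthetic neck-like phantoms with ground-truth lesion masks.

Each phantom emulates the geometry of the clinical neck MRI this package
targets: 26–60 axial slices, strongly anisotropic spacing (slice gap
~4.80 ± 0.228 mm, in-plane ~0.528 ± 0.149 mm), and one contiguous
high-signal lesion occupying a tiny fraction (0.0023–0.31%) of the voxels.
The lesion is a thin anterior-midline band — tall along z, wide along x,
thin along y, the morphology of fluid in the retropharyngeal space — built
by thresholding a sum of overlapping anisotropic Gaussian blobs to a target
volume and keeping the largest 26-connected component.  The background is a
cartoon of a fat-suppressed T2 axial neck: a dark airway column, a moderate
vertebral column with a brighter canal, plus Gaussian noise.  No attempt is
made at physical MR realism (coils, bias fields, Dixon chemistry).

At the default desk scale (128² in-plane) target lesion volumes are scaled
by ``(in_plane_size / 512)²`` so the sparsity regime — the reason a
bounding-region stage exists at all — is preserved.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import BinaryMask3D, ImageVolume, write_mask, write_volume

__all__ = ["PhantomSpec", "PhantomCase", "SpecError", "generate_phantom",
           "generate_cohort", "write_cohort", "SPARSITY_BAND"]

# positive-voxel fraction band observed in the clinical cohort
SPARSITY_BAND = (2.3e-5, 3.1e-3)
# native lesion-volume range (mm³) at the clinical in-plane scale
NATIVE_VOLUME_RANGE = (234.0, 31490.0)
NATIVE_IN_PLANE = 512  # representative clinical in-plane size (288-640 px)


class SpecError(ValueError):
    """The phantom specification is infeasible for the grid geometry."""


@dataclass(frozen=True)
class PhantomSpec:
    """Sampling specification for one phantom.

    Fields left ``None`` are drawn from the cohort distributions at
    generation time: ``n_axial`` uniform on [26, 60], slice gap
    dz ~ N(4.80, 0.228) clipped to [3.98, 5.96] mm, in-plane
    dy = dx ~ N(0.528, 0.149) clipped to [0.375, 0.694] mm, and the lesion
    volume log-uniform on [234, 31490] mm³ scaled by
    ``(in_plane_size/512)²`` (with the implied voxel count kept inside the
    sparsity band).  ``lesion_volume_mm3 = 0`` produces a negative phantom.
    """

    in_plane_size: int = 128
    n_axial: int | None = None
    spacing: tuple[float, float, float] | None = None
    lesion_volume_mm3: float | None = None
    lesion_contrast: float = 2.5
    noise_sd: float = 0.05
    seed: int = 0


@dataclass(frozen=True)
class PhantomCase:
    """A generated phantom: image, truth mask, resolved spec snapshot."""

    volume: ImageVolume
    mask: BinaryMask3D
    spec: PhantomSpec          # with all sampled fields resolved
    lesion_mm3: float          # achieved (post-discretization) volume


# background intensity levels (arbitrary units; lesion level is
# lesion_contrast × _BG_MEAN and must clear the brightest structure)
_BG_BASE = 0.20
_BG_MEAN = 0.20
_AIRWAY = 0.05
_VERTEBRA = 0.35
_CANAL = 0.40

# lesion physical aspect (extent ratios y : x : z) — thin anterior-posterior,
# wide left-right, tall along the axial stack
_ASPECT = (1.0, 3.0, 4.0)


def _resolve(spec: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    n_axial = spec.n_axial
    if n_axial is None:
        n_axial = int(rng.integers(26, 61))
    spacing = spec.spacing
    if spacing is None:
        dz = float(np.clip(rng.normal(4.80, 0.228), 3.98, 5.96))
        dyx = float(np.clip(rng.normal(0.528, 0.149), 0.375, 0.694))
        spacing = (dz, dyx, dyx)
    return replace(spec, n_axial=n_axial, spacing=spacing)


def _background(shape) -> np.ndarray:
    nz, ny, nx = shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    y, x = yy / ny, xx / nx
    img = np.full((ny, nx), _BG_BASE)

    def disk(cy, cx, ry, rx):
        return ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2 <= 1.0

    img[disk(0.25, 0.5, 0.10, 0.13)] = _AIRWAY        # airway column
    img[disk(0.55, 0.5, 0.11, 0.11)] = _VERTEBRA      # vertebral body
    img[disk(0.70, 0.5, 0.035, 0.05)] = _CANAL        # canal / CSF
    img[disk(0.88, 0.5, 0.08, 0.30)] = 0.28           # paraspinal muscle slab
    # mild per-slice brightness modulation along z
    mod = 1.0 + 0.05 * np.sin(np.linspace(0, np.pi, nz))[:, None, None]
    return img[None, :, :] * mod


def _lesion_field(shape, spacing, rng: np.random.Generator,
                  target_mm3: float) -> np.ndarray:
    nz, ny, nx = shape
    dz, dy, dx = spacing
    # ellipsoid-equivalent scale t from V ≈ 2π t³ for aspect (1, 3, 4)
    t = (target_mm3 / (2.0 * np.pi)) ** (1.0 / 3.0)
    ey, ex, ez = (_ASPECT[0] * t, _ASPECT[1] * t, _ASPECT[2] * t)
    sy, sx, sz = (max(e / 2.355, 1e-3) for e in (ey, ex, ez))  # mm
    # voxel-unit sigmas
    sz_v, sy_v, sx_v = sz / dz, sy / dy, sx / dx
    z0 = nz / 2 + rng.uniform(-0.15, 0.15) * nz
    y0 = 0.40 * ny + rng.uniform(-0.02, 0.02) * ny
    x0 = 0.50 * nx + rng.uniform(-0.03, 0.03) * nx
    zz = np.arange(nz)[:, None, None]
    yy = np.arange(ny)[None, :, None]
    xx = np.arange(nx)[None, None, :]
    field = np.zeros(shape)
    for _ in range(3):
        cz = z0 + rng.normal(0, 0.6) * sz_v
        cy = y0 + rng.normal(0, 0.6) * sy_v
        cx = x0 + rng.normal(0, 0.6) * sx_v
        field += np.exp(-0.5 * (((zz - cz) / max(sz_v, 0.3)) ** 2
                                + ((yy - cy) / max(sy_v, 0.3)) ** 2
                                + ((xx - cx) / max(sx_v, 0.3)) ** 2))
    return field


def generate_phantom(spec: PhantomSpec, id: str | None = None) -> PhantomCase:
    """Generate one phantom, fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    spec = _resolve(spec, rng)
    nz, ny, nx = spec.n_axial, spec.in_plane_size, spec.in_plane_size
    shape = (nz, ny, nx)
    voxvol = float(np.prod(spec.spacing))
    total = nz * ny * nx
    area_scale = (spec.in_plane_size / NATIVE_IN_PLANE) ** 2

    target = spec.lesion_volume_mm3
    sampled = target is None
    if sampled:
        lo, hi = NATIVE_VOLUME_RANGE
        target = float(np.exp(rng.uniform(np.log(lo), np.log(hi)))) * area_scale

    if target == 0:
        mask_data = np.zeros(shape, dtype=np.uint8)
        achieved = 0.0
        spec = replace(spec, lesion_volume_mm3=0.0)
    else:
        k = int(round(target / voxvol))
        if sampled:
            # keep the implied positive fraction inside the clinical band
            # (10% interior margin against discretization)
            k_lo = int(np.ceil(SPARSITY_BAND[0] * 1.1 * total))
            k_hi = int(np.floor(SPARSITY_BAND[1] / 1.1 * total))
            k = int(np.clip(k, k_lo, k_hi))
        if k < 1 or k > 0.02 * total:
            raise SpecError(
                f"target {target:.1f} mm³ implies {k} voxels on a "
                f"{shape} grid at {voxvol:.3f} mm³/voxel — infeasible")
        target = k * voxvol
        field = _lesion_field(shape, spec.spacing, rng, target)
        flat = field.ravel()
        top = np.argpartition(flat, flat.size - k)[flat.size - k:]
        mask_data = np.zeros(total, dtype=np.uint8)
        mask_data[top] = 1
        mask_data = mask_data.reshape(shape)
        # one contiguous lesion: keep the largest 26-connected component
        labels, ncomp = ndimage.label(mask_data, structure=np.ones((3, 3, 3)))
        if ncomp > 1:
            sizes = ndimage.sum_labels(mask_data, labels, range(1, ncomp + 1))
            mask_data = (labels == (1 + int(np.argmax(sizes)))).astype(np.uint8)
        achieved = float(mask_data.sum()) * voxvol
        spec = replace(spec, lesion_volume_mm3=target)

    data = _background(shape)
    if mask_data.any():
        lesion_level = spec.lesion_contrast * _BG_MEAN
        field_in = field[mask_data.astype(bool)]
        fmin, fmax = field_in.min(), field_in.max()
        w = (0.85 + 0.30 * (field_in - fmin) / (fmax - fmin)) if fmax > fmin \
            else np.full(field_in.shape, 1.0)
        data[mask_data.astype(bool)] = lesion_level * w
    data = data + rng.normal(0.0, spec.noise_sd, size=shape)
    data = np.clip(data, 0.0, None).astype(np.float32)

    pid = id or f"phantom-{spec.seed}"
    return PhantomCase(
        volume=ImageVolume(id=pid, data=data, spacing=spec.spacing),
        mask=BinaryMask3D(data=mask_data, spacing=spec.spacing),
        spec=spec, lesion_mm3=achieved)


def generate_cohort(n: int, base_spec: PhantomSpec | None = None,
                    seed: int = 0) -> list[PhantomCase]:
    """``n`` phantoms with independently resampled geometry, reproducible
    from the master ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    base = base_spec or PhantomSpec()
    sub_seeds = np.random.SeedSequence(seed).generate_state(n)
    cases = []
    for i, s in enumerate(sub_seeds):
        spec_i = replace(base, seed=int(s))
        cases.append(generate_phantom(spec_i, id=f"case{i:03d}"))
    return cases


def write_cohort(cases: list[PhantomCase], outdir) -> Path:
    """Write paired NIfTI files plus a manifest CSV; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "dz_mm", "dy_mm", "dx_mm", "n_axial",
                    "lesion_mm3", "seed"])
        for case in cases:
            cid = case.volume.id
            write_volume(case.volume, outdir / f"{cid}_img.nii.gz")
            write_mask(case.mask, outdir / f"{cid}_mask.nii.gz")
            dz, dy, dx = case.volume.spacing
            w.writerow([cid, f"{dz:.6f}", f"{dy:.6f}", f"{dx:.6f}",
                        case.volume.shape[0], f"{case.lesion_mm3:.3f}",
                        case.spec.seed])
    return manifest
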