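"""Tile segmentation: the 64×64 U-Net per view, its soft-Dice training,
per-view 3D mask prediction, and 2.5-dimensional majority voting.

The network is a two-level encoder–decoder: paired 3×3 same-padding
convolutions at widths 16/32 with 2×2 max pooling, a width-64 bottleneck,
2×2 stride-2 transposed-convolution upsampling, skip concatenations from
both encoder levels, and a 1×1 sigmoid head — 116,753 trainable parameters
at the reference widths.  One U-Net per view is trained on 64×64 tiles with
the soft Dice loss ``1 − (2Σpq + ε)/(Σp + Σq + ε)`` and Adam (lr 0.001) for
30 epochs.

Prediction starts from a zero-initialized array the size of the patient
volume: tiles are sampled around the predicted bounding region, segmented,
reinserted (mean-fused on overlaps), un-stretched if the axial stack was
stretched, and binarized.  The fourth, "2.5D" mask is the per-voxel majority
vote of the coronal, sagittal, and axial masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn, tiling
from .core import BinaryMask3D, ImageVolume
from .localize import PositiveRegion, region_mask
from .planes import PlaneView

__all__ = [
    "REFERENCE_UNET_FILTERS", "UNetModel", "SegTrainConfig",
    "build_unet", "train_unet", "collect_view_tiles",
    "predict_view_mask", "majority_vote",
]

REFERENCE_UNET_FILTERS = (16, 32, 64)


class UNetModel:
    """Encoder–decoder with two skip concatenations, 64×64 in and out."""

    def __init__(self, filters=REFERENCE_UNET_FILTERS, seed: int = 0,
                 view: PlaneView | None = None):
        f1, f2, f3 = filters
        self.filters = tuple(filters)
        self.view = view
        rngs = iter(np.random.Generator(np.random.PCG64(s))
                    for s in np.random.SeedSequence(seed).spawn(13))
        C = _nn.Conv2D
        self.e1a = C(1, f1, 3, "same", "relu", next(rngs))
        self.e1b = C(f1, f1, 3, "same", "relu", next(rngs))
        self.pool1 = _nn.MaxPool2D()
        self.e2a = C(f1, f2, 3, "same", "relu", next(rngs))
        self.e2b = C(f2, f2, 3, "same", "relu", next(rngs))
        self.pool2 = _nn.MaxPool2D()
        self.ba = C(f2, f3, 3, "same", "relu", next(rngs))
        self.bb = C(f3, f3, 3, "same", "relu", next(rngs))
        self.up1 = _nn.ConvTranspose2D(f3, f2, next(rngs))
        self.d1a = C(2 * f2, f2, 3, "same", "relu", next(rngs))
        self.d1b = C(f2, f2, 3, "same", "relu", next(rngs))
        self.up2 = _nn.ConvTranspose2D(f2, f1, next(rngs))
        self.d2a = C(2 * f1, f1, 3, "same", "relu", next(rngs))
        self.d2b = C(f1, f1, 3, "same", "relu", next(rngs))
        self.head = C(f1, 1, 1, "valid", None, next(rngs))
        self._layers = [self.e1a, self.e1b, self.pool1, self.e2a, self.e2b,
                        self.pool2, self.ba, self.bb, self.up1, self.d1a,
                        self.d1b, self.up2, self.d2a, self.d2b, self.head]

    @property
    def params(self):
        return [p for l in self._layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self._layers for g in l.grads]

    def num_params(self) -> int:
        return int(sum(l.num_params() for l in self._layers))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits (pre-sigmoid), shape (n, 64, 64)."""
        s1 = self.e1b.forward(self.e1a.forward(x, train), train)
        h = self.pool1.forward(s1, train)
        s2 = self.e2b.forward(self.e2a.forward(h, train), train)
        h = self.pool2.forward(s2, train)
        h = self.bb.forward(self.ba.forward(h, train), train)
        h = self.up1.forward(h, train)
        h = np.concatenate([s2, h], axis=3)
        h = self.d1b.forward(self.d1a.forward(h, train), train)
        h = self.up2.forward(h, train)
        h = np.concatenate([s1, h], axis=3)
        h = self.d2b.forward(self.d2a.forward(h, train), train)
        z = self.head.forward(h, train)
        return z[:, :, :, 0]

    def backward(self, dz: np.ndarray) -> None:
        f1, f2 = self.filters[0], self.filters[1]
        d = self.head.backward(dz[:, :, :, None])
        d = self.d2a.backward(self.d2b.backward(d))
        dskip1, d = d[:, :, :, :f1], d[:, :, :, f1:]
        d = self.up2.backward(d)
        d = self.d1a.backward(self.d1b.backward(d))
        dskip2, d = d[:, :, :, :f2], d[:, :, :, f2:]
        d = self.up1.backward(d)
        d = self.ba.backward(self.bb.backward(d))
        d = self.pool2.backward(d)
        d = self.e2a.backward(self.e2b.backward(d + dskip2))
        d = self.pool1.backward(d)
        self.e1a.backward(self.e1b.backward(d + dskip1))

    def predict_tiles(self, pixels: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Per-pixel probabilities for a stack of 64×64 tiles."""
        x = np.asarray(pixels, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        out = []
        for i in range(0, len(x), batch_size):
            out.append(_nn.sigmoid(self.forward(x[i:i + batch_size, :, :, None])))
        return np.concatenate(out) if out else np.empty((0,) + x.shape[1:])


def build_unet(seed: int = 0, filters=REFERENCE_UNET_FILTERS,
               view: PlaneView | None = None) -> UNetModel:
    """Construct the segmentation U-Net, seeded (reference widths by default)."""
    return UNetModel(filters=filters, seed=seed, view=view)


@dataclass
class SegTrainConfig:
    """U-Net training settings (loss is soft Dice, optimizer Adam; fixed)."""

    learning_rate: float = 0.001
    epochs: int = 30
    batch_size: int = 16
    epsilon: float = 1.0   # soft-Dice smoothing
    seed: int = 0


def _soft_dice_loss_and_grad(p, q, eps):
    """Per-sample soft Dice loss and dloss/dp; p, q shape (n, 64, 64)."""
    num = 2.0 * (p * q).sum(axis=(1, 2)) + eps
    den = p.sum(axis=(1, 2)) + q.sum(axis=(1, 2)) + eps
    loss = 1.0 - num / den
    # d/dp of (num/den): (2 q den - num) / den²
    dp = -(2.0 * q * den[:, None, None] - num[:, None, None]) / den[:, None, None] ** 2
    return loss, dp


def train_unet(model: UNetModel, tiles: np.ndarray, truth_tiles: np.ndarray,
               config: SegTrainConfig | None = None) -> list[float]:
    """Train in place on paired image/truth tiles; returns per-epoch mean loss.

    At least one truth tile must contain positive pixels (the Dice loss is
    degenerate on an all-empty truth set).
    """
    config = config or SegTrainConfig()
    x = np.asarray(tiles, dtype=np.float32)
    q = np.asarray(truth_tiles, dtype=np.float32)
    if x.shape != q.shape or x.ndim != 3:
        raise ValueError("tiles and truth tiles must be matching (n,64,64) stacks")
    if config.epochs > 0 and q.sum() == 0:
        raise ValueError("all truth tiles are empty; Dice training is degenerate")
    rng = np.random.default_rng(config.seed)
    opt = _nn.Adam(model.params, lr=config.learning_rate)
    history: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(len(x))
        losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            xb, qb = x[idx], q[idx]
            z = model.forward(xb[:, :, :, None], train=True)
            p = _nn.sigmoid(z)
            loss, dp = _soft_dice_loss_and_grad(p, qb, config.epsilon)
            losses.append(float(loss.mean()))
            dz = (dp * p * (1.0 - p) / len(xb)).astype(np.float32)
            model.backward(dz)
            opt.step(model.grads)
        history.append(float(np.mean(losses)))
    return history


def collect_view_tiles(volume: ImageVolume, region: PositiveRegion,
                       view: PlaneView, *, mask: BinaryMask3D | None = None,
                       stride: int = tiling.TILE_STRIDE,
                       frac_min: float = 1.0 / 3.0,
                       abs_min: int = tiling.ABS_MIN_REFERENCE):
    """Sample all selection-rule tiles of one view around ``region``.

    Returns ``(tiles, truth_patches, stretched_shape, original_nz)``;
    ``truth_patches`` (64×64 binary arrays cut from the mask with identical
    provenance) is None unless ``mask`` is given.  For coronal/sagittal
    views of volumes with < 64 axial slices, sampling happens in the
    z-stretched grid and ``stretched_shape`` reflects that.
    """
    nz = volume.shape[0]
    vmin, vmax = float(volume.data.min()), float(volume.data.max())
    norm = ((volume.data - vmin) / (vmax - vmin) if vmax > vmin
            else np.zeros_like(volume.data))
    rmask = region_mask(region, volume.shape, volume.spacing).data
    factor = 1.0
    if view is not PlaneView.AXIAL and nz < tiling.TILE_SIZE:
        norm, factor = tiling.stretch_axial(norm, order=1)
        rmask, _ = tiling.stretch_axial(rmask, order=0)
        mask_data = None if mask is None else tiling.stretch_axial(mask.data, order=0)[0]
    else:
        mask_data = None if mask is None else mask.data
    shape = norm.shape
    axis = view.axis
    tiles: list[tiling.Tile] = []
    truths: list[np.ndarray] | None = None if mask is None else []
    # iterate every index along the view axis whose slice meets the region
    for idx in range(shape[axis]):
        fp = np.take(rmask, idx, axis=axis)
        if not fp.any():
            continue
        img = np.take(norm, idx, axis=axis)
        new = tiling.sample_tiles(img, fp, view, idx, stride=stride,
                                  frac_min=frac_min, abs_min=abs_min,
                                  stretch_factor=factor)
        tiles.extend(new)
        if truths is not None:
            msl = np.take(mask_data, idx, axis=axis)
            for t in new:
                truths.append(msl[t.row_off:t.row_off + tiling.TILE_SIZE,
                                  t.col_off:t.col_off + tiling.TILE_SIZE]
                              .astype(np.float32))
    return tiles, truths, shape, nz


def predict_view_mask(model: UNetModel, volume: ImageVolume,
                      region: PositiveRegion, view: PlaneView,
                      threshold: float = 0.5, *,
                      stride: int = tiling.TILE_STRIDE,
                      frac_min: float = 1.0 / 3.0,
                      abs_min: int = tiling.ABS_MIN_REFERENCE,
                      fusion: str = "mean") -> BinaryMask3D:
    """Predict one view's 3D mask around the bounding region.

    An empty region (or no qualifying tiles) yields an empty mask: the
    score map is zero-initialized and only tile footprints can raise it.
    """
    if model.view is not None and model.view != view:
        raise ValueError(f"model was trained for {model.view.value}, not {view.value}")
    if region.is_empty:
        return BinaryMask3D(np.zeros(volume.shape, dtype=np.uint8), volume.spacing)
    tiles, _, stretched_shape, nz = collect_view_tiles(
        volume, region, view, stride=stride, frac_min=frac_min, abs_min=abs_min)
    if not tiles:
        return BinaryMask3D(np.zeros(volume.shape, dtype=np.uint8), volume.spacing)
    preds = model.predict_tiles(np.stack([t.pixels for t in tiles]).astype(np.float32))
    score = tiling.reassemble(tiles, list(preds), stretched_shape, fusion=fusion)
    if stretched_shape[0] != nz:
        score = tiling.unstretch_axial(score, nz, order=1)
    return BinaryMask3D((score >= threshold).astype(np.uint8), volume.spacing)


def majority_vote(mask_cor: BinaryMask3D, mask_sag: BinaryMask3D,
                  mask_ax: BinaryMask3D) -> BinaryMask3D:
    """Per-voxel 2-of-3 vote over the three per-view masks (the 2.5D mask)."""
    mask_cor.check_congruent(mask_sag)
    mask_cor.check_congruent(mask_ax)
    votes = (mask_cor.data.astype(np.int16) + mask_sag.data + mask_ax.data)
    return BinaryMask3D((votes >= 2).astype(np.uint8), mask_cor.spacing)
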