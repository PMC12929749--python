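"""Per-view slice classification: the encoder CNN, its training loop,
moving-average smoothing of slice-score series, and Youden thresholding.

The classifier is a U-Net-style encoder — four stages of paired 3×3
convolutions (valid padding) and 2×2 max pooling — followed by four dense
layers ending in a single sigmoid unit.  At the reference widths
(16/32/64/128 convolution filters, 128/64/32/1 dense units) the network has
exactly 565,873 trainable parameters.  One such network is trained per
anatomical view on 128×128 normalized slices with binary cross-entropy and
Adam (lr 0.001) for five epochs.

Slice scores along a view form an ordered series; isolated misclassifications
are suppressed with a centered moving average before binarization at the
cutpoint maximizing Youden's J = sensitivity + specificity − 1 on the
training-set predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _nn
from .core import ImageVolume
from .planes import CLASSIFIER_INPUT_SIZE, PlaneView, preprocess_view

__all__ = [
    "REFERENCE_CONV_FILTERS", "REFERENCE_DENSE_UNITS",
    "ClassifierModel", "ClassifyTrainConfig", "SliceScoreSeries",
    "build_classifier", "train_classifier", "moving_average",
    "youden_threshold", "classify_volume",
]

REFERENCE_CONV_FILTERS = (16, 32, 64, 128)
REFERENCE_DENSE_UNITS = (128, 64, 32)


@dataclass
class ClassifyTrainConfig:
    """Training settings for the slice classifier (loss is binary
    cross-entropy, optimizer Adam; both fixed)."""

    learning_rate: float = 0.001
    epochs: int = 5
    batch_size: int = 32
    seed: int = 0


class ClassifierModel:
    """A built (possibly trained) slice classifier for one view."""

    def __init__(self, net: _nn.Sequential, view: PlaneView | None,
                 conv_filters, dense_units):
        self.net = net
        self.view = view
        self.conv_filters = tuple(conv_filters)
        self.dense_units = tuple(dense_units)

    def num_params(self) -> int:
        return self.net.num_params()

    def predict_scores(self, slices: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Sigmoid scores in (0,1) for a stack of 128×128 slices, shape (n,)."""
        x = np.asarray(slices, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        out = []
        for i in range(0, len(x), batch_size):
            z = self.net.forward(x[i:i + batch_size, :, :, None])
            out.append(_nn.sigmoid(z[:, 0]))
        return np.concatenate(out) if out else np.empty(0, dtype=np.float32)


def build_classifier(seed: int = 0,
                     conv_filters=REFERENCE_CONV_FILTERS,
                     dense_units=REFERENCE_DENSE_UNITS,
                     view: PlaneView | None = None) -> ClassifierModel:
    """Construct the encoder classifier, seeded.

    The default widths are the reference architecture (565,873 parameters);
    narrower widths may be passed for desk-scale experiments.
    """
    rngs = [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(seed).spawn(2 * len(conv_filters)
                                                        + len(dense_units) + 1)]
    it = iter(rngs)
    layers: list[_nn.Layer] = []
    cin = 1
    size = CLASSIFIER_INPUT_SIZE
    for f in conv_filters:
        layers.append(_nn.Conv2D(cin, f, 3, "valid", "relu", next(it)))
        layers.append(_nn.Conv2D(f, f, 3, "valid", "relu", next(it)))
        layers.append(_nn.MaxPool2D())
        cin = f
        size = (size - 4) // 2
    layers.append(_nn.Flatten())
    nin = size * size * cin
    for u in dense_units:
        layers.append(_nn.Dense(nin, u, "relu", next(it)))
        nin = u
    layers.append(_nn.Dense(nin, 1, None, next(it)))
    return ClassifierModel(_nn.Sequential(layers), view, conv_filters, dense_units)


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, 1e-7, 1.0 - 1e-7)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def train_classifier(model: ClassifierModel, slices: np.ndarray,
                     labels: np.ndarray,
                     config: ClassifyTrainConfig | None = None) -> list[float]:
    """Train in place; returns the per-epoch mean training BCE.

    Requires both classes in ``labels`` (a single-class set makes the
    downstream Youden threshold degenerate).  ``epochs = 0`` is a no-op.
    """
    config = config or ClassifyTrainConfig()
    x = np.asarray(slices, dtype=np.float32)
    y = np.asarray(labels, dtype=np.float32)
    if x.ndim != 3 or len(x) != len(y):
        raise ValueError("expected (n,128,128) slices with matching labels")
    if config.epochs > 0 and (y.min() == y.max()):
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(config.seed)
    opt = _nn.Adam(model.net.params, lr=config.learning_rate)
    history: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(len(x))
        losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            xb = x[idx][:, :, :, None]
            yb = y[idx]
            z = model.net.forward(xb, train=True)[:, 0]
            p = _nn.sigmoid(z)
            losses.append(_bce(p, yb))
            dz = ((p - yb) / len(yb)).astype(np.float32)
            model.net.backward(dz[:, None])
            opt.step(model.net.grads)
        history.append(float(np.mean(losses)))
    return history


def moving_average(scores, window: int = 3) -> np.ndarray:
    """Centered moving mean; the window shrinks at the series ends.

    ``window`` must be odd and ≥ 1; ``window = 1`` is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    s = np.asarray(scores, dtype=np.float64)
    if window == 1:
        return s.copy()
    n = len(s)
    h = window // 2
    csum = np.concatenate([[0.0], np.cumsum(s)])
    lo = np.maximum(np.arange(n) - h, 0)
    hi = np.minimum(np.arange(n) + h + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def youden_threshold(scores, labels) -> tuple[float, float]:
    """Cutpoint maximizing J = sensitivity + specificity − 1.

    Candidates are the midpoints between adjacent sorted unique scores plus
    one candidate below the minimum and one above the maximum; the
    classification rule is ``score >= threshold``.  Ties in J break toward
    the lowest threshold.  Returns ``(threshold, J)``.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    if len(s) != len(y) or len(s) == 0:
        raise ValueError("scores and labels must be equal-length and nonempty")
    npos = int((y == 1).sum())
    nneg = int((y == 0).sum())
    if npos == 0 or nneg == 0:
        raise ValueError("both classes must be present")
    uniq = np.unique(s)
    cands = np.concatenate([[uniq[0] - 1.0],
                            (uniq[:-1] + uniq[1:]) / 2.0,
                            [uniq[-1] + 1.0]])
    best_t, best_j = cands[0], -np.inf
    for t in cands:
        pred = s >= t
        tp = int((pred & (y == 1)).sum())
        tn = int((~pred & (y == 0)).sum())
        j = tp / npos + tn / nneg - 1.0
        if j > best_j:
            best_t, best_j = float(t), float(j)
    return best_t, best_j


@dataclass
class SliceScoreSeries:
    """Ordered per-slice classifier outputs along one view."""

    view: PlaneView
    raw: np.ndarray
    smoothed: np.ndarray
    threshold: float
    labels: np.ndarray = field(init=False)

    def __post_init__(self):
        if len(self.raw) != len(self.smoothed):
            raise ValueError("raw and smoothed series must align")
        self.labels = (np.asarray(self.smoothed) >= self.threshold).astype(np.int8)


def classify_volume(model: ClassifierModel, volume: ImageVolume,
                    view: PlaneView, threshold: float,
                    window: int = 3) -> SliceScoreSeries:
    """Score every slice of ``view``, smooth, and binarize at ``threshold``."""
    if model.view is not None and model.view != view:
        raise ValueError(f"model was trained for {model.view.value}, not {view.value}")
    stack = preprocess_view(volume, view)
    raw = model.predict_scores(stack)
    smoothed = moving_average(raw, window)
    return SliceScoreSeries(view=view, raw=raw, smoothed=smoothed,
                            threshold=threshold)
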