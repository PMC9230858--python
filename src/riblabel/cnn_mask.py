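"""CNN segmentation arm: voxel-overlap metrics, patient-level k-fold
splitting, external-mask ingestion, and a compact trainable U-net.

The rib-labeling stage accepts a ribs-only mask from *any* segmenter, so
this module's primary job is the evaluation contract: pixel-by-pixel
confusion counts between a predicted and a reference mask and the derived
Dice similarity coefficient (DSC), precision, recall, specificity and
accuracy, plus the patient-level five-fold splitting used to validate
training.  The U-net here is a small pure-NumPy encoder-decoder with skip
connections (3x3 convolutions, ReLU, 2x2 max-pooling, nearest-neighbor
up-sampling, sigmoid output) trained with Adam on binary cross-entropy,
honoring the fixed learning setup of batch size 8 and a 300-epoch cap with
early stopping.  It is sized for CPU-scale experiments, not clinical-scale
training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.model_selection import KFold

from .errors import ParameterError
from .iip_mask import RibMask
from .volume_io import BinaryVolume, WindowedVolume

# ---------------------------------------------------------------------------
# Confusion counts and segmentation metrics
# ---------------------------------------------------------------------------


@dataclass
class ConfusionCounts:
    """Voxel-wise true/false positive/negative counts (positive = rib)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ParameterError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class SegMetrics:
    """Segmentation quality; a metric whose denominator is zero is None
    (undefined), never silently 0.

    dsc = 2*TP / ((TP+FP) + (TP+FN)); precision = TP/(TP+FP);
    recall = TP/(TP+FN); specificity = TN/(TN+FP);
    accuracy = (TP+TN)/total.
    """

    dsc: Optional[float]
    precision: Optional[float]
    recall: Optional[float]
    specificity: Optional[float]
    accuracy: Optional[float]

    def to_dict(self) -> dict:
        return {"dsc": self.dsc, "precision": self.precision,
                "recall": self.recall, "specificity": self.specificity,
                "accuracy": self.accuracy}


def confusion_counts(pred: BinaryVolume, truth: BinaryVolume) -> ConfusionCounts:
    """Compare two masks voxel by voxel; a 255 voxel is a rib (positive)."""
    if pred.shape != truth.shape:
        raise ParameterError(
            f"mask geometry mismatch: {pred.shape} vs {truth.shape}")
    p = pred.foreground()
    t = truth.foreground()
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp, fp, tn, fn)


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def compute_metrics(c: ConfusionCounts) -> SegMetrics:
    return SegMetrics(
        dsc=_ratio(2 * c.tp, (c.tp + c.fp) + (c.tp + c.fn)),
        precision=_ratio(c.tp, c.tp + c.fp),
        recall=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        accuracy=_ratio(c.tp + c.tn, c.total),
    )


def kfold_split(case_ids: Sequence, k: int, seed: int = 0):
    """Deterministic patient-level k-fold partition: every case appears in
    exactly one test fold.  Returns a list of (train_ids, test_ids)."""
    case_ids = list(case_ids)
    if k < 2:
        raise ParameterError("k must be at least 2")
    if k > len(case_ids):
        raise ParameterError(f"k={k} exceeds the {len(case_ids)} cases")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [([case_ids[i] for i in train], [case_ids[i] for i in test])
            for train, test in kf.split(case_ids)]


# ---------------------------------------------------------------------------
# U-net (pure NumPy)
# ---------------------------------------------------------------------------


@dataclass
class UnetConfig:
    depth: int = 4               # encoder levels (pooling steps)
    base_filters: int = 16       # filters at the first level; doubles per level
    input_size: tuple[int, int] = (512, 512)
    batch_size: int = 8
    max_epochs: int = 300
    early_stopping_patience: int = 10
    learning_rate: float = 1e-3
    val_fraction: float = 0.2
    seed: int = 0


def _conv_forward(x, W, b):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = sliding_window_view(xp, (3, 3), axis=(2, 3))
    cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * 9)
    y = cols @ W.reshape(W.shape[0], -1).T + b
    y = y.reshape(n, h, w, -1).transpose(0, 3, 1, 2)
    return y, (cols, x.shape)


def _conv_backward(dy, cache, W):
    cols, xshape = cache
    n, c, h, w = xshape
    f = W.shape[0]
    dym = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(n * h * w, f)
    dW = (dym.T @ cols).reshape(W.shape)
    db = dym.sum(axis=0)
    dcols = (dym @ W.reshape(f, -1)).reshape(n, h, w, c, 3, 3)
    dxp = np.zeros((n, c, h + 2, w + 2))
    for di in range(3):
        for dj in range(3):
            dxp[:, :, di:di + h, dj:dj + w] += dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
    return dxp[:, :, 1:-1, 1:-1], dW, db


def _conv1x1_forward(x, W, b):
    # W: (F, C); pointwise channel mix
    y = np.einsum("nchw,fc->nfhw", x, W) + b[None, :, None, None]
    return y, x


def _conv1x1_backward(dy, x, W):
    dW = np.einsum("nfhw,nchw->fc", dy, x)
    db = dy.sum(axis=(0, 2, 3))
    dx = np.einsum("nfhw,fc->nchw", dy, W)
    return dx, dW, db


def _pool_forward(x):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
    y = xr.max(axis=(3, 5))
    mask = xr == y[:, :, :, None, :, None]
    mask = mask / mask.sum(axis=(3, 5), keepdims=True)  # split gradient on ties
    return y, mask


def _pool_backward(dy, mask):
    n, c, hh, _, ww, _ = mask.shape
    dx = mask * dy[:, :, :, None, :, None]
    return dx.reshape(n, c, hh * 2, ww * 2)


def _upsample(x):
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def _upsample_backward(dy):
    n, c, h, w = dy.shape
    return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Unet:
    """Encoder-decoder with skip connections; sigmoid pixel output."""

    def __init__(self, cfg: UnetConfig):
        h, w = cfg.input_size
        if h % (1 << cfg.depth) or w % (1 << cfg.depth):
            raise ParameterError(
                f"input size {cfg.input_size} not divisible by 2^{cfg.depth}")
        self.cfg = cfg
        self.params: dict[str, np.ndarray] = {}
        self.history: dict[str, list[float]] = {}
        rng = np.random.default_rng(cfg.seed)

        def add_conv(name, cin, cout):
            scale = np.sqrt(2.0 / (cin * 9))
            self.params[f"{name}_W"] = rng.normal(0, scale, (cout, cin, 3, 3))
            self.params[f"{name}_b"] = np.zeros(cout)

        f = lambda i: cfg.base_filters * (1 << i)  # noqa: E731
        cin = 1
        for i in range(cfg.depth):
            add_conv(f"enc{i}a", cin, f(i))
            add_conv(f"enc{i}b", f(i), f(i))
            cin = f(i)
        add_conv("bota", cin, f(cfg.depth))
        add_conv("botb", f(cfg.depth), f(cfg.depth))
        cin = f(cfg.depth)
        for i in reversed(range(cfg.depth)):
            add_conv(f"dec{i}up", cin, f(i))
            add_conv(f"dec{i}a", 2 * f(i), f(i))
            add_conv(f"dec{i}b", f(i), f(i))
            cin = f(i)
        self.params["out_W"] = rng.normal(0, np.sqrt(1.0 / cfg.base_filters),
                                          (1, cfg.base_filters))
        self.params["out_b"] = np.zeros(1)

    # -- forward ---------------------------------------------------------
    def _conv_relu(self, x, name, tape):
        y, cache = _conv_forward(x, self.params[f"{name}_W"], self.params[f"{name}_b"])
        relu_mask = y > 0
        tape.append((name, cache, relu_mask))
        return y * relu_mask

    def forward(self, x, tape=None):
        """x: (N, 1, H, W) in [0, 1]; returns logits (N, 1, H, W)."""
        record = tape if tape is not None else []
        skips, pools = [], []
        h = x
        for i in range(self.cfg.depth):
            h = self._conv_relu(h, f"enc{i}a", record)
            h = self._conv_relu(h, f"enc{i}b", record)
            skips.append(h)
            h, mask = _pool_forward(h)
            pools.append(mask)
        h = self._conv_relu(h, "bota", record)
        h = self._conv_relu(h, "botb", record)
        for i in reversed(range(self.cfg.depth)):
            h = _upsample(h)
            h = self._conv_relu(h, f"dec{i}up", record)
            h = np.concatenate([skips[i], h], axis=1)
            h = self._conv_relu(h, f"dec{i}a", record)
            h = self._conv_relu(h, f"dec{i}b", record)
        logits, out_cache = _conv1x1_forward(h, self.params["out_W"], self.params["out_b"])
        if tape is not None:
            tape.append(("__meta__", (pools, out_cache), None))
        return logits

    def backward(self, dlogits, tape):
        """Backpropagate; returns parameter gradients keyed like params."""
        grads: dict[str, np.ndarray] = {}
        name, (pools, out_cache), _ = tape.pop()
        assert name == "__meta__"
        dx, grads["out_W"], grads["out_b"] = _conv1x1_backward(
            dlogits, out_cache, self.params["out_W"])

        def back_conv(dy):
            name, cache, relu_mask = tape.pop()
            dy = dy * relu_mask
            dx, dW, db = _conv_backward(dy, cache, self.params[f"{name}_W"])
            grads[f"{name}_W"] = dW
            grads[f"{name}_b"] = db
            return dx

        f = lambda i: self.cfg.base_filters * (1 << i)  # noqa: E731
        dskips = [None] * self.cfg.depth
        for i in range(self.cfg.depth):  # decoder blocks, shallow -> deep
            dx = back_conv(dx)           # dec{i}b
            dx = back_conv(dx)           # dec{i}a
            dskips[i] = dx[:, :f(i)]
            dx = dx[:, f(i):]
            dx = back_conv(dx)           # dec{i}up
            dx = _upsample_backward(dx)
        dx = back_conv(dx)               # botb
        dx = back_conv(dx)               # bota
        for i in reversed(range(self.cfg.depth)):
            dx = _pool_backward(dx, pools[i])
            dx = dx + dskips[i]
            dx = back_conv(dx)           # enc{i}b
            dx = back_conv(dx)           # enc{i}a
        return grads

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        logits = self.forward(x)
        return 1.0 / (1.0 + np.exp(-logits))


def build_unet(cfg: UnetConfig) -> Unet:
    return Unet(cfg)


def _bce_from_logits(logits, y):
    loss = np.maximum(logits, 0) - logits * y + np.log1p(np.exp(-np.abs(logits)))
    dlogits = (1.0 / (1.0 + np.exp(-logits)) - y) / y.size
    return float(loss.mean()), dlogits


def _prepare(images: np.ndarray) -> np.ndarray:
    arr = np.asarray(images, dtype=np.float64)
    if arr.ndim != 3:
        raise ParameterError("images must be (N, H, W)")
    if arr.max(initial=0.0) > 1.5:
        arr = arr / 255.0
    return arr[:, None]


def train_unet(model: Unet, images: np.ndarray, masks: np.ndarray,
               cfg: Optional[UnetConfig] = None) -> Unet:
    """Train with Adam on binary cross-entropy.

    ``images``/``masks`` are (N, H, W) with H, W matching the model's input
    size; masks are {0, 1} or {0, 255}.  A seeded fraction of the cases is
    held out as the validation set monitored for early stopping.  The model
    is left holding the best-validation-loss parameters; per-epoch losses
    are recorded on ``model.history``.
    """
    cfg = cfg or model.cfg
    x = _prepare(images)
    y = np.asarray(masks, dtype=np.float64)[:, None]
    y = (y > 0.5 * max(1.0, y.max(initial=0.0))).astype(np.float64)
    if x.shape != y.shape:
        raise ParameterError("images and masks shapes differ")
    if x.shape[2:] != tuple(cfg.input_size):
        raise ParameterError(
            f"images are {x.shape[2:]}, config expects {tuple(cfg.input_size)}")

    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(x))
    n_val = max(1, int(round(cfg.val_fraction * len(x))))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if not len(train_idx):
        raise ParameterError("not enough images to split off a validation set")

    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(p) for k, p in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    best_val = np.inf
    best_params = {k: p.copy() for k, p in model.params.items()}
    history = {"train_loss": [], "val_loss": []}
    patience_left = cfg.early_stopping_patience

    for _epoch in range(cfg.max_epochs):
        perm = rng.permutation(train_idx)
        epoch_loss = 0.0
        for start in range(0, len(perm), cfg.batch_size):
            batch = perm[start:start + cfg.batch_size]
            tape: list = []
            logits = model.forward(x[batch], tape)
            loss, dlogits = _bce_from_logits(logits, y[batch])
            grads = model.backward(dlogits, tape)
            step += 1
            for k, g in grads.items():
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                mh = m[k] / (1 - beta1 ** step)
                vh = v[k] / (1 - beta2 ** step)
                model.params[k] -= cfg.learning_rate * mh / (np.sqrt(vh) + eps)
            epoch_loss += loss * len(batch)
        history["train_loss"].append(epoch_loss / len(perm))

        val_logits = model.forward(x[val_idx])
        val_loss, _ = _bce_from_logits(val_logits, y[val_idx])
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_params = {k: p.copy() for k, p in model.params.items()}
            patience_left = cfg.early_stopping_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break

    model.params = best_params
    model.history = history
    return model


def predict_mask(model: Unet, win: WindowedVolume) -> RibMask:
    """Segment every slice of a windowed volume into a ribs-only mask.

    Slices are edge-padded up to the nearest multiple of the model's
    pooling factor, the sigmoid output is thresholded at 0.5, and the
    padding is cropped away.
    """
    factor = 1 << model.cfg.depth
    nz, h, w = win.shape
    ph = (-h) % factor
    pw = (-w) % factor
    out = np.zeros((nz, h, w), dtype=np.uint8)
    batch = max(1, model.cfg.batch_size)
    x = win.voxels.astype(np.float64) / 255.0
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, ph), (0, pw)), mode="edge")
    for start in range(0, nz, batch):
        proba = model.predict_proba(x[start:start + batch, None])
        pred = (proba[:, 0, :h, :w] > 0.5)
        out[start:start + batch] = np.where(pred, 255, 0)
    mask = BinaryVolume(out, win.spacing)
    return RibMask(mask, detections=[],
                   removed=[{"stage": "cnn_predict", "note": "mask from U-net"}])


def mask_to_ribmask(mask: BinaryVolume) -> RibMask:
    """Ingest a precomputed rib mask from any external segmenter."""
    return RibMask(mask, detections=[],
                   removed=[{"stage": "ingest", "note": "external mask"}])
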