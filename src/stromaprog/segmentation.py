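"""Valid-convolution U-Net for 3-class H&E tile segmentation.

The network follows the classic U-shaped topology: an encoder of repeated
{two unpadded 3x3 conv + ReLU, 2x2 max-pool} levels, a two-conv bottleneck,
and a decoder of {2x stride-2 transpose conv, center-crop-and-concatenate
skip, two unpadded convs} levels, closed by a 1x1 convolution and softmax.
Because every convolution is unpadded the output is smaller than the input:
a 396-px tile with 4 pooling levels and two convolutions per block yields a
212-px prediction, and the lost 92-px border is supplied by the overlapping
tile strategy in :mod:`stromaprog.tiling`.

Training uses pixel-wise categorical cross-entropy over non-ignored pixels,
Adam, learning-rate reduction by 90% after a plateau of 3 monitoring
intervals, and early stopping after 5 intervals without improvement — with
up to 50 epochs and a batch size of 160 as the reference schedule
(desk-scale runs use smaller batches via the same configuration object).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import _nn
from ._nn import Adam, Conv1x1, Conv3x3, MaxPool2, SpatialDropout, UpConv2, center_crop
from .tiling import IGNORE


class GeometryError(ValueError):
    """Raised when a U-Net specification yields an impossible tile geometry."""


@dataclass(frozen=True)
class UNetSpec:
    """Topology of the valid-convolution U-Net."""

    depth: int = 4
    base_channels: int = 32
    kernel: int = 3
    convs_per_block: int = 2
    dropout_rate: float = 0.10
    n_classes: int = 3
    input_px: int = 396

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if self.kernel % 2 == 0 or self.kernel < 1:
            raise ValueError("kernel must be odd and positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.base_channels < 1 or self.n_classes < 2 or self.convs_per_block < 1:
            raise ValueError("invalid channel/class/conv counts")


def geometry_trace(input_px: int, spec: UNetSpec) -> dict:
    """Trace spatial sizes through the network; raise on invalid geometry.

    Returns a dict with the per-level encoder (skip) sizes, the bottleneck
    size, per-level decoder sizes after the convolutions, and the final
    output size.
    """
    shrink = spec.convs_per_block * (spec.kernel - 1)
    s = input_px
    enc_sizes: list[int] = []
    for level in range(spec.depth):
        s -= shrink
        if s <= 0:
            raise GeometryError(f"encoder level {level}: size {s} after convolutions")
        enc_sizes.append(s)
        if s % 2:
            raise GeometryError(f"encoder level {level}: odd size {s} before pooling")
        s //= 2
    s -= shrink
    if s <= 0:
        raise GeometryError(f"bottleneck: size {s} after convolutions")
    bottleneck = s
    dec_sizes: list[int] = []
    for level in reversed(range(spec.depth)):
        s *= 2
        skip = enc_sizes[level]
        if skip < s or (skip - s) % 2:
            raise GeometryError(
                f"decoder level {level}: cannot crop skip {skip} to {s}"
            )
        s -= shrink
        if s <= 0:
            raise GeometryError(f"decoder level {level}: size {s} after convolutions")
        dec_sizes.append(s)
    return {
        "encoder_sizes": enc_sizes,
        "bottleneck_size": bottleneck,
        "decoder_sizes": dec_sizes,
        "output_px": s,
    }


def output_size(input_px: int, spec: UNetSpec = UNetSpec()) -> int:
    """Spatial output size of the network for a given input size."""
    return geometry_trace(input_px, spec)["output_px"]


@dataclass(frozen=True)
class TrainConfig:
    """Training schedule (reference defaults; scale down for desk runs)."""

    batch_size: int = 160
    max_epochs: int = 50
    lr_init: float = 1e-3
    plateau_patience: int = 3
    lr_factor: float = 0.10
    early_stop_patience: int = 5
    seed: int = 0
    min_delta: float = 1e-4
    micro_batch: int = 2  # tiles per gradient-accumulation chunk (memory bound)
    class_weights: tuple | None = None  # optional per-class loss weights

    def __post_init__(self) -> None:
        if min(self.batch_size, self.max_epochs, self.plateau_patience,
               self.early_stop_patience, self.micro_batch) < 1:
            raise ValueError("schedule counts must be positive")
        if not 0 < self.lr_factor < 1:
            raise ValueError("lr_factor must lie in (0, 1)")
        if self.lr_init <= 0:
            raise ValueError("lr_init must be positive")


class PlateauSchedule:
    """Reduce-on-plateau with early stopping, monitored once per interval.

    The learning rate is multiplied by ``factor`` whenever the monitored
    loss has failed to improve (by more than ``min_delta``) for ``patience``
    consecutive intervals; training stops after ``stop_patience`` intervals
    without improvement.
    """

    def __init__(self, lr: float, factor: float, patience: int,
                 stop_patience: int, min_delta: float = 1e-4):
        self.lr = lr
        self.factor = factor
        self.patience = patience
        self.stop_patience = stop_patience
        self.min_delta = min_delta
        self.best: float | None = None
        self._plateau = 0
        self._stall = 0
        self.n_reductions = 0

    def update(self, loss: float) -> bool:
        """Record one monitored loss; returns True if training should stop."""
        if self.best is None or loss < self.best - self.min_delta:
            self.best = loss
            self._plateau = 0
            self._stall = 0
            return False
        self._plateau += 1
        self._stall += 1
        if self._plateau >= self.patience:
            self.lr *= self.factor
            self.n_reductions += 1
            self._plateau = 0
        return self._stall >= self.stop_patience


@dataclass
class EvalMetrics:
    mean_iou: float
    categorical_accuracy: float
    per_class_iou: np.ndarray
    per_class_dice: np.ndarray


def segmentation_metrics(
    preds: Iterable[np.ndarray],
    truths: Iterable[np.ndarray],
    n_classes: int = 3,
    ignore: int = IGNORE,
) -> EvalMetrics:
    """Pooled IoU / Dice per class and categorical accuracy over tiles.

    Pixels labelled ``ignore`` in the truth are excluded everywhere.  A class
    absent from both prediction and truth is excluded from the means (its
    IoU/Dice is reported as NaN).
    """
    inter = np.zeros(n_classes)
    pred_n = np.zeros(n_classes)
    true_n = np.zeros(n_classes)
    correct = 0
    total = 0
    for p, t in zip(preds, truths):
        p = np.asarray(p)
        t = np.asarray(t)
        valid = t != ignore
        pv, tv = p[valid], t[valid]
        if ((pv < 0) | (pv >= n_classes)).any():
            raise ValueError("prediction contains classes outside range")
        correct += int((pv == tv).sum())
        total += int(valid.sum())
        for k in range(n_classes):
            inter[k] += int(((pv == k) & (tv == k)).sum())
            pred_n[k] += int((pv == k).sum())
            true_n[k] += int((tv == k).sum())
    if total == 0:
        raise ValueError("no non-ignored pixels to evaluate")
    union = pred_n + true_n - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, np.nan)
        dice = np.where(pred_n + true_n > 0, 2 * inter / (pred_n + true_n), np.nan)
    return EvalMetrics(
        mean_iou=float(np.nanmean(iou)),
        categorical_accuracy=correct / total,
        per_class_iou=iou,
        per_class_dice=dice,
    )


def _to_input(rgb: np.ndarray) -> np.ndarray:
    return (np.asarray(rgb, dtype=np.float32) / 255.0 - 0.5)[None] if rgb.ndim == 3 else (
        np.asarray(rgb, dtype=np.float32) / 255.0 - 0.5
    )


class UNet:
    """Trainable valid-convolution U-Net (numpy implementation).

    Parameters are initialized deterministically from ``seed``.  Use
    :meth:`fit` to train, :meth:`predict_tile` for inference on a single
    input tile, and :meth:`evaluate` for pooled metrics over labelled tiles.
    """

    def __init__(self, spec: UNetSpec = UNetSpec(), seed: int = 0):
        if spec.kernel != 3 or spec.convs_per_block != 2:
            raise GeometryError("this implementation builds 2x valid 3x3 convs per block")
        self.spec = spec
        self.trace = geometry_trace(spec.input_px, spec)
        self.output_px = self.trace["output_px"]
        rng = np.random.default_rng(seed)
        self._drop_rng = np.random.default_rng(seed + 1)
        d, b = spec.depth, spec.base_channels

        def block(c_in, c_out):
            return [
                Conv3x3(c_in, c_out, rng),
                SpatialDropout(spec.dropout_rate, self._drop_rng),
                Conv3x3(c_out, c_out, rng),
                SpatialDropout(spec.dropout_rate, self._drop_rng),
            ]

        self.enc_blocks = []
        c_in = 3
        for level in range(d):
            c = b * 2**level
            self.enc_blocks.append(block(c_in, c))
            c_in = c
        self.pool = MaxPool2()
        self.bottleneck = block(c_in, b * 2**d)
        self.up_convs = []
        self.dec_blocks = []
        c_in = b * 2**d
        for level in reversed(range(d)):
            c = b * 2**level
            self.up_convs.append(UpConv2(c_in, c, rng))
            self.dec_blocks.append(block(2 * c, c))
            c_in = c
        self.head = Conv1x1(c_in, spec.n_classes, rng)

    # -- plumbing -----------------------------------------------------------

    def _layers(self):
        for blk in self.enc_blocks:
            yield from blk
        yield from self.bottleneck
        for up, blk in zip(self.up_convs, self.dec_blocks):
            yield up
            yield from blk
        yield self.head

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers():
            out.extend(layer.params())
        return out

    def gradients(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers():
            out.extend(layer.grads())
        return out

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits of shape (N, output_px, output_px, n_classes)."""
        if x.shape[1] != self.spec.input_px or x.shape[2] != self.spec.input_px:
            raise ValueError(
                f"expected {self.spec.input_px}-px input, got {x.shape[1:3]}"
            )
        self._skips = []
        self._pools = []
        for blk in self.enc_blocks:
            for layer in blk:
                x = layer.forward(x, training)
            self._skips.append(x)
            pool = MaxPool2()
            x = pool.forward(x, training)
            self._pools.append(pool)
        for layer in self.bottleneck:
            x = layer.forward(x, training)
        self._crop_shapes = []
        for up, blk in zip(self.up_convs, self.dec_blocks):
            x = up.forward(x, training)
            skip = self._skips[len(self._skips) - 1 - self.up_convs.index(up)]
            cropped = center_crop(skip, x.shape[1:3])
            self._crop_shapes.append((skip.shape, x.shape[1:3]))
            x = np.concatenate([cropped, x], axis=-1)
            for layer in blk:
                x = layer.forward(x, training)
        return self.head.forward(x, training)

    def predict_proba(self, rgb_tile: np.ndarray) -> np.ndarray:
        """Softmax class probabilities for one uint8 RGB tile."""
        logits = self.forward(_to_input(rgb_tile), training=False)
        return _nn.softmax(logits)[0]

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.head.backward(dlogits.astype(np.float32))
        n_dec = len(self.dec_blocks)
        skip_grads = [None] * self.spec.depth
        for i in reversed(range(n_dec)):
            for layer in reversed(self.dec_blocks[i]):
                g = layer.backward(g)
            c_skip = g.shape[-1] // 2
            g_skip, g_up = g[..., :c_skip], g[..., c_skip:]
            skip_shape, crop_hw = self._crop_shapes[i]
            full = np.zeros(skip_shape, dtype=np.float32)
            oh = (skip_shape[1] - crop_hw[0]) // 2
            ow = (skip_shape[2] - crop_hw[1]) // 2
            full[:, oh : oh + crop_hw[0], ow : ow + crop_hw[1], :] = g_skip
            skip_grads[self.spec.depth - 1 - i] = full
            g = self.up_convs[i].backward(np.ascontiguousarray(g_up))
        for layer in reversed(self.bottleneck):
            g = layer.backward(g)
        for level in reversed(range(self.spec.depth)):
            g = self._pools[level].backward(g)
            g = g + skip_grads[level]
            for layer in reversed(self.enc_blocks[level]):
                g = layer.backward(g)

    # -- training -----------------------------------------------------------

    def fit(
        self,
        tiles: Sequence[tuple[np.ndarray, np.ndarray]],
        cfg: TrainConfig = TrainConfig(),
    ) -> pd.DataFrame:
        """Train on (rgb input tile, label tile) pairs; returns the history.

        Labels are ``output_px`` squared with the ignore sentinel outside the
        ROI; the loss is averaged over non-ignored pixels only.  Batches of
        ``cfg.batch_size`` tiles are processed in gradient-accumulation
        chunks of ``cfg.micro_batch`` tiles.  The monitored quantity for the
        plateau/early-stop schedule is the mean training loss per epoch.
        """
        if len(tiles) == 0:
            raise ValueError("empty training set")
        order_rng = np.random.default_rng(cfg.seed)
        self._drop_rng = np.random.default_rng(cfg.seed + 1)
        for blk in self.enc_blocks + [self.bottleneck] + self.dec_blocks:
            for layer in blk:
                if isinstance(layer, SpatialDropout):
                    layer.rng = self._drop_rng
        params = self.parameters()
        opt = Adam(params, cfg.lr_init)
        sched = PlateauSchedule(
            cfg.lr_init, cfg.lr_factor, cfg.plateau_patience,
            cfg.early_stop_patience, cfg.min_delta,
        )
        cw = None if cfg.class_weights is None else np.asarray(cfg.class_weights, float)
        history = []
        n = len(tiles)
        for epoch in range(cfg.max_epochs):
            order = order_rng.permutation(n)
            tot_loss = 0.0
            tot_pix = 0
            tot_correct = 0
            for b0 in range(0, n, cfg.batch_size):
                batch = order[b0 : b0 + cfg.batch_size]
                accum = [np.zeros_like(p) for p in params]
                batch_pix = 0
                any_grad = False
                for m0 in range(0, len(batch), cfg.micro_batch):
                    idx = batch[m0 : m0 + cfg.micro_batch]
                    x = np.stack([
                        np.asarray(tiles[i][0], dtype=np.float32) / 255.0 - 0.5
                        for i in idx
                    ])
                    y = np.stack([tiles[i][1] for i in idx])
                    logits = self.forward(x, training=True)
                    loss, dlogits, n_valid = _nn.cross_entropy_ignore(
                        logits, y, class_weights=cw
                    )
                    if n_valid == 0:
                        import warnings

                        warnings.warn("batch with all pixels ignored; skipped")
                        continue
                    pred = logits.argmax(axis=-1)
                    tot_correct += int(((pred == y) & (y != IGNORE)).sum())
                    tot_loss += loss * n_valid
                    tot_pix += n_valid
                    batch_pix += n_valid
                    self.backward(dlogits)
                    for a, gr in zip(accum, self.gradients()):
                        a += gr * n_valid
                    any_grad = True
                if any_grad:
                    opt.lr = sched.lr
                    opt.step([a / batch_pix for a in accum])
            epoch_loss = tot_loss / max(tot_pix, 1)
            history.append(
                {
                    "epoch": epoch,
                    "loss": epoch_loss,
                    "categorical_accuracy": tot_correct / max(tot_pix, 1),
                    "lr": sched.lr,
                }
            )
            if sched.update(epoch_loss):
                break
        self.history_ = pd.DataFrame(history)
        return self.history_

    # -- inference ----------------------------------------------------------

    def predict_tile(self, rgb_tile: np.ndarray) -> np.ndarray:
        """Argmax class mask (output_px squared, uint8) for one input tile.

        Ties in the softmax break toward the lower class index.
        """
        rgb_tile = np.asarray(rgb_tile)
        if rgb_tile.shape[:2] != (self.spec.input_px, self.spec.input_px):
            raise ValueError(
                f"expected {self.spec.input_px}x{self.spec.input_px} tile, "
                f"got {rgb_tile.shape[:2]}"
            )
        return self.predict_proba(rgb_tile).argmax(axis=-1).astype(np.uint8)

    def evaluate(
        self, tiles: Sequence[tuple[np.ndarray, np.ndarray]]
    ) -> EvalMetrics:
        """Pooled IoU/Dice and categorical accuracy over labelled tiles."""
        if len(tiles) == 0:
            raise ValueError("need at least one labelled tile")
        preds = (self.predict_tile(rgb) for rgb, _ in tiles)
        truths = (lab for _, lab in tiles)
        return segmentation_metrics(preds, truths, self.spec.n_classes)

    # -- persistence --------------------------------------------------------

    def save(self, path: str) -> None:
        import json

        arrays = {f"p{i}": p for i, p in enumerate(self.parameters())}
        np.savez(path, **arrays)
        with open(str(path) + ".json", "w") as fh:
            json.dump(self.spec.__dict__, fh)

    @classmethod
    def load(cls, path: str) -> "UNet":
        import json

        with open(str(path) + ".json") as fh:
            spec = UNetSpec(**json.load(fh))
        model = cls(spec)
        data = np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz")
        for i, p in enumerate(model.parameters()):
            p[...] = data[f"p{i}"]
        return model


def build_model(spec: UNetSpec = UNetSpec(), seed: int = 0) -> UNet:
    """Construct a U-Net with deterministic initialization."""
    return UNet(spec, seed)
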