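"""Small convolutional tile classifier, trained with early stopping.

A binary CNN distinguishes informative from empty pre-scan tiles.  The
network is a stack of (3x3 convolution, ReLU, 2x2 max-pool) blocks —
each block halving the spatial size — followed by global average
pooling and a single sigmoid output giving the probability that a tile
is informative.  Training follows the protocol used for the triage
network: balanced dataset, 80/20 train/validation split, batch size 32,
adaptive-moment (Adam) optimisation of the binary cross-entropy, early
stopping on validation accuracy with a patience of 10 epochs,
checkpoints at every validation improvement and a per-epoch CSV log.

The implementation is pure NumPy (im2col convolutions); the network is
small enough that the full 2 x 2,080-tile protocol trains in minutes on
one CPU core.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from skimage.transform import resize as _resize

from .phantoms import TileDataset
from .triage import TriageResult

__all__ = [
    "ClassifierConfig",
    "ConvNet",
    "TrainResult",
    "build_classifier",
    "train_classifier",
    "predict",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Architecture and training hyper-parameters.

    Defaults: four conv blocks with 8/16/32/64 filters on a 64x64
    input (8x8 feature map before global pooling), Adam at 1e-3,
    batch 32, 80/20 split, early-stop patience 10 epochs.
    """

    n_blocks: int = 4
    filters: tuple[int, ...] = (8, 16, 32, 64)
    input_size: int = 64
    batch_size: int = 32
    train_fraction: float = 0.8
    patience_epochs: int = 10
    max_epochs: int = 40
    learning_rate: float = 1e-3
    probability_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("need at least one conv block")
        if len(self.filters) != self.n_blocks:
            raise ValueError("one filter count per block required")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train fraction must be in (0, 1)")
        if not (0 <= self.probability_threshold <= 1):
            raise ValueError("probability threshold must be in [0, 1]")
        if self.batch_size < 1 or self.patience_epochs < 1 or self.max_epochs < 1:
            raise ValueError("batch size, patience and max epochs must be >= 1")


def _he_init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class ConvNet:
    """Plain-NumPy CNN: conv/ReLU/max-pool blocks, GAP, sigmoid head."""

    def __init__(self, config: ClassifierConfig, input_shape: tuple[int, int],
                 seed: int = 0):
        h, w = input_shape
        if h % (2**config.n_blocks) or w % (2**config.n_blocks):
            raise ValueError(
                f"input {input_shape} not divisible by 2^{config.n_blocks}"
            )
        self.config = config
        self.input_shape = (int(h), int(w))
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        c_in = 1
        for f in config.filters:
            self.weights.append(_he_init(rng, c_in * 9, (c_in * 9, f)))
            self.biases.append(np.zeros(f, dtype=np.float32))
            c_in = f
        self.head_w = _he_init(rng, c_in, (c_in, 1))
        self.head_b = np.zeros(1, dtype=np.float32)
        # normalisation fitted on training data: (low, high) percentiles
        self.norm: tuple[float, float] = (0.0, 1.0)
        self._adam_state = None

    # --- parameter bookkeeping ------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        return [*self.weights, *self.biases, self.head_w, self.head_b]

    def set_parameters(self, params: list[np.ndarray]) -> None:
        nb = self.config.n_blocks
        self.weights = [p.copy() for p in params[:nb]]
        self.biases = [p.copy() for p in params[nb : 2 * nb]]
        self.head_w = params[2 * nb].copy()
        self.head_b = params[2 * nb + 1].copy()

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # --- forward / backward ---------------------------------------------

    @staticmethod
    def _im2col(x: np.ndarray) -> np.ndarray:
        """(N, C, H, W) -> (N*H*W, C*9) patches of the 1-padded input."""
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
        # win: (N, C, H, W, 3, 3) -> (N, H, W, C, 3, 3)
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * 9
        )

    def _forward(self, x: np.ndarray, want_cache: bool = False):
        cache = []
        for wgt, b in zip(self.weights, self.biases):
            n, c, h, w = x.shape
            f = wgt.shape[1]
            cols = self._im2col(x)
            conv = (cols @ wgt + b).reshape(n, h, w, f).transpose(0, 3, 1, 2)
            relu = np.maximum(conv, 0.0)
            # 2x2 max pool, stride 2
            h2, w2 = h // 2, w // 2
            rr = relu.reshape(n, f, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5)
            rr = np.ascontiguousarray(rr).reshape(n, f, h2, w2, 4)
            amax = rr.argmax(axis=-1)
            pooled = np.take_along_axis(rr, amax[..., None], axis=-1)[..., 0]
            if want_cache:
                cache.append((cols, conv, amax, (n, c, h, w, f)))
            x = pooled
        feat = x.mean(axis=(2, 3))  # global average pool -> (N, F_last)
        logits = feat @ self.head_w + self.head_b
        if want_cache:
            return logits[:, 0], (cache, feat, x.shape)
        return logits[:, 0]

    def _backward(self, dlogits: np.ndarray, cache):
        blocks, feat, last_shape = cache
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        d_head_w = feat.T @ dlogits[:, None]
        d_head_b = dlogits.sum(keepdims=True)
        dfeat = dlogits[:, None] @ self.head_w.T  # (N, F_last)
        n, f, h2, w2 = last_shape
        dx = np.broadcast_to(
            dfeat[:, :, None, None] / (h2 * w2), (n, f, h2, w2)
        ).astype(np.float32)

        for i in range(len(self.weights) - 1, -1, -1):
            cols, conv, amax, (n, c, h, w, f) = blocks[i]
            h2, w2 = h // 2, w // 2
            # un-pool: route gradient to the argmax corner of each 2x2 cell
            drr = np.zeros((n, f, h2, w2, 4), dtype=np.float32)
            np.put_along_axis(drr, amax[..., None], dx[..., None], axis=-1)
            drelu = (
                drr.reshape(n, f, h2, w2, 2, 2)
                .transpose(0, 1, 2, 4, 3, 5)
                .reshape(n, f, h, w)
            )
            dconv = np.where(conv > 0, drelu, 0.0)
            dy = dconv.transpose(0, 2, 3, 1).reshape(n * h * w, f)
            grads_w[i] = cols.T @ dy
            grads_b[i] = dy.sum(axis=0)
            if i > 0:
                # dx = correlation of dy with spatially flipped kernels
                wgt = self.weights[i].reshape(c, 3, 3, f)
                wflip = wgt[:, ::-1, ::-1, :].transpose(3, 1, 2, 0).reshape(f * 9, c)
                dyc = self._im2col(dconv)
                dx = (dyc @ wflip).reshape(n, h, w, c).transpose(0, 3, 1, 2)
        return [*grads_w, *grads_b, d_head_w, d_head_b]

    def _adam_step(self, grads, lr):
        if self._adam_state is None:
            self._adam_state = {
                "m": [np.zeros_like(p) for p in self.parameters()],
                "v": [np.zeros_like(p) for p in self.parameters()],
                "t": 0,
            }
        st = self._adam_state
        st["t"] += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        params = self.parameters()
        for p, g, m, v in zip(params, grads, st["m"], st["v"]):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mh = m / (1 - b1 ** st["t"])
            vh = v / (1 - b2 ** st["t"])
            p -= (lr * mh / (np.sqrt(vh) + eps)).astype(p.dtype)

    # --- user-facing inference ------------------------------------------

    def preprocess(self, tiles) -> np.ndarray:
        """Tiles (2D MIPs or 3D stacks) -> normalised (N, 1, H, W) float32."""
        lo, hi = self.norm
        out = np.empty((len(tiles), 1, *self.input_shape), dtype=np.float32)
        for i, t in enumerate(tiles):
            t = np.asarray(t, dtype=np.float32)
            if t.ndim == 3:
                t = t.max(axis=0)
            if t.ndim != 2:
                raise ValueError("each tile must be a 2D MIP or 3D stack")
            if t.shape != self.input_shape:
                t = _resize(t, self.input_shape, preserve_range=True,
                            anti_aliasing=True).astype(np.float32)
            out[i, 0] = t
        out -= lo
        out /= max(hi - lo, 1e-6)
        np.clip(out, 0.0, 1.0, out=out)
        return out

    def predict_proba(self, tiles, batch_size: int = 256) -> np.ndarray:
        """Probability of 'informative' per tile, clipped inside (0, 1)."""
        x = self.preprocess(tiles)
        probs = np.empty(len(x))
        for s in range(0, len(x), batch_size):
            z = self._forward(x[s : s + batch_size]).astype(np.float64)
            probs[s : s + len(z)] = 1.0 / (1.0 + np.exp(-z))
        return np.clip(probs, 1e-7, 1.0 - 1e-7)

    # --- serialization ---------------------------------------------------

    def save(self, path) -> None:
        arrays = {f"w{i}": w for i, w in enumerate(self.weights)}
        arrays |= {f"b{i}": b for i, b in enumerate(self.biases)}
        np.savez(
            path,
            head_w=self.head_w,
            head_b=self.head_b,
            norm=np.asarray(self.norm),
            filters=np.asarray(self.config.filters),
            input_shape=np.asarray(self.input_shape),
            **arrays,
        )

    @classmethod
    def load(cls, path, config: ClassifierConfig | None = None) -> "ConvNet":
        with np.load(path) as data:
            filters = tuple(int(f) for f in data["filters"])
            cfg = config or ClassifierConfig(n_blocks=len(filters), filters=filters,
                                             input_size=int(data["input_shape"][0]))
            net = cls(cfg, tuple(int(v) for v in data["input_shape"]))
            net.weights = [data[f"w{i}"] for i in range(len(filters))]
            net.biases = [data[f"b{i}"] for i in range(len(filters))]
            net.head_w = data["head_w"]
            net.head_b = data["head_b"]
            net.norm = (float(data["norm"][0]), float(data["norm"][1]))
        return net


def build_classifier(
    config: ClassifierConfig = ClassifierConfig(),
    input_shape: tuple[int, int] | None = None,
    seed: int = 0,
) -> ConvNet:
    """Untrained classifier; input must be divisible by 2**n_blocks."""
    shape = input_shape or (config.input_size, config.input_size)
    return ConvNet(config, shape, seed=seed)


@dataclass
class TrainResult:
    model: ConvNet
    log: "object"  # pandas DataFrame: one row per epoch
    best_val_accuracy: float
    best_epoch: int
    train_indices: np.ndarray
    val_indices: np.ndarray
    checkpoints: list[Path] = field(default_factory=list)


def train_classifier(
    dataset: TileDataset,
    config: ClassifierConfig = ClassifierConfig(),
    seed: int = 0,
    checkpoint_dir=None,
    log_path=None,
) -> TrainResult:
    """Train with a deterministic 80/20 split and early stopping.

    Stops once validation accuracy has not improved for
    ``config.patience_epochs`` epochs (or at ``max_epochs``); the
    checkpoint with the best validation accuracy is returned.  The CSV
    log has one row per epoch: epoch, train loss, train accuracy,
    validation loss, validation accuracy.
    """
    import pandas as pd

    labels = np.asarray(dataset.labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("dataset must contain both classes")

    rng = np.random.default_rng(seed)
    n = len(dataset)
    order = rng.permutation(n)
    n_train = int(round(config.train_fraction * n))
    train_idx, val_idx = order[:n_train], order[n_train:]

    model = build_classifier(config, seed=seed)
    # fit intensity normalisation on the training tiles (1st/99th pct)
    sample = np.concatenate(
        [np.asarray(dataset.tiles[i], dtype=np.float32).ravel() for i in train_idx[:256]]
    )
    model.norm = (float(np.percentile(sample, 1)), float(np.percentile(sample, 99)))

    x_train = model.preprocess([dataset.tiles[i] for i in train_idx])
    y_train = labels[train_idx].astype(np.float32)
    x_val = model.preprocess([dataset.tiles[i] for i in val_idx])
    y_val = labels[val_idx].astype(np.float32)

    def _eval(x, y) -> tuple[float, float]:
        losses, correct = [], 0
        for s in range(0, len(x), 512):
            z = model._forward(x[s : s + 512]).astype(np.float64)
            yy = y[s : s + 512]
            losses.append(np.sum(np.logaddexp(0.0, z) - yy * z))
            correct += int(np.sum((z > 0) == (yy > 0.5)))
        return float(np.sum(losses) / len(x)), correct / len(x)

    best_acc, best_epoch = -1.0, -1
    best_params = None
    since_best = 0
    checkpoints: list[Path] = []
    rows = []
    for epoch in range(config.max_epochs):
        perm = rng.permutation(len(x_train))
        ep_loss, ep_correct = 0.0, 0
        for s in range(0, len(perm), config.batch_size):
            idx = perm[s : s + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            z, cache = model._forward(xb, want_cache=True)
            z64 = z.astype(np.float64)
            ep_loss += float(np.sum(np.logaddexp(0.0, z64) - yb * z64))
            ep_correct += int(np.sum((z64 > 0) == (yb > 0.5)))
            p = 1.0 / (1.0 + np.exp(-z64))
            dlogits = ((p - yb) / len(idx)).astype(np.float32)
            grads = model._backward(dlogits, cache)
            model._adam_step(grads, config.learning_rate)
        val_loss, val_acc = _eval(x_val, y_val)
        rows.append(
            {
                "epoch": epoch,
                "train_loss": ep_loss / len(x_train),
                "train_accuracy": ep_correct / len(x_train),
                "val_loss": val_loss,
                "val_accuracy": val_acc,
            }
        )
        if val_acc > best_acc:
            best_acc, best_epoch = val_acc, epoch
            best_params = [p.copy() for p in model.parameters()]
            since_best = 0
            if checkpoint_dir is not None:
                ckpt = Path(checkpoint_dir) / f"epoch{epoch:03d}_valacc{val_acc:.4f}.npz"
                model.save(ckpt)
                checkpoints.append(ckpt)
        else:
            since_best += 1
            if since_best >= config.patience_epochs:
                break

    model.set_parameters(best_params)
    log = pd.DataFrame(rows)
    if log_path is not None:
        log.to_csv(log_path, index=False)
    return TrainResult(
        model=model,
        log=log,
        best_val_accuracy=best_acc,
        best_epoch=best_epoch,
        train_indices=train_idx,
        val_indices=val_idx,
        checkpoints=checkpoints,
    )


def predict(
    model: ConvNet,
    tiles,
    probability_threshold: float = 0.5,
) -> list[TriageResult]:
    """Per-tile informative probability, labelled by threshold.

    Convention: informative iff probability >= threshold, with
    probabilities clipped strictly inside (0, 1); hence threshold 0
    selects everything and threshold 1 nothing.
    """
    probs = model.predict_proba(tiles)
    return [
        TriageResult(
            tile_id=i,
            score=float(p),
            label="informative" if p >= probability_threshold else "non-informative",
        )
        for i, p in enumerate(probs)
    ]
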