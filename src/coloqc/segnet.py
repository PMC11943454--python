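"""Compact encoder-decoder semantic segmentation network.

The model maps an RGB colonoscopy frame to a four-class label map (mucosa,
residue, artifact, lumen) with no reject option: every pixel receives a
class, which is what makes it preferable to the rule-based cube classifier
that leaves color nuances it has never seen unclassified.

Architecture (minimal encoder-decoder): two stride-2 convolution blocks
(3x3 convolution, batch normalization, ReLU) with channel doubling halve
the spatial resolution twice; a mirrored decoder restores it with two
nearest-neighbour x2 upsamplings, each followed by the same conv-BN-ReLU
block; a final 1x1 projection produces the four per-pixel class scores.
Input dimensions must be divisible by 4 so the two halvings invert exactly.

Training minimises pixel-wise softmax cross-entropy over the four classes.
Gray level 0 in the training labels (unannotated background) is excluded
from the loss, so the network learns to extend the annotated "clouds of
pixels" into a total labeling.  Inputs are "zerocenter"-normalised by
subtracting the per-channel mean of the training frames.  Optimisation is
plain SGD with momentum 0.9 under a staged learning-rate schedule
(50 epochs at 1e-3, 50 at 7e-4, 50 at 4.9e-4 by default), mini-batches of
48 frames, order reshuffled every epoch.  Everything is implemented with
numpy (im2col convolutions); given a seed, training is bit-reproducible on
one platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotator import GRAY_CODE
from .color_features import RegionClass

DEFAULT_SCHEDULE = ((50, 1e-3), (50, 7e-4), (50, 4.9e-4))


@dataclass
class SegNetConfig:
    input_height: int = 576
    input_width: int = 720
    base_channels: int = 32
    n_classes: int = 4
    batch_size: int = 48
    schedule: tuple = DEFAULT_SCHEDULE
    momentum: float = 0.9
    shuffle_each_epoch: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes != 4:
            raise ValueError("the model emits exactly the four regions of interest")
        if self.input_height % 4 or self.input_width % 4:
            raise ValueError(
                "input dimensions must be divisible by 4 (two exact halvings)"
            )
        self.schedule = tuple((int(e), float(lr)) for e, lr in self.schedule)
        if any(e <= 0 or lr <= 0 for e, lr in self.schedule):
            raise ValueError("schedule stages need positive epochs and rates")


@dataclass
class TrainReport:
    """Per-epoch history of mini-batch loss/accuracy plus final values."""

    history: list = field(default_factory=list)  # dicts: stage, epoch, lr, loss, accuracy
    final_loss: float = float("nan")
    final_accuracy: float = float("nan")


def param_count(cfg: SegNetConfig) -> int:
    """Number of trainable parameters (weights, biases, BN scales) for a config."""
    c = cfg.base_channels
    n = 0
    n += 9 * 3 * c + c + 2 * c            # enc1: 3x3, 3 -> C, + BN gamma/beta
    n += 9 * c * 2 * c + 2 * c + 4 * c    # enc2: 3x3, C -> 2C, + BN
    n += 9 * 2 * c * c + c + 2 * c        # dec1: 3x3, 2C -> C, + BN
    n += 9 * c * c + c + 2 * c            # dec2: 3x3, C -> C, + BN
    n += c * cfg.n_classes + cfg.n_classes  # 1x1 head
    return n


# ---------------------------------------------------------------- primitives


def _conv3x3_fwd(x, W, b, stride):
    N, H, Wd, C = x.shape
    Ho, Wo = H // stride, Wd // stride
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    cols = np.empty((N, Ho, Wo, 3, 3, C), dtype=x.dtype)
    for ki in range(3):
        for kj in range(3):
            cols[:, :, :, ki, kj, :] = xp[
                :, ki : ki + stride * Ho : stride, kj : kj + stride * Wo : stride, :
            ]
    Co = W.shape[-1]
    out = cols.reshape(-1, 9 * C) @ W.reshape(9 * C, Co) + b
    return out.reshape(N, Ho, Wo, Co), cols


def _conv3x3_bwd(dout, cols, W, x_shape, stride):
    N, H, Wd, C = x_shape
    _, Ho, Wo, Co = dout.shape
    flat = dout.reshape(-1, Co)
    dW = (cols.reshape(-1, 9 * C).T @ flat).reshape(W.shape)
    db = flat.sum(axis=0)
    dcols = (flat @ W.reshape(9 * C, Co).T).reshape(N, Ho, Wo, 3, 3, C)
    dxp = np.zeros((N, H + 2, Wd + 2, C), dtype=dout.dtype)
    for ki in range(3):
        for kj in range(3):
            dxp[
                :, ki : ki + stride * Ho : stride, kj : kj + stride * Wo : stride, :
            ] += dcols[:, :, :, ki, kj, :]
    return dxp[:, 1:-1, 1:-1, :], dW, db


_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


def _bn_fwd(x, gamma, beta, running_mean, running_var, train):
    """Per-channel batch normalization over (N, H, W)."""
    if train:
        mu = x.mean(axis=(0, 1, 2))
        var = x.var(axis=(0, 1, 2))
        running_mean *= 1.0 - _BN_MOMENTUM
        running_mean += _BN_MOMENTUM * mu
        running_var *= 1.0 - _BN_MOMENTUM
        running_var += _BN_MOMENTUM * var
    else:
        mu, var = running_mean, running_var
    inv = (1.0 / np.sqrt(var + _BN_EPS)).astype(x.dtype)
    xhat = (x - mu) * inv
    return gamma * xhat + beta, (xhat, inv, gamma)


def _bn_bwd(dout, cache):
    xhat, inv, gamma = cache
    dgamma = (dout * xhat).sum(axis=(0, 1, 2))
    dbeta = dout.sum(axis=(0, 1, 2))
    dxhat = dout * gamma
    dx = inv * (
        dxhat
        - dxhat.mean(axis=(0, 1, 2))
        - xhat * (dxhat * xhat).mean(axis=(0, 1, 2))
    )
    return dx.astype(dout.dtype), dgamma, dbeta


def _upsample2(x):
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def _upsample2_bwd(d):
    N, H2, W2, C = d.shape
    return d.reshape(N, H2 // 2, 2, W2 // 2, 2, C).sum(axis=(2, 4))


def _softmax_ce(logits, labels):
    """Cross-entropy over the last axis; ``labels < 0`` are ignored."""
    m = logits.max(axis=-1, keepdims=True)
    e = np.exp(logits - m)
    p = e / e.sum(axis=-1, keepdims=True)
    valid = labels >= 0
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("batch contains no annotated pixels")
    vi = np.nonzero(valid)
    y = labels[valid]
    loss = float(-np.log(p[vi + (y,)] + 1e-12).mean())
    acc = float((np.argmax(logits, axis=-1)[valid] == y).mean())
    dlogits = p
    dlogits[vi + (y,)] -= 1.0
    dlogits[~valid] = 0.0
    dlogits /= n_valid
    return loss, acc, dlogits


_GRAY_TO_INDEX = {GRAY_CODE[c]: int(c) for c in (
    RegionClass.MUCOSA, RegionClass.RESIDUE, RegionClass.ARTIFACT, RegionClass.LUMEN
)}


def labels_from_gray(gray: np.ndarray) -> np.ndarray:
    """Map grayscale training labels to class indices; background 0 -> -1."""
    arr = np.asarray(gray)
    out = np.full(arr.shape, -2, dtype=np.int64)
    out[arr == 0] = -1
    for g, idx in _GRAY_TO_INDEX.items():
        out[arr == g] = idx
    if (out == -2).any():
        bad = int(arr[out == -2].flat[0])
        raise ValueError(f"gray level {bad} is outside the label code table")
    return out


# --------------------------------------------------------------------- model


class SegNet:
    """The encoder-decoder model; see the module docstring for the layout."""

    _PARAMS = (
        "W1", "b1", "g1", "e1",
        "W2", "b2", "g2", "e2",
        "W3", "b3", "g3", "e3",
        "W4", "b4", "g4", "e4",
        "W5", "b5",
    )
    _BUFFERS = ("rm1", "rv1", "rm2", "rv2", "rm3", "rv3", "rm4", "rv4")

    def __init__(self, cfg: SegNetConfig):
        self.cfg = cfg
        c = cfg.base_channels
        rng = np.random.default_rng(cfg.seed)

        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(
                np.float32
            )

        widths = {1: c, 2: 2 * c, 3: c, 4: c}
        self.params = {
            "W1": he((3, 3, 3, c), 9 * 3),
            "W2": he((3, 3, c, 2 * c), 9 * c),
            "W3": he((3, 3, 2 * c, c), 9 * 2 * c),
            "W4": he((3, 3, c, c), 9 * c),
            "W5": he((c, cfg.n_classes), c),
            "b5": np.zeros(cfg.n_classes, np.float32),
        }
        self.buffers = {}
        for i, w in widths.items():
            self.params[f"b{i}"] = np.zeros(w, np.float32)
            self.params[f"g{i}"] = np.ones(w, np.float32)   # BN gamma
            self.params[f"e{i}"] = np.zeros(w, np.float32)  # BN beta
            self.buffers[f"rm{i}"] = np.zeros(w, np.float32)
            self.buffers[f"rv{i}"] = np.ones(w, np.float32)
        self.channel_means = np.zeros(3, np.float32)  # zerocenter statistics
        self.channel_scale = np.full(3, 255.0, np.float32)

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())

    def _block(self, x, i, stride, train, cache):
        """conv-BN-ReLU block ``i``; records intermediates when training."""
        p, buf = self.params, self.buffers
        a, cols = _conv3x3_fwd(x, p[f"W{i}"], p[f"b{i}"], stride)
        bn, bn_cache = _bn_fwd(
            a, p[f"g{i}"], p[f"e{i}"], buf[f"rm{i}"], buf[f"rv{i}"], train
        )
        r = np.maximum(bn, 0)
        if cache is not None:
            cache[f"in{i}"] = x
            cache[f"cols{i}"] = cols
            cache[f"bn{i}"] = bn_cache
            cache[f"r{i}"] = r
        return r

    def forward(self, x: np.ndarray, want_cache: bool = False, train: bool = False):
        """Compute per-pixel class logits for a float32 NHWC batch."""
        p = self.params
        cache: dict | None = {"x": x} if want_cache else None
        r1 = self._block(x, 1, 2, train, cache)
        r2 = self._block(r1, 2, 2, train, cache)
        r3 = self._block(_upsample2(r2), 3, 1, train, cache)
        r4 = self._block(_upsample2(r3), 4, 1, train, cache)
        logits = r4 @ p["W5"] + p["b5"]
        if not want_cache:
            return logits
        return logits, cache

    def _block_bwd(self, dr, i, stride, cache, grads):
        p = self.params
        dbn = dr * (cache[f"r{i}"] > 0)
        da, grads[f"g{i}"], grads[f"e{i}"] = _bn_bwd(dbn, cache[f"bn{i}"])
        dx, grads[f"W{i}"], grads[f"b{i}"] = _conv3x3_bwd(
            da, cache[f"cols{i}"], p[f"W{i}"], cache[f"in{i}"].shape, stride
        )
        return dx

    def _backward(self, dlogits, cache):
        p, g = self.params, {}
        r4 = cache["r4"]
        g["W5"] = r4.reshape(-1, r4.shape[-1]).T @ dlogits.reshape(-1, dlogits.shape[-1])
        g["b5"] = dlogits.sum(axis=(0, 1, 2))
        dr4 = dlogits @ p["W5"].T
        du2 = self._block_bwd(dr4, 4, 1, cache, g)
        du1 = self._block_bwd(_upsample2_bwd(du2), 3, 1, cache, g)
        dr1 = self._block_bwd(_upsample2_bwd(du1), 2, 2, cache, g)
        self._block_bwd(dr1, 1, 2, cache, g)
        return g

    # ------------------------------------------------------------- inference

    def _prepare(self, frames: np.ndarray) -> np.ndarray:
        x = np.asarray(frames, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1] != self.cfg.input_height or x.shape[2] != self.cfg.input_width:
            raise ValueError(
                f"frame size {x.shape[1]}x{x.shape[2]} does not match the model "
                f"input {self.cfg.input_height}x{self.cfg.input_width}"
            )
        # zero-center by the training means (stored in pixel units), then
        # rescale to unit variance so He-initialised layers are well
        # conditioned under the staged learning rates
        return (x - self.channel_means) / self.channel_scale

    def predict(self, frame: np.ndarray) -> np.ndarray:
        """Arg-max labeling of one RGB frame; every pixel gets one of the
        four regions — UNCLASSIFIED never occurs."""
        logits = self.forward(self._prepare(frame))
        return np.argmax(logits[0], axis=-1).astype(np.uint8)

    def predict_batch(self, frames: np.ndarray) -> np.ndarray:
        logits = self.forward(self._prepare(frames))
        return np.argmax(logits, axis=-1).astype(np.uint8)

    # ------------------------------------------------------------ checkpoint

    def save(self, path: str | Path) -> None:
        meta = json.dumps(asdict(self.cfg))
        np.savez_compressed(
            path, meta=np.array(meta), channel_means=self.channel_means,
            channel_scale=self.channel_scale, **self.params, **self.buffers,
        )

    @classmethod
    def load(cls, path: str | Path) -> "SegNet":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            meta["schedule"] = tuple(tuple(s) for s in meta["schedule"])
            model = cls(SegNetConfig(**meta))
            for k in cls._PARAMS:
                model.params[k] = z[k]
            for k in cls._BUFFERS:
                model.buffers[k] = z[k]
            model.channel_means = z["channel_means"]
            model.channel_scale = z["channel_scale"]
        return model


def build_model(cfg: SegNetConfig | None = None) -> SegNet:
    return SegNet(cfg or SegNetConfig())


def train(
    model: SegNet,
    frames: Sequence[np.ndarray],
    gray_labels: Sequence[np.ndarray],
    cfg: SegNetConfig | None = None,
) -> TrainReport:
    """Train on paired RGB frames and grayscale annotation labels.

    ``gray_labels`` use the training gray code (64/94/124/154, background 0);
    a label outside the code table aborts before any weight update.  Reported
    loss/accuracy per epoch are means over that epoch's mini-batches,
    computed on annotated pixels only.
    """
    cfg = cfg or model.cfg
    if len(frames) == 0 or len(frames) != len(gray_labels):
        raise ValueError("need one grayscale label per training frame")
    x = np.stack([np.asarray(f, dtype=np.float32) for f in frames])
    y = np.stack([labels_from_gray(g) for g in gray_labels])
    if x.shape[:3] != y.shape:
        raise ValueError("frame and label dimensions differ")

    model.channel_means = x.mean(axis=(0, 1, 2)).astype(np.float32)
    model.channel_scale = np.maximum(
        x.std(axis=(0, 1, 2)).astype(np.float32), np.float32(1.0)
    )
    x = (x - model.channel_means) / model.channel_scale

    rng = np.random.default_rng(cfg.seed + 1)
    velocity = {k: np.zeros_like(v) for k, v in model.params.items()}
    report = TrainReport()
    n = x.shape[0]
    for stage, (epochs, lr) in enumerate(cfg.schedule, start=1):
        for epoch in range(1, epochs + 1):
            order = rng.permutation(n) if cfg.shuffle_each_epoch else np.arange(n)
            losses, accs = [], []
            for start in range(0, n, cfg.batch_size):
                sel = order[start : start + cfg.batch_size]
                logits, cache = model.forward(x[sel], want_cache=True, train=True)
                loss, acc, dlogits = _softmax_ce(logits, y[sel])
                grads = model._backward(dlogits.astype(np.float32), cache)
                for k, gk in grads.items():
                    velocity[k] = cfg.momentum * velocity[k] - lr * gk.astype(np.float32)
                    model.params[k] += velocity[k]
                losses.append(loss)
                accs.append(acc)
            report.history.append(
                {
                    "stage": stage,
                    "epoch": epoch,
                    "lr": lr,
                    "loss": float(np.mean(losses)),
                    "accuracy": float(np.mean(accs)),
                }
            )
    if report.history:
        report.final_loss = report.history[-1]["loss"]
        report.final_accuracy = report.history[-1]["accuracy"]
    return report
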