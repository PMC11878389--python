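"""Small convolutional network for the four topographic pattern classes.

The network is the classic stack of paired convolution / 2x2 max-pooling
layers followed by a dense layer and a 4-way softmax, implemented directly
on numpy (im2col convolution, exact argmax pooling, cross-entropy loss,
mini-batch SGD).  Everything is float32 and fully seeded: the same seed
reproduces initial weights, the shuffling order and hence the whole
training curve on one thread.

Default architecture: 64x64x2 input (filled contour mask + hue plane),
conv 5x5x8 / pool, conv 3x3x16 / pool, dense 64, softmax 4.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np


class InvalidSpecError(ValueError):
    pass


@dataclass
class CnnSpec:
    input_size: int = 64
    channels: int = 2
    blocks: Sequence[Tuple[int, int]] = ((5, 8), (3, 16))  # (kernel, filters) per pair
    dense_units: int = 64
    n_classes: int = 4

    def feature_shape(self) -> Tuple[int, int]:
        """(channels, spatial) after the conv/pool pairs; validates the spec."""
        if len(self.blocks) < 1:
            raise InvalidSpecError("need at least one conv/pool pair")
        s, c = self.input_size, self.channels
        for k, f in self.blocks:
            s = s - k + 1  # valid convolution
            if s < 2:
                raise InvalidSpecError("pooled spatial size below 1")
            s = s // 2  # 2x2 max-pool
            c = f
        if s < 1:
            raise InvalidSpecError("pooled spatial size below 1")
        return c, s

    def to_dict(self) -> dict:
        return {
            "input_size": self.input_size,
            "channels": self.channels,
            "blocks": [list(b) for b in self.blocks],
            "dense_units": self.dense_units,
            "n_classes": self.n_classes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CnnSpec":
        d = dict(d)
        d["blocks"] = tuple(tuple(b) for b in d["blocks"])
        return cls(**d)


@dataclass
class TrainConfig:
    epochs: int = 100  # "training seasons"
    batch_size: int = 64
    learning_rate: float = 1e-2
    momentum: float = 0.9
    seed: int = 0
    augment_rotation: bool = False  # +-10 deg; never vertical flips
    augment_brightness: bool = False

    def __post_init__(self):
        if self.epochs < 1:
            raise InvalidSpecError("epochs must be >= 1")


@dataclass
class EpochCurve:
    """Per-epoch accuracies, percent."""

    train_acc: List[float] = field(default_factory=list)
    test_acc: List[float] = field(default_factory=list)

    def mean_test_acc(self) -> float:
        return float(np.mean(self.test_acc))


class Model:
    """Weights + spec; forward/backward are free functions over this state."""

    def __init__(self, spec: CnnSpec, weights: dict):
        self.spec = spec
        self.weights = weights  # name -> float32 array

    def save(self, path) -> None:
        buf = {k: v for k, v in self.weights.items()}
        with open(path, "wb") as fh:
            np.savez(fh, __spec__=np.frombuffer(json.dumps(self.spec.to_dict()).encode(), dtype=np.uint8), **buf)

    @classmethod
    def load(cls, path) -> "Model":
        with np.load(path) as z:
            spec = CnnSpec.from_dict(json.loads(bytes(z["__spec__"]).decode()))
            weights = {k: z[k] for k in z.files if k != "__spec__"}
        return cls(spec, weights)

    def digest(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for k in sorted(self.weights):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.weights[k]).tobytes())
        return h.hexdigest()


def build_model(spec: CnnSpec, seed: int = 0) -> Model:
    """He-normal initialization, deterministic per seed."""
    c_out, s_out = spec.feature_shape()
    rng = np.random.default_rng(seed)
    w = {}
    c_in = spec.channels
    for bi, (k, f) in enumerate(spec.blocks):
        fan_in = c_in * k * k
        w[f"conv{bi}_w"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(f, c_in, k, k)).astype(
            np.float32
        )
        w[f"conv{bi}_b"] = np.zeros(f, dtype=np.float32)
        c_in = f
    flat = c_out * s_out * s_out
    w["dense_w"] = rng.normal(0.0, np.sqrt(2.0 / flat), size=(flat, spec.dense_units)).astype(
        np.float32
    )
    w["dense_b"] = np.zeros(spec.dense_units, dtype=np.float32)
    w["out_w"] = rng.normal(
        0.0, np.sqrt(2.0 / spec.dense_units), size=(spec.dense_units, spec.n_classes)
    ).astype(np.float32)
    w["out_b"] = np.zeros(spec.n_classes, dtype=np.float32)
    return Model(spec, w)


# ---------------------------------------------------------------------------
# Layer primitives (im2col)
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(C, N, H, W) -> (C*k*k, N*Ho*Wo) patch matrix (valid windows).

    Built from k*k*C plain slice copies, which keeps the copy at memory
    bandwidth (a transposed gather here would dominate the whole epoch).
    """
    c, n, h, w = x.shape
    ho, wo = h - k + 1, w - k + 1
    out = np.empty((c * k * k, n * ho * wo), dtype=np.float32)
    row = 0
    for ci in range(c):
        for p in range(k):
            for q in range(k):
                np.copyto(
                    out[row].reshape(n, ho, wo), x[ci, :, p : p + ho, q : q + wo]
                )
                row += 1
    return out


def _conv_forward(x, w, b):
    """x: (C, N, H, W); returns y: (F, N, Ho, Wo) and the patch matrix."""
    f, c, k, _ = w.shape
    _, n, h, wd = x.shape
    ho, wo = h - k + 1, wd - k + 1
    cols = _im2col(x, k)
    y = (w.reshape(f, -1) @ cols).reshape(f, n, ho, wo)
    return y + b[:, None, None, None], cols


def _conv_backward(dy, cols, w, need_dx=True):
    f, c, k, _ = w.shape
    _, n, ho, wo = dy.shape
    dyf = dy.reshape(f, -1)
    dw = (dyf @ cols.T).reshape(w.shape)
    db = dyf.sum(axis=1)
    if not need_dx:
        return None, dw.astype(np.float32), db.astype(np.float32)
    # input gradient: full correlation of padded dy with spatially flipped w
    dyp = np.pad(dy, ((0, 0), (0, 0), (k - 1, k - 1), (k - 1, k - 1)))
    pcols = _im2col(dyp, k)  # (F*k*k, N*H*W)
    wf = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(c, f * k * k)
    dx = (wf @ pcols).reshape(c, n, ho + k - 1, wo + k - 1)
    return dx.astype(np.float32), dw.astype(np.float32), db.astype(np.float32)


def _pool_forward(x):
    """2x2 max-pool on (C, N, H, W); argmax kept for an exact backward."""
    c, n, h, w = x.shape
    ho, wo = h // 2, w // 2
    xr = x[:, :, : ho * 2, : wo * 2].reshape(c, n, ho, 2, wo, 2)
    xf = xr.transpose(0, 1, 2, 4, 3, 5).reshape(c, n, ho, wo, 4)
    idx = xf.argmax(axis=-1)
    out = np.take_along_axis(xf, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def _pool_backward(dy, cache):
    idx, x_shape = cache
    c, n, h, w = x_shape
    ho, wo = h // 2, w // 2
    dxf = np.zeros((c, n, ho, wo, 4), dtype=np.float32)
    np.put_along_axis(dxf, idx[..., None], dy[..., None].astype(np.float32), axis=-1)
    dx = dxf.reshape(c, n, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(c, n, ho * 2, wo * 2)
    if ho * 2 != h or wo * 2 != w:
        dx = np.pad(dx, ((0, 0), (0, 0), (0, h - ho * 2), (0, w - wo * 2)))
    return dx


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def forward(model: Model, x: np.ndarray, want_cache: bool = False):
    """Class scores (softmax, rows sum to 1) for a batch (N, C, H, W)."""
    spec = model.spec
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    if x.shape[1:] != (spec.channels, spec.input_size, spec.input_size):
        raise ValueError(f"input shape {x.shape[1:]} does not match spec")
    w = model.weights
    cache = {"acts": []}
    h = np.ascontiguousarray(x.transpose(1, 0, 2, 3))  # channels-first (C, N, H, W)
    for bi in range(len(spec.blocks)):
        z, cols = _conv_forward(h, w[f"conv{bi}_w"], w[f"conv{bi}_b"])
        a = np.maximum(z, 0.0)
        p, pc = _pool_forward(a)
        cache["acts"].append((cols, z, pc))
        h = p
    flat = np.ascontiguousarray(h.transpose(1, 0, 2, 3)).reshape(h.shape[1], -1)
    d1 = flat @ w["dense_w"] + w["dense_b"]
    a1 = np.maximum(d1, 0.0)
    logits = a1 @ w["out_w"] + w["out_b"]
    probs = _softmax(logits)
    if not want_cache:
        return probs
    cache.update(h_pool=h, flat=flat, d1=d1, a1=a1, logits=logits, probs=probs)
    return probs, cache


def _backward(model: Model, cache, y_onehot: np.ndarray) -> dict:
    w = model.weights
    n = y_onehot.shape[0]
    g = {}
    dlogits = (cache["probs"] - y_onehot) / n
    g["out_w"] = cache["a1"].T @ dlogits
    g["out_b"] = dlogits.sum(axis=0)
    da1 = dlogits @ w["out_w"].T
    dd1 = da1 * (cache["d1"] > 0)
    g["dense_w"] = cache["flat"].T @ dd1
    g["dense_b"] = dd1.sum(axis=0)
    hp = cache["h_pool"]  # (C, N, s, s)
    dh = np.ascontiguousarray(
        (dd1 @ w["dense_w"].T).reshape(hp.shape[1], hp.shape[0], hp.shape[2], hp.shape[3])
        .transpose(1, 0, 2, 3)
    )
    for bi in reversed(range(len(model.spec.blocks))):
        cols, z, pc = cache["acts"][bi]
        da = _pool_backward(dh, pc)
        dz = da * (z > 0)
        dh, dw_, db_ = _conv_backward(dz, cols, w[f"conv{bi}_w"], need_dx=bi > 0)
        g[f"conv{bi}_w"] = dw_
        g[f"conv{bi}_b"] = db_
    return g


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _accuracy(model: Model, x: np.ndarray, y: np.ndarray, batch: int = 128) -> float:
    hits = 0
    for i in range(0, len(x), batch):
        p = forward(model, x[i : i + batch])
        hits += int((p.argmax(axis=1) == y[i : i + batch]).sum())
    return 100.0 * hits / len(x)


def _augment(x, rng, cfg: TrainConfig):
    from scipy.ndimage import rotate

    out = x.copy()
    for i in range(len(out)):
        if cfg.augment_rotation:
            ang = rng.uniform(-10.0, 10.0)
            out[i] = rotate(out[i], ang, axes=(1, 2), reshape=False, order=1, mode="constant")
        if cfg.augment_brightness:
            out[i, 1:] = np.clip(out[i, 1:] + rng.uniform(-0.03, 0.03), 0.0, 1.0)
    return out


def train(
    model: Model,
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    test_y: np.ndarray,
    cfg: Optional[TrainConfig] = None,
):
    """Mini-batch SGD with momentum on cross-entropy; records the epoch curve.

    train/test inputs are (N, C, H, W) float32 with integer class indices.
    Returns ``(model, EpochCurve)``; the model is updated in place.
    """
    cfg = cfg or TrainConfig()
    train_y = np.asarray(train_y)
    test_y = np.asarray(test_y)
    if len(train_y) == 0 or len(test_y) == 0:
        raise InvalidSpecError("train and test sets must both be non-empty")
    present = np.unique(train_y)
    if len(present) < model.spec.n_classes:
        raise InvalidSpecError(
            f"train set covers classes {present.tolist()} of {model.spec.n_classes}"
        )
    rng = np.random.default_rng(cfg.seed)
    vel = {k: np.zeros_like(v) for k, v in model.weights.items()}
    n = len(train_x)
    onehot = np.eye(model.spec.n_classes, dtype=np.float32)
    curve = EpochCurve()
    augmenting = cfg.augment_rotation or cfg.augment_brightness
    train_x = np.asarray(train_x, dtype=np.float32)
    test_x = np.asarray(test_x, dtype=np.float32)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        hits = 0
        for i in range(0, n, cfg.batch_size):
            sel = order[i : i + cfg.batch_size]
            xb = train_x[sel]
            if augmenting:
                xb = _augment(xb, rng, cfg)
            yb = train_y[sel]
            probs, cache = forward(model, xb, want_cache=True)
            hits += int((probs.argmax(axis=1) == yb).sum())
            grads = _backward(model, cache, onehot[yb])
            for k, gk in grads.items():
                vel[k] = cfg.momentum * vel[k] - cfg.learning_rate * gk
                model.weights[k] += vel[k]
        curve.train_acc.append(100.0 * hits / n)
        curve.test_acc.append(_accuracy(model, test_x, test_y))
    return model, curve


def predict(model: Model, x: np.ndarray):
    """(label index, scores) for one input or a batch; argmax ties break low."""
    probs = forward(model, x)
    idx = probs.argmax(axis=1)
    if probs.shape[0] == 1:
        return int(idx[0]), probs[0]
    return idx, probs
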