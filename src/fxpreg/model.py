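"""The registration regressor: a compact CNN mapping a 32x32x3 concatenated
fixed/moving image to three normalized rigid parameters.

Architecture (2984 trainable parameters):

    input (32,32,3)
    -> conv 2x2, 8 kernels, stride 1, valid, ReLU   -> (31,31,8)   104 params
    -> max-pool 2x2, stride 2                        -> (15,15,8)
    -> conv 2x2, 16 kernels, stride 1, valid, ReLU   -> (14,14,16)  528 params
    -> max-pool 2x2, stride 2                        -> (7,7,16)
    -> flatten                                       -> 784
    -> dropout 0.5 (training only)
    -> three independent bias-free linear heads      -> rot, dx, dy (784 each)

Convolutions are cross-correlations (no kernel flip), the convention of all
mainstream frameworks.  Heads carry no bias: the printed per-head parameter
count of 784 equals the flatten width, which pins the head to a pure dot
product.

Training is plain numpy: forward, manual backprop, Adam, summed per-head MSE
loss, inverted dropout on the shared flattened vector (one mask for all three
heads).  The forward pass is fully self-contained so the fixed-point emulator
can mirror it operation for operation.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NetworkWeights",
    "TrainConfig",
    "Prediction",
    "ARCH_SHAPES",
    "init_weights",
    "conv2d_valid",
    "relu",
    "maxpool_2x2",
    "forward_float",
    "forward_batch",
    "count_parameters",
    "train",
    "save_weights",
    "load_weights",
]

HEAD_NAMES = ("rot", "dx", "dy")

#: Layer output shapes through the network, input first.
ARCH_SHAPES = [
    (32, 32, 3),
    (31, 31, 8),
    (15, 15, 8),
    (14, 14, 16),
    (7, 7, 16),
    (784,),
    (3,),
]

_TENSOR_SHAPES = {
    "conv1_w": (2, 2, 3, 8),
    "conv1_b": (8,),
    "conv2_w": (2, 2, 8, 16),
    "conv2_b": (16,),
    "head_rot_w": (784,),
    "head_dx_w": (784,),
    "head_dy_w": (784,),
}


@dataclass
class NetworkWeights:
    """All trainable tensors of the regressor."""

    conv1_w: np.ndarray
    conv1_b: np.ndarray
    conv2_w: np.ndarray
    conv2_b: np.ndarray
    head_rot_w: np.ndarray
    head_dx_w: np.ndarray
    head_dy_w: np.ndarray

    def __post_init__(self) -> None:
        for name, shape in _TENSOR_SHAPES.items():
            t = np.asarray(getattr(self, name), dtype=float)
            if t.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {t.shape}")
            if not np.all(np.isfinite(t)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, t)

    def tensors(self) -> dict:
        return {name: getattr(self, name) for name in _TENSOR_SHAPES}

    def heads(self) -> np.ndarray:
        """Head weights stacked to a (784, 3) matrix, order rot/dx/dy."""
        return np.stack(
            [self.head_rot_w, self.head_dx_w, self.head_dy_w], axis=1
        )

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(**{k: v.copy() for k, v in self.tensors().items()})


@dataclass
class TrainConfig:
    """Training protocol: Adam, summed per-head MSE, dropout 0.5."""

    learning_rate: float = 1e-5
    batch_size: int = 50
    epochs: int = 500
    dropout_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class Prediction:
    """Raw (unclamped) linear head outputs on the normalized target scale."""

    rot_n: float
    dx_n: float
    dy_n: float

    def as_array(self) -> np.ndarray:
        return np.array([self.rot_n, self.dx_n, self.dy_n], dtype=float)


def init_weights(seed: int = 0) -> NetworkWeights:
    """Glorot-uniform initialization, zero biases (seeded)."""
    rng = np.random.default_rng(seed)

    def glorot(shape, fan_in, fan_out):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=shape)

    return NetworkWeights(
        conv1_w=glorot((2, 2, 3, 8), 2 * 2 * 3, 2 * 2 * 8),
        conv1_b=np.zeros(8),
        conv2_w=glorot((2, 2, 8, 16), 2 * 2 * 8, 2 * 2 * 16),
        conv2_b=np.zeros(16),
        head_rot_w=glorot((784,), 784, 1),
        head_dx_w=glorot((784,), 784, 1),
        head_dy_w=glorot((784,), 784, 1),
    )


def count_parameters(w: NetworkWeights) -> int:
    """Exact count of scalar trainables (2984 for the full model)."""
    return int(sum(t.size for t in w.tensors().values()))


# ---------------------------------------------------------------------------
# Layer primitives.  Batched internally; the public single-image ops accept
# H x W x C arrays.
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B,H,W,N) -> (B, H-k+1, W-k+1, k*k*N) patches, index order (i, j, n)."""
    oh, ow = x.shape[1] - k + 1, x.shape[2] - k + 1
    return np.concatenate(
        [
            x[:, i : i + oh, j : j + ow, :]
            for i in range(k)
            for j in range(k)
        ],
        axis=3,
    )


def conv2d_valid(x: np.ndarray, kernels: np.ndarray, biases: np.ndarray) -> np.ndarray:
    """Valid cross-correlation, stride 1.

    ``out[r,c,m] = b[m] + sum_{i,j,n} x[r+i, c+j, n] * kernels[i,j,n,m]``,
    the six-nested-loop semantics, computed via im2col + matmul.
    """
    x = np.asarray(x, dtype=float)
    kernels = np.asarray(kernels, dtype=float)
    biases = np.asarray(biases, dtype=float)
    single = x.ndim == 3
    if single:
        x = x[None]
    k = kernels.shape[0]
    if kernels.shape[1] != k or kernels.shape[2] != x.shape[3]:
        raise ValueError("kernel shape does not match input channels")
    if biases.shape != (kernels.shape[3],):
        raise ValueError("bias length must equal output channel count")
    if k > x.shape[1] or k > x.shape[2]:
        raise ValueError("kernel larger than input")
    cols = _im2col(x, k)
    out = cols @ kernels.reshape(k * k * x.shape[3], -1) + biases
    return out[0] if single else out


def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(0, x)."""
    return np.maximum(np.asarray(x), 0)


def maxpool_2x2(x: np.ndarray) -> np.ndarray:
    """Non-overlapping 2x2 max pooling, stride 2; trailing odd row/col dropped."""
    x = np.asarray(x)
    single = x.ndim == 3
    if single:
        x = x[None]
    b, h, w, c = x.shape
    if h < 2 or w < 2:
        raise ValueError("input too small to pool")
    h2, w2 = h // 2, w // 2
    v = x[:, : 2 * h2, : 2 * w2, :].reshape(b, h2, 2, w2, 2, c)
    out = v.max(axis=(2, 4))
    return out[0] if single else out


_POOL_OFFSETS = ((0, 0), (0, 1), (1, 0), (1, 1))


def _pool_windows(x: np.ndarray) -> np.ndarray:
    """(B,H,W,C) -> (B,H2,W2,C,4) pooling windows (for argmax bookkeeping)."""
    h2, w2 = x.shape[1] // 2, x.shape[2] // 2
    return np.stack(
        [
            x[:, i : 2 * h2 : 2, j : 2 * w2 : 2, :]
            for i, j in _POOL_OFFSETS
        ],
        axis=-1,
    )


def forward_batch(
    w: NetworkWeights,
    x: np.ndarray,
    dropout_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    cache: dict | None = None,
) -> np.ndarray:
    """Forward pass on a (B,32,32,3) batch -> (B,3) normalized predictions.

    With ``dropout_rate`` > 0 an inverted-dropout mask (shared by the three
    heads) is applied to the flattened vector; ``cache``, if given, is filled
    with intermediates for backprop.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 4 or x.shape[1:] != (32, 32, 3):
        raise ValueError("input batch must have shape (B, 32, 32, 3)")
    b = x.shape[0]
    cols1 = _im2col(x, 2)
    a1 = cols1 @ w.conv1_w.reshape(12, 8) + w.conv1_b
    r1 = np.maximum(a1, 0)
    win1 = _pool_windows(r1)
    arg1 = win1.argmax(axis=-1)
    p1 = win1.max(axis=-1)

    cols2 = _im2col(p1, 2)
    a2 = cols2 @ w.conv2_w.reshape(32, 16) + w.conv2_b
    r2 = np.maximum(a2, 0)
    win2 = _pool_windows(r2)
    arg2 = win2.argmax(axis=-1)
    p2 = win2.max(axis=-1)

    flat = p2.reshape(b, 784)
    if dropout_rate > 0.0:
        if rng is None:
            raise ValueError("dropout requires an rng")
        keep = 1.0 - dropout_rate
        mask = (rng.random((b, 784)) < keep) / keep
        dropped = flat * mask
    else:
        mask = None
        dropped = flat
    y = dropped @ w.heads()

    if cache is not None:
        cache.update(
            x=x, cols1=cols1, a1=a1, arg1=arg1, p1=p1, cols2=cols2, a2=a2,
            arg2=arg2, flat=flat, mask=mask, dropped=dropped, y=y,
        )
    return y


def forward_float(w: NetworkWeights, x: np.ndarray) -> Prediction:
    """Inference on one normalized 32x32x3 image (dropout inactive)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (32, 32, 3):
        raise ValueError("input must have shape (32, 32, 3)")
    y = forward_batch(w, x[None])[0]
    return Prediction(*map(float, y))


# ---------------------------------------------------------------------------
# Backprop + Adam
# ---------------------------------------------------------------------------


def _unpool(grad_p: np.ndarray, arg: np.ndarray, shape) -> np.ndarray:
    """Scatter pooled gradients back to the argmax positions."""
    b, h, w, c = shape
    h2, w2 = h // 2, w // 2
    out = np.zeros(shape, dtype=grad_p.dtype)
    for idx, (i, j) in enumerate(_POOL_OFFSETS):
        out[:, i : 2 * h2 : 2, j : 2 * w2 : 2, :] = grad_p * (arg == idx)
    return out


def _col2im(grad_cols: np.ndarray, shape, k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (accumulate overlapping patches)."""
    b, h, w, n = shape
    oh, ow = h - k + 1, w - k + 1
    g = grad_cols.reshape(b, oh, ow, k, k, n)
    out = np.zeros(shape)
    for i in range(k):
        for j in range(k):
            out[:, i : i + oh, j : j + ow, :] += g[:, :, :, i, j, :]
    return out


def _backward(w: NetworkWeights, cache: dict, targets: np.ndarray) -> dict:
    """Gradients of the summed per-head MSE w.r.t. every tensor."""
    b = cache["x"].shape[0]
    dy = 2.0 * (cache["y"] - targets) / b  # (B,3)
    grads = {}
    d_heads = cache["dropped"].T @ dy  # (784,3)
    grads["head_rot_w"] = d_heads[:, 0]
    grads["head_dx_w"] = d_heads[:, 1]
    grads["head_dy_w"] = d_heads[:, 2]

    d_flat = dy @ w.heads().T
    if cache["mask"] is not None:
        d_flat = d_flat * cache["mask"]
    d_p2 = d_flat.reshape(b, 7, 7, 16)
    d_r2 = _unpool(d_p2, cache["arg2"], (b, 14, 14, 16))
    d_a2 = d_r2 * (cache["a2"] > 0)
    grads["conv2_w"] = (
        cache["cols2"].reshape(-1, 32).T @ d_a2.reshape(-1, 16)
    ).reshape(2, 2, 8, 16)
    grads["conv2_b"] = d_a2.sum(axis=(0, 1, 2))
    d_cols2 = d_a2 @ w.conv2_w.reshape(32, 16).T
    d_p1 = _col2im(d_cols2, (b, 15, 15, 8), 2)
    d_r1 = _unpool(d_p1, cache["arg1"], (b, 31, 31, 8))
    d_a1 = d_r1 * (cache["a1"] > 0)
    grads["conv1_w"] = (
        cache["cols1"].reshape(-1, 12).T @ d_a1.reshape(-1, 8)
    ).reshape(2, 2, 3, 8)
    grads["conv1_b"] = d_a1.sum(axis=(0, 1, 2))
    return grads


def _per_head_mse(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    return ((y - t) ** 2).mean(axis=0)


def train(data, cfg: TrainConfig) -> tuple[NetworkWeights, dict]:
    """Train with Adam on summed per-head MSE.

    ``data`` is a DatasetSplit (train/val non-empty).  Returns the trained
    weights and a history dict with per-epoch, per-head train and validation
    losses.  Deterministic given ``cfg.seed`` (weight init, shuffling and
    dropout masks all derive from it).
    """
    if not data.train or not data.val:
        raise ValueError("train and val splits must be non-empty")
    ss = np.random.SeedSequence(cfg.seed)
    init_seed, shuffle_ss, dropout_ss = ss.spawn(3)
    w = init_weights(int(init_seed.generate_state(1)[0] % 2**31))
    shuffle_rng = np.random.default_rng(shuffle_ss)
    dropout_rng = np.random.default_rng(dropout_ss)

    from .phantom import concat_pair

    def stack(pairs):
        x = np.stack([concat_pair(p.fixed, p.moving) for p in pairs])
        t = np.stack([p.gt_norm for p in pairs])
        return x, t

    x_train, t_train = stack(data.train)
    x_val, t_val = stack(data.val)
    n = x_train.shape[0]

    tensors = w.tensors()
    m = {k: np.zeros_like(v) for k, v in tensors.items()}
    v = {k: np.zeros_like(vv) for k, vv in tensors.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    history = {"train": [], "val": []}

    for _ in range(cfg.epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss = np.zeros(3)
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            cache: dict = {}
            y = forward_batch(
                w,
                x_train[idx],
                dropout_rate=cfg.dropout_rate,
                rng=dropout_rng,
                cache=cache,
            )
            epoch_loss += _per_head_mse(y, t_train[idx])
            n_batches += 1
            grads = _backward(w, cache, t_train[idx])
            step += 1
            for k in tensors:
                g = grads[k]
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                mhat = m[k] / (1 - beta1**step)
                vhat = v[k] / (1 - beta2**step)
                getattr(w, k)[...] -= (
                    cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
                )
        history["train"].append(epoch_loss / n_batches)
        y_val = forward_batch(w, x_val)
        history["val"].append(_per_head_mse(y_val, t_val))

    history["train"] = np.array(history["train"])
    history["val"] = np.array(history["val"])
    return w, history


# ---------------------------------------------------------------------------
# Persistence: zip container of raw .npy tensors + JSON metadata header.
# ---------------------------------------------------------------------------


def save_weights(w: NetworkWeights, path, metadata: dict | None = None) -> None:
    """Lossless save: named float64 tensors + JSON metadata.

    The header records the exact trainable parameter count (2984) and the
    target normalization divisors.
    """
    from .rigid import NORM_DIVISORS

    meta = {
        "format": "fxpreg-weights-v1",
        "param_count": count_parameters(w),
        "norm_divisors": NORM_DIVISORS.tolist(),
        "tensor_shapes": {k: list(v) for k, v in _TENSOR_SHAPES.items()},
    }
    if metadata:
        meta.update(metadata)
    arrays = {k: v for k, v in w.tensors().items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8
    ), **arrays)


def load_weights(path) -> NetworkWeights:
    """Load a weight file; raises ValueError on malformed content."""
    try:
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            if meta.get("format") != "fxpreg-weights-v1":
                raise ValueError("unrecognized weight file format")
            tensors = {k: z[k] for k in _TENSOR_SHAPES}
    except (KeyError, zipfile.BadZipFile, OSError) as exc:
        raise ValueError(f"malformed weight file: {exc}") from exc
    return NetworkWeights(**tensors)


def load_weight_metadata(path) -> dict:
    with np.load(path) as z:
        return json.loads(bytes(z["__meta__"]).decode())
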