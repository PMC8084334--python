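"""Minimal NumPy neural-network layers: 3x3 convolutions, batch
normalization, ReLU, 2x2 average/max pooling, global average pooling,
dropout and a linear head, with analytic backward passes.  Shapes are
channel-first ``(batch, channels, height, width)``; weights live in plain
dicts so checkpoints stay a single NPZ.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def conv3x3_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Same-padding 3x3 convolution. ``w``: (out_ch, in_ch, 3, 3).

    The im2col array is materialized contiguously once and cached, so the
    gather cost is shared between the forward pass and both backward
    contractions (plain GEMMs on the cached array).
    """
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.ascontiguousarray(
        sliding_window_view(xp, (3, 3), axis=(2, 3))
    )  # (B, C, H, W, 3, 3)
    y = np.tensordot(cols, w, axes=([1, 4, 5], [1, 2, 3]))  # (B, H, W, O)
    y = np.ascontiguousarray(y.transpose(0, 3, 1, 2)) + b[None, :, None, None]
    return y, cols


def conv3x3_backward(
    dy: np.ndarray, cols: np.ndarray, w: np.ndarray, need_dx: bool = True
):
    dw = np.tensordot(dy, cols, axes=([0, 2, 3], [0, 2, 3]))  # (O, C, 3, 3)
    db = dy.sum(axis=(0, 2, 3))
    if not need_dx:
        return None, dw, db
    # dx via full correlation of dy with the flipped kernel
    dyp = np.pad(dy, ((0, 0), (0, 0), (2, 2), (2, 2)))
    cols_dy = np.ascontiguousarray(
        sliding_window_view(dyp, (3, 3), axis=(2, 3))
    )  # (B, O, H+2, W+2, 3, 3)
    wf = w[:, :, ::-1, ::-1]  # (O, C, 3, 3)
    dxp = np.tensordot(cols_dy, wf, axes=([1, 4, 5], [0, 2, 3]))  # (B, H+2, W+2, C)
    dxp = dxp.transpose(0, 3, 1, 2)
    h, w_ = dy.shape[2], dy.shape[3]
    dx = dxp[:, :, 1 : h + 1, 1 : w_ + 1]
    return np.ascontiguousarray(dx), dw, db


def maxpool2_forward(x: np.ndarray):
    b, c, h, w = x.shape
    xr = (
        x.reshape(b, c, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(b, c, h // 2, w // 2, 4)
    )
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return y, (idx, x.shape)


def avgpool2_forward(x: np.ndarray):
    b, c, h, w = x.shape
    y = x.reshape(b, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))
    return y, x.shape


def avgpool2_backward(dy: np.ndarray, shape):
    b, c, h, w = shape
    dx = np.broadcast_to(
        dy[:, :, :, None, :, None] / 4.0, (b, c, h // 2, 2, w // 2, 2)
    ).reshape(b, c, h, w)
    return np.ascontiguousarray(dx.astype(dy.dtype))


def maxpool2_backward(dy: np.ndarray, cache):
    idx, (b, c, h, w) = cache
    dxr = np.zeros((b, c, h // 2, w // 2, 4), dtype=dy.dtype)
    np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
    dx = (
        dxr.reshape(b, c, h // 2, w // 2, 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(b, c, h, w)
    )
    return np.ascontiguousarray(dx)


def batchnorm_forward(
    x: np.ndarray,
    gamma: np.ndarray,
    beta: np.ndarray,
    state: dict,
    key: str,
    train: bool,
    momentum: float = 0.9,
    eps: float = 1e-5,
):
    """Per-channel batch normalization over (batch, H, W).

    ``state`` holds running mean/var under ``key`` for evaluation mode.
    """
    if train:
        mu = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))
        state[f"{key}_mean"] = momentum * state.get(f"{key}_mean", mu) + (
            1 - momentum
        ) * mu
        state[f"{key}_var"] = momentum * state.get(f"{key}_var", var) + (
            1 - momentum
        ) * var
    else:
        mu = state[f"{key}_mean"]
        var = state[f"{key}_var"]
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu[None, :, None, None]) * inv_std[None, :, None, None]
    y = gamma[None, :, None, None] * xhat + beta[None, :, None, None]
    cache = (xhat, gamma, inv_std)
    return y.astype(x.dtype), cache


def batchnorm_backward(dy: np.ndarray, cache):
    xhat, gamma, inv_std = cache
    b, c, h, w = dy.shape
    n = b * h * w
    dgamma = (dy * xhat).sum(axis=(0, 2, 3))
    dbeta = dy.sum(axis=(0, 2, 3))
    dxhat = dy * gamma[None, :, None, None]
    sum_dxhat = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
    sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
    dx = (
        inv_std[None, :, None, None]
        / n
        * (n * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)
    )
    return dx.astype(dy.dtype), dgamma, dbeta


def relu_forward(x: np.ndarray):
    return np.maximum(x, 0), x > 0


def relu_backward(dy: np.ndarray, mask: np.ndarray):
    return dy * mask


def global_avg_pool_forward(x: np.ndarray):
    return x.mean(axis=(2, 3)), x.shape


def global_avg_pool_backward(dy: np.ndarray, shape):
    b, c, h, w = shape
    return np.broadcast_to(dy[:, :, None, None] / (h * w), shape).astype(dy.dtype)


def dropout_forward(x: np.ndarray, rate: float, rng: np.random.Generator):
    """Inverted dropout; identity when ``rate == 0``."""
    if rate <= 0:
        return x, None
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * mask, mask.astype(x.dtype)


def dropout_backward(dy: np.ndarray, mask):
    return dy if mask is None else dy * mask


class ConvBackbone:
    """Small convolutional feature extractor phi(x).

    ``depth = len(channels)`` blocks of conv(3x3) + batchnorm + ReLU +
    2x2 pooling (average by default — it preserves the linear spatial
    functionals that smooth environmental statistics live in; ``max``
    optional),
    finished either by global average pooling (``pool='gap'``, the default)
    or by flattening the final map (``pool='flatten'``, keeping
    center-pixel-specific layout at the cost of a larger head).  The patch
    size must be divisible by ``2 ** depth``.
    """

    def __init__(
        self,
        in_channels: int,
        channels=(32, 64, 256),
        patch_size: int = 32,
        pool: str = "gap",
        block_pool: str = "avg",
    ):
        if patch_size % (2 ** len(channels)) != 0:
            raise ValueError(
                f"patch_size {patch_size} not divisible by 2^{len(channels)}"
            )
        if pool not in ("flatten", "gap"):
            raise ValueError(f"unknown pool {pool!r}")
        if block_pool not in ("avg", "max"):
            raise ValueError(f"unknown block_pool {block_pool!r}")
        self.in_channels = in_channels
        self.channels = tuple(int(c) for c in channels)
        self.patch_size = patch_size
        self.pool = pool
        self.block_pool = block_pool
        self.map_size = patch_size // (2 ** len(channels))

    @property
    def feature_dim(self) -> int:
        if self.pool == "gap":
            return self.channels[-1]
        return self.channels[-1] * self.map_size**2

    def init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        params = {}
        c_in = self.in_channels
        for i, c_out in enumerate(self.channels):
            fan_in = c_in * 9
            params[f"conv{i}_w"] = (
                rng.standard_normal((c_out, c_in, 3, 3)) * np.sqrt(2.0 / fan_in)
            ).astype(np.float32)
            params[f"conv{i}_b"] = np.zeros(c_out, dtype=np.float32)
            params[f"bn{i}_gamma"] = np.ones(c_out, dtype=np.float32)
            params[f"bn{i}_beta"] = np.zeros(c_out, dtype=np.float32)
            c_in = c_out
        return params

    def forward(self, x: np.ndarray, params: dict, state: dict, train: bool = False):
        caches = []
        for i in range(len(self.channels)):
            x, conv_cache = conv3x3_forward(
                x, params[f"conv{i}_w"], params[f"conv{i}_b"]
            )
            x, bn_cache = batchnorm_forward(
                x, params[f"bn{i}_gamma"], params[f"bn{i}_beta"],
                state, f"bn{i}", train,
            )
            x, relu_mask = relu_forward(x)
            if self.block_pool == "avg":
                x, pool_cache = avgpool2_forward(x)
            else:
                x, pool_cache = maxpool2_forward(x)
            caches.append((conv_cache, bn_cache, relu_mask, pool_cache))
        if self.pool == "gap":
            z, tail_cache = global_avg_pool_forward(x)
        else:
            z, tail_cache = x.reshape(x.shape[0], -1), x.shape
        caches.append(tail_cache)
        return z, caches

    def backward(self, dz: np.ndarray, params: dict, caches) -> dict:
        grads = {}
        if self.pool == "gap":
            dx = global_avg_pool_backward(dz, caches[-1])
        else:
            dx = dz.reshape(caches[-1])
        for i in reversed(range(len(self.channels))):
            conv_cache, bn_cache, relu_mask, pool_cache = caches[i]
            if self.block_pool == "avg":
                dx = avgpool2_backward(dx, pool_cache)
            else:
                dx = maxpool2_backward(dx, pool_cache)
            dx = relu_backward(dx, relu_mask)
            dx, dgamma, dbeta = batchnorm_backward(dx, bn_cache)
            grads[f"bn{i}_gamma"] = dgamma
            grads[f"bn{i}_beta"] = dbeta
            dx, dw, db = conv3x3_backward(
                dx, conv_cache, params[f"conv{i}_w"], need_dx=i > 0
            )
            grads[f"conv{i}_w"] = dw
            grads[f"conv{i}_b"] = db
        return grads


class SGDMomentum:
    """Classic SGD with momentum over a parameter dict.

    Weight decay applies to convolution and head parameters (including the
    per-species intercepts, keeping learned priors mild) but not to the
    batch-norm scales and shifts.
    """

    def __init__(
        self,
        params: dict[str, np.ndarray],
        momentum: float = 0.9,
        weight_decay: float = 0.0,
    ):
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict, lr: float) -> None:
        for k, v in self.velocity.items():
            g = grads[k]
            if self.weight_decay and not k.startswith("bn"):
                g = g + self.weight_decay * params[k]
            np.multiply(v, self.momentum, out=v)
            v -= lr * g
            params[k] += v
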