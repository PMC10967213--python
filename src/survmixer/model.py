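"""The pathway-image survival classifier: a small ConvMixer-style CNN.

Architecture (input: one-channel ``image_side x image_side`` pathway image):

1. *Patch embedding* — a non-overlapping convolution with kernel = stride =
   patch size, so each pathway patch maps to exactly one spatial position
   of a ``channels x grid x grid`` feature map; GELU + batch norm follow.
2. *Mixer blocks* (repeated ``n_blocks`` times) — a depthwise 3x3
   convolution (same padding, shape-preserving) with residual connection,
   then a pointwise 1x1 convolution fusing channels; each convolution is
   followed by activation + batch norm.
3. *Blank masking* — grid positions that carry no pathway are zeroed.
   Because same-padding depthwise convolutions mix neighboring positions,
   blank slots are re-zeroed after the embedding and after every block,
   not only before the head; this makes the model's output provably
   independent of anything written inside blank patches.
4. *Head* — global average pooling over grid positions, a single linear
   unit, and a sigmoid giving P(death within horizon).

Everything — forward, backward, Adam — is implemented directly in NumPy.
The hand-written backward pass doubles as the gradient source for
Grad-CAM: ``SurvConvMixer.gradient_at`` returns d(logit)/d(feature map)
at any named layer.

Spatial feature maps use the (batch, channels, height, width) convention.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import erf, expit

from .imaging import ImageLayout

_SQRT2 = float(np.sqrt(2.0))
_INV_SQRT_2PI = float(1.0 / np.sqrt(2.0 * np.pi))
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


class ModelError(ValueError):
    """Raised for configuration or geometry problems in the network."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Hyperparameters of the network and its training loop.

    ``patch_kernel`` must equal ``patch_stride`` (non-overlapping patch
    embedding). ``depthwise_stride`` defaults to 1 so hidden feature maps
    keep the grid shape that masking and Grad-CAM rely on.
    """

    channels: int = 256
    n_blocks: int = 2
    patch_kernel: int = 7
    patch_stride: int = 7
    depthwise_kernel: int = 3
    depthwise_stride: int = 1
    activation: str = "gelu"
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0
    pool_nonblank_only: bool = False

    def __post_init__(self) -> None:
        if self.patch_kernel != self.patch_stride:
            raise ModelError("patch_kernel must equal patch_stride (non-overlapping embedding)")
        if self.channels < 1 or self.n_blocks < 1:
            raise ModelError("channels and n_blocks must be >= 1")
        if self.activation not in ("gelu", "relu"):
            raise ModelError(f"unknown activation {self.activation!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# Parameters and primitive layers
# ---------------------------------------------------------------------------

class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


def _act(name: str, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Activation value and pointwise derivative."""
    if name == "gelu":
        phi = 0.5 * (1.0 + erf(x / _SQRT2))
        y = x * phi
        dy = phi + x * _INV_SQRT_2PI * np.exp(-0.5 * x * x)
        return y, dy
    # relu
    mask = (x > 0).astype(float)
    return x * mask, mask


class _Activation:
    def __init__(self, name: str):
        self.name = name
        self._dy: np.ndarray | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y, self._dy = _act(self.name, x)
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._dy


class _BatchNorm:
    """Per-channel batch normalization over (batch, height, width)."""

    def __init__(self, channels: int):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = _BN_MOMENTUM
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        g = self.gamma.value[None, :, None, None]
        b = self.beta.value[None, :, None, None]
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            invstd = 1.0 / np.sqrt(var + _BN_EPS)
            xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
            self._cache = ("train", xhat, invstd)
            return g * xhat + b
        invstd = 1.0 / np.sqrt(self.running_var + _BN_EPS)
        self._cache = ("eval", None, invstd)
        return g * (x - self.running_mean[None, :, None, None]) * invstd[None, :, None, None] + b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        mode, xhat, invstd = self._cache
        g = self.gamma.value[None, :, None, None]
        if mode == "eval":
            # eval-mode BN is a fixed per-channel affine map
            return dout * g * invstd[None, :, None, None]
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * g
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (invstd[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)


class _PatchEmbed:
    """Non-overlapping convolution: kernel = stride = patch side, 1 → C channels."""

    def __init__(self, patch_side: int, channels: int, rng: np.random.Generator):
        fan_in = patch_side ** 2
        self.patch_side = patch_side
        self.channels = channels
        self.weight = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(channels, fan_in)))
        self.bias = Param(np.zeros(channels))
        self._patches: np.ndarray | None = None
        self._shape: tuple | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, h, w = x.shape
        s = self.patch_side
        if h % s or w % s:
            raise ModelError(f"image side {h}x{w} not divisible by patch size {s}")
        gh, gw = h // s, w // s
        patches = (
            x.reshape(n, gh, s, gw, s).transpose(0, 1, 3, 2, 4).reshape(n, gh * gw, s * s)
        )
        self._patches = patches
        self._shape = (n, gh, gw)
        z = patches @ self.weight.value.T + self.bias.value  # (n, P, C)
        return z.transpose(0, 2, 1).reshape(n, self.channels, gh, gw)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, gh, gw = self._shape
        s = self.patch_side
        dz = dout.reshape(n, self.channels, gh * gw).transpose(0, 2, 1)  # (n, P, C)
        flat_dz = dz.reshape(-1, self.channels)
        flat_patches = self._patches.reshape(-1, s * s)
        self.weight.grad += flat_dz.T @ flat_patches
        self.bias.grad += flat_dz.sum(axis=0)
        dpatches = dz @ self.weight.value  # (n, P, s*s)
        return (
            dpatches.reshape(n, gh, gw, s, s).transpose(0, 1, 3, 2, 4).reshape(n, gh * s, gw * s)
        )


class _DepthwiseConv:
    """Per-channel 2D convolution with same padding (stride 1) or general stride."""

    def __init__(self, channels: int, kernel: int, stride: int, rng: np.random.Generator):
        self.kernel = kernel
        self.stride = stride
        self.weight = Param(rng.normal(0.0, np.sqrt(2.0 / (kernel * kernel)), size=(channels, kernel, kernel)))
        self.bias = Param(np.zeros(channels))
        self._xp: np.ndarray | None = None
        self._in_shape: tuple | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def _out_side(self, side: int) -> int:
        pad = self.kernel // 2
        return (side + 2 * pad - self.kernel) // self.stride + 1

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, h, w = x.shape
        k, st = self.kernel, self.stride
        pad = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        self._xp = xp
        self._in_shape = (n, c, h, w)
        oh, ow = self._out_side(h), self._out_side(w)
        y = np.zeros((n, c, oh, ow))
        for dy in range(k):
            for dx in range(k):
                y += (
                    self.weight.value[None, :, dy, dx, None, None]
                    * xp[:, :, dy:dy + st * oh:st, dx:dx + st * ow:st]
                )
        return y + self.bias.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        k, st = self.kernel, self.stride
        pad = k // 2
        oh, ow = dout.shape[2], dout.shape[3]
        dxp = np.zeros_like(self._xp)
        for dy in range(k):
            for dx in range(k):
                window = self._xp[:, :, dy:dy + st * oh:st, dx:dx + st * ow:st]
                self.weight.grad[:, dy, dx] += (dout * window).sum(axis=(0, 2, 3))
                dxp[:, :, dy:dy + st * oh:st, dx:dx + st * ow:st] += (
                    dout * self.weight.value[None, :, dy, dx, None, None]
                )
        self.bias.grad += dout.sum(axis=(0, 2, 3))
        return dxp[:, :, pad:pad + h, pad:pad + w]


class _PointwiseConv:
    """1x1 convolution: a linear map across channels at each position."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.channels = channels
        self.weight = Param(rng.normal(0.0, np.sqrt(2.0 / channels), size=(channels, channels)))
        self.bias = Param(np.zeros(channels))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return (
            np.einsum("nchw,dc->ndhw", x, self.weight.value)
            + self.bias.value[None, :, None, None]
        )

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.weight.grad += np.einsum("ndhw,nchw->dc", dout, self._x)
        self.bias.grad += dout.sum(axis=(0, 2, 3))
        return np.einsum("ndhw,dc->nchw", dout, self.weight.value)


class _BlankMask:
    """Zero all channels at blank grid positions; idempotent."""

    def __init__(self, layout: ImageLayout):
        g = layout.grid_side
        mask = np.ones((g, g))
        for r, c in layout.blank_slots:
            mask[r, c] = 0.0
        self.mask = mask[None, None, :, :]

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if x.shape[2:] != self.mask.shape[2:]:
            raise ModelError(
                f"feature map grid {x.shape[2:]} does not match layout grid {self.mask.shape[2:]}"
            )
        return x * self.mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self.mask


class _ResidualDepthwise:
    """x + BN(act(depthwise(x))); residual skipped if stride changes the shape."""

    def __init__(self, channels: int, kernel: int, stride: int, activation: str, rng):
        self.conv = _DepthwiseConv(channels, kernel, stride, rng)
        self.act = _Activation(activation)
        self.bn = _BatchNorm(channels)
        self._residual_used = False

    def params(self) -> list[Param]:
        return self.conv.params() + self.bn.params()

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = self.bn.forward(self.act.forward(self.conv.forward(x, training), training), training)
        self._residual_used = y.shape == x.shape
        return y + x if self._residual_used else y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dbranch = self.conv.backward(self.act.backward(self.bn.backward(dout)))
        return dbranch + dout if self._residual_used else dbranch


class _Sequential:
    def __init__(self, *ops):
        self.ops = list(ops)

    def params(self) -> list[Param]:
        return [p for op in self.ops for p in op.params()]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for op in self.ops:
            x = op.forward(x, training)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for op in reversed(self.ops):
            dout = op.backward(dout)
        return dout


# ---------------------------------------------------------------------------
# The network
# ---------------------------------------------------------------------------

class SurvConvMixer:
    """Patch-embedding CNN over pathway images with blank-slot masking.

    Named stages (usable as Grad-CAM layers): ``"embed"`` and ``"block1"``
    ... ``"blockN"``, each taken *after* its blank-slot re-zeroing. The
    default interpretation layer is the final block's masked output.
    """

    def __init__(self, cfg: ModelConfig, layout: ImageLayout):
        if layout.image_side % cfg.patch_kernel:
            raise ModelError(
                f"image side {layout.image_side} not divisible by patch kernel {cfg.patch_kernel}"
            )
        if layout.image_side // cfg.patch_kernel != layout.grid_side:
            raise ModelError("patch kernel does not map the image onto the layout grid")
        self.cfg = cfg
        self.layout = layout
        rng = np.random.default_rng(cfg.seed)
        mask = _BlankMask(layout)
        stages: list[tuple[str, _Sequential]] = [
            (
                "embed",
                _Sequential(
                    _PatchEmbed(cfg.patch_kernel, cfg.channels, rng),
                    _Activation(cfg.activation),
                    _BatchNorm(cfg.channels),
                    mask,
                ),
            )
        ]
        for b in range(1, cfg.n_blocks + 1):
            stages.append(
                (
                    f"block{b}",
                    _Sequential(
                        _ResidualDepthwise(
                            cfg.channels, cfg.depthwise_kernel, cfg.depthwise_stride,
                            cfg.activation, rng,
                        ),
                        _PointwiseConv(cfg.channels, rng),
                        _Activation(cfg.activation),
                        _BatchNorm(cfg.channels),
                        mask,
                    ),
                )
            )
        self.stages = stages
        self.head_weight = Param(rng.normal(0.0, np.sqrt(1.0 / cfg.channels), size=(cfg.channels,)))
        self.head_bias = Param(np.zeros(1))
        n_positions = layout.grid_side ** 2
        self._pool_div = (
            n_positions - len(layout.blank_slots) if cfg.pool_nonblank_only else n_positions
        )
        self._mask = mask
        self._cache: dict[str, np.ndarray] = {}

    # -- parameter plumbing -------------------------------------------------

    def params(self) -> list[Param]:
        out = [p for _, stage in self.stages for p in stage.params()]
        out += [self.head_weight, self.head_bias]
        return out

    def zero_grads(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    @property
    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def stage_names(self) -> list[str]:
        return [name for name, _ in self.stages]

    # -- forward / backward -------------------------------------------------

    def forward_features(self, images: np.ndarray, training: bool = False) -> np.ndarray:
        """Run all stages, caching each named output; returns the final map."""
        x = np.asarray(images, dtype=float)
        if x.ndim == 2:
            x = x[None]
        self._cache = {}
        for name, stage in self.stages:
            x = stage.forward(x, training)
            self._cache[name] = x
        return x

    def _head(self, features: np.ndarray) -> np.ndarray:
        pooled = features.sum(axis=(2, 3)) / self._pool_div  # (n, C)
        self._pooled = pooled
        return pooled @ self.head_weight.value + self.head_bias.value[0]

    def logits(self, images: np.ndarray, training: bool = False) -> np.ndarray:
        return self._head(self.forward_features(images, training))

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Per-sample probability of the positive (death-within-horizon) class."""
        return expit(self.logits(images, training=False))

    def _backward_from_logits(self, dlogits: np.ndarray, upto: str | None = None):
        """Backpropagate d(loss)/d(logit); returns grad at stage ``upto`` or the input."""
        n, c = self._pooled.shape
        self.head_weight.grad += self._pooled.T @ dlogits
        self.head_bias.grad += np.array([dlogits.sum()])
        g = self.layout.grid_side
        dfeat = (
            dlogits[:, None, None, None]
            * self.head_weight.value[None, :, None, None]
            / self._pool_div
        ) * np.ones((n, c, g, g))
        dout = dfeat
        for name, stage in reversed(self.stages):
            if name == upto:
                return dout
            dout = stage.backward(dout)
        if upto is not None:
            raise ModelError(f"unknown layer {upto!r}; available: {self.stage_names()}")
        return dout

    # -- Grad-CAM support ---------------------------------------------------

    def feature_map(self, layer: str) -> np.ndarray:
        if layer not in self._cache:
            raise ModelError(f"layer {layer!r} not cached; run forward first")
        return self._cache[layer]

    def gradient_at(self, images: np.ndarray, layer: str) -> tuple[np.ndarray, np.ndarray]:
        """(feature map A, d(logit)/dA) at the named layer, eval mode.

        In eval mode every operation acts per-sample, so backpropagating a
        unit gradient for all logits yields each sample's own gradient.
        """
        self.forward_features(images, training=False)
        self._head(self._cache[self.stages[-1][0]])
        self.zero_grads()
        n = self._pooled.shape[0]
        grads = self._backward_from_logits(np.ones(n), upto=layer)
        self.zero_grads()
        return self._cache[layer], grads

    def score_from(self, layer: str, features: np.ndarray) -> np.ndarray:
        """Pre-sigmoid score obtained by resuming the forward pass after ``layer``.

        Used by finite-difference checks of the Grad-CAM gradients.
        """
        names = self.stage_names()
        if layer not in names:
            raise ModelError(f"unknown layer {layer!r}; available: {names}")
        x = np.asarray(features, dtype=float)
        for name, stage in self.stages[names.index(layer) + 1:]:
            x = stage.forward(x, training=False)
        return self._head(x)

    # -- persistence --------------------------------------------------------

    def layout_hash(self) -> str:
        return hashlib.sha256(self.layout.to_json().encode()).hexdigest()[:16]

    def save(self, directory: str | Path, stem: str = "model") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        for i, (_, stage) in enumerate(self.stages):
            for j, op in enumerate(stage.ops):
                if isinstance(op, _BatchNorm):
                    arrays[f"bn{i}_{j}_mean"] = op.running_mean
                    arrays[f"bn{i}_{j}_var"] = op.running_var
                if isinstance(op, _ResidualDepthwise):
                    arrays[f"bn{i}_{j}r_mean"] = op.bn.running_mean
                    arrays[f"bn{i}_{j}r_var"] = op.bn.running_var
        np.savez(directory / f"{stem}.npz", **arrays)
        meta = {"config": self.cfg.to_dict(), "layout_hash": self.layout_hash()}
        (directory / f"{stem}.json").write_text(json.dumps(meta, indent=1))
        (directory / f"{stem}.layout.json").write_text(self.layout.to_json())

    @classmethod
    def load(cls, directory: str | Path, stem: str = "model") -> "SurvConvMixer":
        directory = Path(directory)
        meta = json.loads((directory / f"{stem}.json").read_text())
        layout = ImageLayout.from_json((directory / f"{stem}.layout.json").read_text())
        model = cls(ModelConfig.from_dict(meta["config"]), layout)
        data = np.load(directory / f"{stem}.npz")
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"p{i}"]
        for i, (_, stage) in enumerate(model.stages):
            for j, op in enumerate(stage.ops):
                if isinstance(op, _BatchNorm):
                    op.running_mean = data[f"bn{i}_{j}_mean"]
                    op.running_var = data[f"bn{i}_{j}_var"]
                if isinstance(op, _ResidualDepthwise):
                    op.bn.running_mean = data[f"bn{i}_{j}r_mean"]
                    op.bn.running_var = data[f"bn{i}_{j}r_var"]
        return model


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: list[Param], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def bce_with_logits(logits: np.ndarray, labels: np.ndarray) -> float:
    """Numerically stable mean binary cross-entropy."""
    z, y = np.asarray(logits, dtype=float), np.asarray(labels, dtype=float)
    return float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))


def recalibrate_batchnorm(model: SurvConvMixer, images: np.ndarray) -> None:
    """Re-estimate batch-norm statistics on ``images`` with the final weights.

    Running averages collected during optimization lag behind fast-moving
    weights, which distorts eval-mode predictions after short training
    runs. One full-batch training-mode pass with momentum 1 replaces them
    with self-consistent population statistics.
    """
    bns: list[_BatchNorm] = []
    for _, stage in model.stages:
        for op in stage.ops:
            if isinstance(op, _BatchNorm):
                bns.append(op)
            elif isinstance(op, _ResidualDepthwise):
                bns.append(op.bn)
    saved = [bn.momentum for bn in bns]
    for bn in bns:
        bn.momentum = 1.0
    try:
        model.forward_features(np.asarray(images, dtype=float), training=True)
    finally:
        for bn, mom in zip(bns, saved):
            bn.momentum = mom


def train_model(
    images: np.ndarray,
    labels: Sequence[int],
    cfg: ModelConfig,
    layout: ImageLayout,
    model: SurvConvMixer | None = None,
) -> tuple[SurvConvMixer, list[float]]:
    """Fit the network by Adam on binary cross-entropy.

    Deterministic given ``cfg.seed`` (weight init and batch shuffling both
    derive from it). Returns the trained model and per-epoch mean losses.
    """
    images = np.asarray(images, dtype=float)
    y = np.asarray(labels, dtype=float)
    if images.shape[0] != y.shape[0]:
        raise ModelError("images and labels length mismatch")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos < 2 or n_neg < 2:
        raise ModelError(f"need >=2 samples per class, got {n_pos} positive / {n_neg} negative")

    if model is None:
        model = SurvConvMixer(cfg, layout)
    opt = _Adam(model.params(), cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5ba7c4]))
    n = images.shape[0]
    history: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if idx.size < 2:
                continue  # batch norm needs >1 sample per batch
            zb = model.logits(images[idx], training=True)
            epoch_loss += bce_with_logits(zb, y[idx]) * idx.size
            model.zero_grads()
            dz = (expit(zb) - y[idx]) / idx.size
            model._backward_from_logits(dz)
            opt.step()
        history.append(epoch_loss / n)
    recalibrate_batchnorm(model, images)
    return model, history
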