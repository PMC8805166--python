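"""U-Net restorer for log-normalized diffraction patterns, in pure NumPy.

A symmetric encoder-decoder with skip concatenations: each level applies
two 3x3 same-padded convolutions with ReLU; 2x2 max-pooling downsamples,
nearest-neighbour upsampling and concatenation with the matching encoder
features reverse it; a final 1x1 convolution with a sigmoid maps to
[0, 1].  Dropout (feature-unit, inverted) is applied after the last two
downsampling steps during training.  Training minimizes pixel-mean binary
cross-entropy against the noiseless normalized target with Adam, matching
the published protocol; the layer inventory (channel counts, kernel
sizes) follows the canonical U-Net reduced to desk scale.

Tensors are NCHW, float32 by default (configurable; the gradient test
uses float64).  The implementation is deliberately
self-contained: forward and backward passes are explicit, with im2col
matrix multiplication doing the heavy lifting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np


# ---------------------------------------------------------------- config


@dataclass
class UNetConfig:
    """Architecture + training hyperparameters.

    ``depth`` is the number of downsampling steps; ``input_side`` must be
    divisible by 2**depth.  ``dropout_levels`` lists the encoder levels
    (0-based, counting downsampling steps) that carry dropout; the default
    is the last two.  The full-protocol configuration is 128-pixel inputs,
    20 epochs and batch 32; the desk preset (64 px, depth 3, base 16)
    trains in minutes on one CPU core.
    """

    input_side: int = 128
    depth: int = 4
    base_channels: int = 32
    dropout_rate: float = 0.5
    dropout_levels: tuple[int, ...] | None = None  # None -> last two
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    seed: int = 0
    skip_connections: bool = True
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.input_side % (1 << self.depth):
            raise ValueError("input_side must be divisible by 2**depth")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.dropout_levels is None:
            self.dropout_levels = tuple(range(max(0, self.depth - 2), self.depth))
        else:
            self.dropout_levels = tuple(self.dropout_levels)

    @property
    def bottleneck_side(self) -> int:
        return self.input_side >> self.depth

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


def desk_config(**overrides) -> UNetConfig:
    """CPU-feasible preset: 64x64 inputs, depth 3, 16 base channels, a
    slightly aggressive Adam step for the short schedule."""
    kw = dict(
        input_side=64, depth=3, base_channels=16, epochs=8, batch_size=8,
        learning_rate=2e-3,
    )
    kw.update(overrides)
    return UNetConfig(**kw)


# ------------------------------------------------------------ primitives


def _im2col(x: np.ndarray) -> np.ndarray:
    """(B, C, H, W) -> (B*H*W, C*9) patches for 3x3 same convolution."""
    B, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    s = xp.strides
    patches = np.lib.stride_tricks.as_strided(
        xp, shape=(B, C, H, W, 3, 3), strides=(s[0], s[1], s[2], s[3], s[2], s[3])
    )
    return patches.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * W, C * 9)


class Conv3x3:
    """3x3 same-padded convolution with He-initialized weights."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float32):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.W = (rng.normal(size=(c_in * 9, c_out)) * scale).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, C, H, Wd = x.shape
        cols = _im2col(x)
        out = cols @ self.W + self.b
        if train:
            self._cache = (cols, x.shape)
        return out.reshape(B, H, Wd, -1).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        cols, (B, C, H, Wd) = self._cache
        g = grad.transpose(0, 2, 3, 1).reshape(B * H * Wd, -1)
        dW = cols.T @ g
        db = g.sum(axis=0)
        # input gradient = correlation of grad with spatially flipped kernels
        Wk = self.W.reshape(C, 3, 3, -1)
        Wflip = Wk[:, ::-1, ::-1, :].transpose(3, 1, 2, 0).reshape(-1, C)
        gcols = _im2col(grad)
        dx = (gcols @ Wflip).reshape(B, H, Wd, C).transpose(0, 3, 1, 2)
        return dx, dW, db

    @property
    def params(self):
        return [self.W, self.b]


def relu_forward(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def maxpool_forward(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    B, C, H, W = x.shape
    xr = x.reshape(B, C, H // 2, 2, W // 2, 2)
    out = xr.max(axis=(3, 5))
    mask = xr == out[:, :, :, None, :, None]
    # break ties deterministically: keep only the first maximal position
    flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H // 2, W // 2, 4)
    first = np.cumsum(flat, axis=-1) == 1
    mask = (flat & first).reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return out, np.ascontiguousarray(mask)


def maxpool_backward(grad: np.ndarray, mask: np.ndarray) -> np.ndarray:
    B, C, Hh, _, Wh, _ = mask.shape
    g = mask * grad[:, :, :, None, :, None]
    return g.reshape(B, C, Hh * 2, Wh * 2)


def upsample_forward(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=2).repeat(2, axis=3)


def upsample_backward(grad: np.ndarray) -> np.ndarray:
    B, C, H, W = grad.shape
    return grad.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


# ------------------------------------------------------------------ unet


class _Level:
    """One encoder or decoder level: two conv+ReLU blocks."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float32):
        self.conv1 = Conv3x3(c_in, c_out, rng, dtype)
        self.conv2 = Conv3x3(c_out, c_out, rng, dtype)
        self._a1 = self._a2 = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        a1 = relu_forward(self.conv1.forward(x, train))
        a2 = relu_forward(self.conv2.forward(a1, train))
        if train:
            self._a1, self._a2 = a1, a2
        return a2

    def backward(self, grad: np.ndarray, grads: list) -> np.ndarray:
        grad = grad * (self._a2 > 0)
        grad, dW2, db2 = self.conv2.backward(grad)
        grad = grad * (self._a1 > 0)
        grad, dW1, db1 = self.conv1.backward(grad)
        grads.extend([dW2, db2, dW1, db1])
        return grad


class UNet:
    """Configurable U-Net; ``skip_connections=False`` gives the plain
    autoencoder ablation."""

    def __init__(self, config: UNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        dt = config.np_dtype
        ch = [config.base_channels * (1 << i) for i in range(config.depth + 1)]
        self.enc = [
            _Level(1 if i == 0 else ch[i - 1], ch[i], rng, dt) for i in range(config.depth)
        ]
        self.bottleneck = _Level(ch[config.depth - 1], ch[config.depth], rng, dt)
        self.dec = []
        for i in reversed(range(config.depth)):
            c_in = ch[i + 1] + (ch[i] if config.skip_connections else 0)
            self.dec.append(_Level(c_in, ch[i], rng, dt))
        # final 1x1 projection to a single sigmoid channel (as a 3x3 conv
        # with centre-only support would be wasteful; true 1x1 here)
        self.head_W = (rng.normal(size=(ch[0], 1)) * np.sqrt(2.0 / ch[0])).astype(dt)
        self.head_b = np.zeros(1, dtype=dt)
        self._train_cache = None
        self._opt_state = None

    # -- parameter bookkeeping -------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        ps: list[np.ndarray] = []
        for lvl in [*self.enc, self.bottleneck, *self.dec]:
            for conv in (lvl.conv1, lvl.conv2):
                ps += conv.params
        ps += [self.head_W, self.head_b]
        return ps

    # -- forward / backward ----------------------------------------------
    def forward(
        self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        """Logits-to-sigmoid output in [0, 1]; x is (B, 1, H, W) float32."""
        cfg = self.config
        skips, pools, drops = [], [], []
        h = x.astype(cfg.np_dtype)
        for i, lvl in enumerate(self.enc):
            a = lvl.forward(h, train)
            skips.append(a)
            h, pmask = maxpool_forward(a)
            pools.append(pmask)
            if i in cfg.dropout_levels and cfg.dropout_rate > 0 and train:
                keep = (rng.random(h.shape) >= cfg.dropout_rate).astype(cfg.np_dtype)
                h = h * keep / (1.0 - cfg.dropout_rate)
                drops.append(keep)
            else:
                drops.append(None)
        h = self.bottleneck.forward(h, train)
        cats = []
        for j, lvl in enumerate(self.dec):
            h = upsample_forward(h)
            if cfg.skip_connections:
                skip = skips[cfg.depth - 1 - j]
                h = np.concatenate([h, skip], axis=1)
                cats.append(h.shape[1] - skip.shape[1])
            else:
                cats.append(None)
            h = lvl.forward(h, train)
        B, C, H, W = h.shape
        logits = (h.transpose(0, 2, 3, 1).reshape(-1, C) @ self.head_W + self.head_b)
        logits = logits.reshape(B, H, W, 1).transpose(0, 3, 1, 2)
        out = 1.0 / (1.0 + np.exp(-logits))
        if train:
            self._train_cache = (x.astype(cfg.np_dtype), h, pools, drops, cats, out)
        return out

    def backward(self, dlogits: np.ndarray) -> list[np.ndarray]:
        """Gradients w.r.t. parameters, in the order of :meth:`parameters`.

        ``dlogits`` is dLoss/dlogits (sigmoid+BCE collapse to out - target).
        """
        cfg = self.config
        x, h_last, pools, drops, cats, _ = self._train_cache
        B, C, H, W = h_last.shape
        g = dlogits.transpose(0, 2, 3, 1).reshape(-1, 1).astype(cfg.np_dtype)
        hl = h_last.transpose(0, 2, 3, 1).reshape(-1, C)
        dhead_W = hl.T @ g
        dhead_b = g.sum(axis=0)
        grad = (g @ self.head_W.T).reshape(B, H, W, C).transpose(0, 3, 1, 2)
        rev: list[np.ndarray] = []  # gradients accumulated in backward order
        skip_grads: dict[int, np.ndarray] = {}
        for j in reversed(range(len(self.dec))):
            grad = self.dec[j].backward(grad, rev)
            if cfg.skip_connections:
                c_up = cats[j]
                skip_grads[cfg.depth - 1 - j] = grad[:, c_up:]
                grad = grad[:, :c_up]
            grad = upsample_backward(grad)
        grad = self.bottleneck.backward(grad, rev)
        for i in reversed(range(len(self.enc))):
            keep = drops[i]
            if keep is not None:
                grad = grad * keep / (1.0 - cfg.dropout_rate)
            grad = maxpool_backward(grad, pools[i])
            if cfg.skip_connections:
                grad = grad + skip_grads[i]
            grad = self.enc[i].backward(grad, rev)
        # map backward-order gradients onto parameters() order; rev holds
        # [dW2, db2, dW1, db1] per level in the order the levels were visited
        ordered: list[np.ndarray] = []
        levels = [*self.enc, self.bottleneck, *self.dec]
        per_level = {}
        k = 0
        visited = [*reversed(self.dec)] + [self.bottleneck] + [*reversed(self.enc)]
        for lvl in visited:
            per_level[id(lvl)] = rev[k : k + 4]  # [dW2, db2, dW1, db1]
            k += 4
        for lvl in levels:
            dW2, db2, dW1, db1 = per_level[id(lvl)]
            ordered += [dW1, db1, dW2, db2]
        ordered += [dhead_W, dhead_b]
        return ordered


# ------------------------------------------------------------- training


def bce_loss(output: np.ndarray, target: np.ndarray, eps: float = 1e-7) -> float:
    o = np.clip(output, eps, 1.0 - eps)
    return float(-(target * np.log(o) + (1.0 - target) * np.log(1.0 - o)).mean())


@dataclass
class TrainedRestorer:
    """Trained network with its loss history and config snapshot."""

    net: UNet
    history: list[dict] = field(default_factory=list)

    @property
    def config(self) -> UNetConfig:
        return self.net.config

    def restore(self, corrupted: np.ndarray) -> np.ndarray:
        """Deterministic inference (dropout off) on one normalized pattern
        or a batch; preserves the input's leading shape."""
        arr = np.asarray(corrupted, dtype=np.float32)
        squeeze = arr.ndim == 2
        if squeeze:
            arr = arr[None]
        n = self.config.input_side
        if arr.shape[-2:] != (n, n):
            raise ValueError("input side does not match the trained configuration")
        if arr.min() < -1e-6 or arr.max() > 1 + 1e-6:
            raise ValueError("restore expects normalized inputs in [0, 1]")
        out = self.net.forward(arr[:, None], train=False)[:, 0]
        return out[0] if squeeze else out

    def save(self, path: str) -> None:
        cfg = asdict(self.config)
        cfg["dropout_levels"] = list(cfg["dropout_levels"])
        np.savez_compressed(
            path,
            *self.net.parameters(),
            config=json.dumps(cfg),
            history=json.dumps(self.history),
        )

    @classmethod
    def load(cls, path: str) -> "TrainedRestorer":
        data = np.load(path, allow_pickle=False)
        cfg = json.loads(str(data["config"]))
        cfg["dropout_levels"] = tuple(cfg["dropout_levels"])
        net = UNet(UNetConfig(**cfg))
        params = net.parameters()
        for i, p in enumerate(params):
            p[...] = data[f"arr_{i}"]
        obj = cls(net, json.loads(str(data["history"])))
        return obj


def train(
    net: UNet,
    inputs: np.ndarray,
    targets: np.ndarray,
    config: UNetConfig | None = None,
    val_inputs: np.ndarray | None = None,
    val_targets: np.ndarray | None = None,
    verbose: bool = False,
) -> TrainedRestorer:
    """Adam + pixel-mean BCE training loop.

    ``inputs``/``targets`` are (N, H, W) normalized arrays in [0, 1].
    Returns the trained restorer with per-epoch train/validation BCE.
    Raises on NaN loss.
    """
    cfg = config or net.config
    rng = np.random.default_rng(cfg.seed + 1)
    drop_rng = np.random.default_rng(cfg.seed + 2)
    dt = cfg.np_dtype
    x = np.asarray(inputs, dtype=dt)[:, None]
    y = np.asarray(targets, dtype=dt)[:, None]
    if x.min() < 0 or x.max() > 1 + 1e-6 or y.min() < 0 or y.max() > 1 + 1e-6:
        raise ValueError("training data must lie in [0, 1]")
    params = net.parameters()
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    t = 0
    history = []
    n = x.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            out = net.forward(xb, train=True, rng=drop_rng)
            loss = bce_loss(out, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(f"NaN/inf loss at epoch {epoch}, step {n_batches}")
            epoch_loss += loss
            n_batches += 1
            # d(BCE)/dlogits = (sigmoid - target) / n_pixels
            dlogits = (out - yb) / out[0].size
            grads = net.backward(dlogits)
            t += 1
            lr_t = cfg.learning_rate * np.sqrt(1 - cfg.beta2 ** t) / (1 - cfg.beta1 ** t)
            for p, g, mi, vi in zip(params, grads, m, v):
                g = g.astype(p.dtype) / xb.shape[0]
                mi *= cfg.beta1
                mi += (1 - cfg.beta1) * g
                vi *= cfg.beta2
                vi += (1 - cfg.beta2) * g * g
                p -= lr_t * mi / (np.sqrt(vi) + 1e-8)
        rec = {"epoch": epoch, "train_bce": epoch_loss / max(n_batches, 1)}
        if val_inputs is not None:
            vo = net.forward(np.asarray(val_inputs, np.float32)[:, None], train=False)
            rec["val_bce"] = bce_loss(vo, np.asarray(val_targets, np.float32)[:, None])
        history.append(rec)
        if verbose:
            print(f"epoch {epoch}: " + ", ".join(f"{k}={v:.5f}" for k, v in rec.items() if k != "epoch"))
    return TrainedRestorer(net, history)


def steps_per_epoch(n_total: int, validation_fraction: float, batch_size: int) -> int:
    """ceil(n_train / batch): split bookkeeping for the training loop."""
    n_train = n_total - int(round(n_total * validation_fraction))
    return -(-n_train // batch_size)
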