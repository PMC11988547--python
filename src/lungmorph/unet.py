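"""A small U-shaped encoder–decoder for nucleus foreground probability maps.

Pure-NumPy implementation (im2col convolutions, manual backprop, Adam) of a
scaled-down U-Net: single 3×3 convolution per block, 2×2 max-pool downsampling,
nearest-neighbour upsampling with skip concatenation, and a 1×1 output head
with a sigmoid.  The default depth/width (2 pooling levels, 8 base channels)
keeps CPU training on small synthetic tiles in the seconds-to-minutes range;
both are configurable.

Training minimises per-pixel binary cross-entropy; everything is deterministic
given the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["UNetConfig", "UNet"]


@dataclass
class UNetConfig:
    depth: int = 2            # number of pooling levels
    base_channels: int = 8
    in_channels: int = 3
    learning_rate: float = 3e-3
    epochs: int = 20
    batch_size: int = 4
    seed: int = 0


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """3×3 same-padding convolution.  x: (N,H,W,C), w: (3,3,C,F)."""
    n, h, ww, c = x.shape
    f = w.shape[-1]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (N,H,W,C,3,3)
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * ww, 9 * c)
    out = cols @ w.transpose(0, 1, 2, 3).reshape(9 * c, f) + b
    cache = (cols, x.shape, w)
    return out.reshape(n, h, ww, f), cache


def _conv_backward(dout: np.ndarray, cache):
    cols, xshape, w = cache
    n, h, ww, c = xshape
    f = w.shape[-1]
    dflat = dout.reshape(n * h * ww, f)
    dw = (cols.T @ dflat).reshape(3, 3, c, f)
    db = dflat.sum(axis=0)
    dcols = (dflat @ w.reshape(9 * c, f).T).reshape(n, h, ww, 3, 3, c)
    dxp = np.zeros((n, h + 2, ww + 2, c))
    for i in range(3):
        for j in range(3):
            dxp[:, i:i + h, j:j + ww, :] += dcols[:, :, :, i, j, :]
    return dxp[:, 1:-1, 1:-1, :], dw, db


def _relu_forward(x):
    out = np.maximum(x, 0.0)
    return out, (x > 0)


def _pool_forward(x):
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
    out = xr.max(axis=(2, 4))
    mask = xr == out[:, :, None, :, None, :]
    count = mask.sum(axis=(2, 4), keepdims=True)
    return out, (mask, count, x.shape)


def _pool_backward(dout, cache):
    mask, count, xshape = cache
    n, h, w, c = xshape
    d = (mask / count) * dout[:, :, None, :, None, :]
    return d.reshape(n, h, w, c)


def _up_forward(x):
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def _up_backward(dout):
    n, h, w, c = dout.shape
    return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class UNet:
    """Tiny U-Net over RGB tiles; outputs per-pixel foreground probability."""

    def __init__(self, config: UNetConfig | None = None):
        self.config = config or UNetConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.params: dict[str, np.ndarray] = {}
        chans = [cfg.in_channels] + [cfg.base_channels * 2 ** i
                                     for i in range(cfg.depth + 1)]
        # encoder blocks 0..depth-1, bottleneck, decoder blocks depth-1..0
        for i in range(cfg.depth):
            self._init_conv(rng, f"enc{i}", chans[i], chans[i + 1])
        self._init_conv(rng, "bottleneck", chans[cfg.depth], chans[cfg.depth + 1])
        for i in reversed(range(cfg.depth)):
            in_c = chans[i + 2] + chans[i + 1]  # upsampled + skip
            self._init_conv(rng, f"dec{i}", in_c, chans[i + 1])
        out_c = chans[1]
        self.params["w_out"] = rng.normal(0, np.sqrt(2.0 / out_c), (out_c, 1))
        self.params["b_out"] = np.zeros(1)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0
        self.loss_history: list[float] = []

    def _init_conv(self, rng, name, c_in, c_out):
        scale = np.sqrt(2.0 / (9 * c_in))
        self.params[f"w_{name}"] = rng.normal(0, scale, (3, 3, c_in, c_out))
        self.params[f"b_{name}"] = np.zeros(c_out)

    # -- forward / backward ------------------------------------------------
    def _forward(self, x: np.ndarray):
        cfg = self.config
        caches: dict[str, object] = {}
        skips = []
        h = x
        for i in range(cfg.depth):
            h, caches[f"conv_enc{i}"] = _conv_forward(
                h, self.params[f"w_enc{i}"], self.params[f"b_enc{i}"])
            h, caches[f"relu_enc{i}"] = _relu_forward(h)
            skips.append(h)
            h, caches[f"pool{i}"] = _pool_forward(h)
        h, caches["conv_bottleneck"] = _conv_forward(
            h, self.params["w_bottleneck"], self.params["b_bottleneck"])
        h, caches["relu_bottleneck"] = _relu_forward(h)
        for i in reversed(range(cfg.depth)):
            h = _up_forward(h)
            caches[f"skip_ch{i}"] = skips[i].shape[-1]
            h = np.concatenate([h, skips[i]], axis=-1)
            h, caches[f"conv_dec{i}"] = _conv_forward(
                h, self.params[f"w_dec{i}"], self.params[f"b_dec{i}"])
            h, caches[f"relu_dec{i}"] = _relu_forward(h)
        n, hh, ww, c = h.shape
        caches["head_in"] = h
        logits = (h.reshape(-1, c) @ self.params["w_out"]
                  + self.params["b_out"]).reshape(n, hh, ww)
        return logits, caches

    def _backward(self, dlogits: np.ndarray, caches) -> dict[str, np.ndarray]:
        cfg = self.config
        grads: dict[str, np.ndarray] = {}
        h_in = caches["head_in"]
        n, hh, ww, c = h_in.shape
        dflat = dlogits.reshape(-1, 1)
        grads["w_out"] = h_in.reshape(-1, c).T @ dflat
        grads["b_out"] = dflat.sum(axis=0)
        dh = (dflat @ self.params["w_out"].T).reshape(n, hh, ww, c)
        dskips: dict[int, np.ndarray] = {}
        for i in range(cfg.depth):
            dh = dh * caches[f"relu_dec{i}"]
            dh, grads[f"w_dec{i}"], grads[f"b_dec{i}"] = _conv_backward(
                dh, caches[f"conv_dec{i}"])
            sc = caches[f"skip_ch{i}"]
            dskips[i] = dh[..., -sc:]
            dh = _up_backward(dh[..., :-sc])
        dh = dh * caches["relu_bottleneck"]
        dh, grads["w_bottleneck"], grads["b_bottleneck"] = _conv_backward(
            dh, caches["conv_bottleneck"])
        for i in reversed(range(cfg.depth)):
            dh = _pool_backward(dh, caches[f"pool{i}"])
            dh = dh + dskips[i]
            dh = dh * caches[f"relu_enc{i}"]
            dh, grads[f"w_enc{i}"], grads[f"b_enc{i}"] = _conv_backward(
                dh, caches[f"conv_enc{i}"])
        return grads

    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        self._adam_t += 1
        lr, b1, b2, eps = self.config.learning_rate, 0.9, 0.999, 1e-8
        t = self._adam_t
        for k, g in grads.items():
            g = g.reshape(self.params[k].shape)
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            mhat = self._adam_m[k] / (1 - b1 ** t)
            vhat = self._adam_v[k] / (1 - b2 ** t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- public API --------------------------------------------------------
    def fit(self, tiles: np.ndarray, masks: np.ndarray) -> list[float]:
        """Train on (N,H,W,3) uint8 tiles and (N,H,W) {0,1} masks.

        Returns the per-epoch mean BCE loss history (also stored on
        ``loss_history``).  H and W must be divisible by 2**depth.
        """
        cfg = self.config
        x = np.asarray(tiles, dtype=np.float64) / 255.0
        y = np.asarray(masks, dtype=np.float64)
        if x.shape[:3] != y.shape:
            raise ValueError("tiles and masks must align in N, H, W")
        div = 2 ** cfg.depth
        if x.shape[1] % div or x.shape[2] % div:
            raise ValueError(f"tile size must be divisible by {div}")
        rng = np.random.default_rng(cfg.seed + 1)
        n = x.shape[0]
        for _epoch in range(cfg.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xb, yb = x[idx], y[idx]
                logits, caches = self._forward(xb)
                # BCE with logits: softplus(z) - y z + softplus clamp-free form
                z = logits
                loss = np.mean(np.logaddexp(0.0, z) - yb * z)
                prob = 1.0 / (1.0 + np.exp(-z))
                dlogits = (prob - yb) / z.size
                grads = self._backward(dlogits, caches)
                self._adam_step(grads)
                losses.append(loss)
            self.loss_history.append(float(np.mean(losses)))
        return self.loss_history

    def predict_prob(self, tile: np.ndarray) -> np.ndarray:
        """Foreground probability map with the tile's spatial shape."""
        x = np.asarray(tile, dtype=np.float64) / 255.0
        single = x.ndim == 3
        if single:
            x = x[None]
        logits, _ = self._forward(x)
        prob = 1.0 / (1.0 + np.exp(-logits))
        return prob[0] if single else prob

    def save(self, path: str | Path) -> None:
        cfg = self.config
        np.savez(path, __config__=np.array([cfg.depth, cfg.base_channels,
                                            cfg.in_channels, cfg.seed]),
                 **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "UNet":
        data = np.load(path)
        depth, base, in_c, seed = (int(v) for v in data["__config__"])
        model = cls(UNetConfig(depth=depth, base_channels=base,
                               in_channels=in_c, seed=seed))
        for k in model.params:
            model.params[k] = data[k]
        return model
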