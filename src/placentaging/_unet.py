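"""Compact 2D U-net in NumPy (CPU, float32).

Encoder-decoder with 3x3 "same" convolutions, ReLU, 2x2 max-pooling,
nearest-neighbour upsampling and skip concatenation; a 1x1 output convolution
produces per-pixel logits for sigmoid/binary cross-entropy training with the
Adam optimizer. Convolutions run as im2col matrix products, so training a
desk-scale network (depth 3, 8-16 base filters, 64x64 patches) is practical
on a single CPU core.

All randomness (weight init) flows through a seeded Generator; forward,
backward and the optimizer are deterministic, so training is reproducible
given the seed and the patch stream.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["UNet", "Adam", "bce_with_logits"]


def _conv3x3_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """x: (B, C, H, W); W: (C*9, F); b: (F,). Returns (out (B,F,H,W), cols)."""
    B, C, H, Wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # (B, C, H, W, 3, 3) -> (B, H*W, C*9)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(B, H * Wd, C * 9)
    out = cols @ W + b
    return out.reshape(B, H, Wd, -1).transpose(0, 3, 1, 2), cols


def _conv3x3_backward(dout: np.ndarray, cols: np.ndarray, W: np.ndarray, x_shape):
    B, C, H, Wd = x_shape
    dflat = dout.transpose(0, 2, 3, 1).reshape(B, H * Wd, -1)
    dW = np.einsum("bnc,bnf->cf", cols, dflat, optimize=True)
    db = dflat.sum(axis=(0, 1))
    dcols = (dflat @ W.T).reshape(B, H, Wd, C, 3, 3)
    dxp = np.zeros((B, C, H + 2, Wd + 2), dtype=dout.dtype)
    for ki in range(3):
        for kj in range(3):
            dxp[:, :, ki : ki + H, kj : kj + Wd] += dcols[:, :, :, :, ki, kj].transpose(
                0, 3, 1, 2
            )
    return dxp[:, :, 1:-1, 1:-1], dW, db


def _pool2_forward(x: np.ndarray):
    B, C, H, W = x.shape
    xr = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        B, C, H // 2, W // 2, 4
    )
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _pool2_backward(dout: np.ndarray, idx: np.ndarray, x_shape):
    B, C, H, W = x_shape
    dxr = np.zeros((B, C, H // 2, W // 2, 4), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    return dxr.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        B, C, H, W
    )


def _up2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _up2_backward(dout: np.ndarray) -> np.ndarray:
    B, C, H, W = dout.shape
    return dout.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


def bce_with_logits(logits: np.ndarray, target: np.ndarray):
    """Mean binary cross-entropy on logits; returns (loss, dlogits)."""
    z, y = logits, target
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    p = expit(z)
    n = z.size
    return float(loss.mean()), ((p - y) / n).astype(z.dtype)


class Adam:
    """Standard Adam (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: dict, lr: float = 1e-4):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        corr1 = 1 - b1**self.t
        corr2 = 1 - b2**self.t
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            params[k] -= self.lr * (self.m[k] / corr1) / (np.sqrt(self.v[k] / corr2) + eps)


class UNet:
    """U-net with ``depth`` resolution levels and ``base`` filters at level 0."""

    def __init__(self, depth: int = 3, base: int = 8, in_channels: int = 1, seed: int = 0):
        self.depth = depth
        self.base = base
        self.in_channels = in_channels
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}

        def add_conv(name: str, cin: int, cout: int, k: int = 3) -> None:
            fan_in = cin * k * k
            self.params[f"{name}.W"] = (
                rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, cout))
            ).astype(np.float32)
            self.params[f"{name}.b"] = np.zeros(cout, dtype=np.float32)

        ch = in_channels
        self._enc_ch = []
        for d in range(depth - 1):
            f = base * 2**d
            add_conv(f"enc{d}a", ch, f)
            add_conv(f"enc{d}b", f, f)
            self._enc_ch.append(f)
            ch = f
        f = base * 2 ** (depth - 1)
        add_conv("bota", ch, f)
        add_conv("botb", f, f)
        ch = f
        for d in reversed(range(depth - 1)):
            f = base * 2**d
            add_conv(f"dec{d}a", ch + self._enc_ch[d], f)
            add_conv(f"dec{d}b", f, f)
            ch = f
        add_conv("out", ch, 1, k=1)

    # -- forward / backward --------------------------------------------------

    def forward(self, x: np.ndarray):
        """x: (B, C, H, W) float32 with H, W divisible by 2**(depth-1)."""
        tape = []

        def conv_relu(h, name, relu=True):
            out, cols = _conv3x3_forward(h, self.params[f"{name}.W"], self.params[f"{name}.b"])
            mask = None
            if relu:
                mask = out > 0
                out = out * mask
            tape.append(("conv", name, cols, h.shape, mask))
            return out

        h = x.astype(np.float32)
        skips = []
        for d in range(self.depth - 1):
            h = conv_relu(h, f"enc{d}a")
            h = conv_relu(h, f"enc{d}b")
            skips.append(h)
            h, idx = _pool2_forward(h)
            tape.append(("pool", idx, skips[-1].shape))
        h = conv_relu(h, "bota")
        h = conv_relu(h, "botb")
        for d in reversed(range(self.depth - 1)):
            h = _up2(h)
            tape.append(("up", None, None))
            s = skips[d]
            h = np.concatenate([s, h], axis=1)
            tape.append(("concat", s.shape[1], None))
            h = conv_relu(h, f"dec{d}a")
            h = conv_relu(h, f"dec{d}b")
        # 1x1 output conv as a matrix product over channels
        B, C, H, W = h.shape
        flat = h.transpose(0, 2, 3, 1).reshape(-1, C)
        logits = flat @ self.params["out.W"] + self.params["out.b"]
        tape.append(("out1x1", flat, h.shape, None))
        return logits.reshape(B, H, W, 1).transpose(0, 3, 1, 2), tape

    def backward(self, tape, dlogits: np.ndarray) -> dict:
        grads = {k: None for k in self.params}
        op = tape.pop()
        assert op[0] == "out1x1"
        _, flat, h_shape, _ = op
        B, C, H, W = h_shape
        dflat = dlogits.transpose(0, 2, 3, 1).reshape(-1, 1)
        grads["out.W"] = flat.T @ dflat
        grads["out.b"] = dflat.sum(axis=0)
        dh = (dflat @ self.params["out.W"].T).reshape(B, H, W, C).transpose(0, 3, 1, 2)

        dskips: dict[int, np.ndarray] = {}
        # decoder concats unwind from level 0 upward; encoder pools from the
        # deepest level down — track the two counters independently
        concat_level = 0
        pool_level = self.depth - 2
        while tape:
            kind = tape[-1][0]
            if kind == "conv":
                _, name, cols, x_shape, mask = tape.pop()
                if mask is not None:
                    dh = dh * mask
                dh, dW, db = _conv3x3_backward(dh, cols, self.params[f"{name}.W"], x_shape)
                grads[f"{name}.W"] = dW
                grads[f"{name}.b"] = db
            elif kind == "concat":
                _, n_skip, _ = tape.pop()
                dskips[concat_level] = dh[:, :n_skip]
                dh = dh[:, n_skip:]
                concat_level += 1
            elif kind == "up":
                tape.pop()
                dh = _up2_backward(dh)
            elif kind == "pool":
                _, idx, x_shape = tape.pop()
                dh = _pool2_backward(dh, idx, x_shape)
                dh = dh + dskips.pop(pool_level, 0.0)
                pool_level -= 1
            else:  # pragma: no cover
                raise RuntimeError(f"unknown tape op {kind}")
        return grads

    # -- persistence ---------------------------------------------------------

    def state_dict(self) -> dict:
        return dict(self.params)

    def load_state_dict(self, state: dict) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float32)
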