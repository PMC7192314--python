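"""Minimal NumPy convolutional-network engine.

Just enough machinery for a small 2-conv / 2-FC softmax classifier:
im2col-based valid convolution, 2x2 max pooling, dense layers, ReLU,
softmax cross-entropy, and plain SGD with momentum.  Everything is
deterministic given the RNG seed.  Layout is (N, C, H, W).
"""

from __future__ import annotations

import numpy as np

__all__ = ["SmallCNN", "conv2d_forward", "maxpool2_forward", "sgd_update"]


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """View (N, C, H, W) as (N, C*kh*kw, OH*OW) patch columns."""
    N, C, H, W = x.shape
    OH, OW = H - kh + 1, W - kw + 1
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x, shape=(N, C, OH, OW, kh, kw), strides=(s0, s1, s2, s3, s2, s3),
        writeable=False,
    )
    # (N, C, kh, kw, OH, OW) -> (N, C*kh*kw, OH*OW)
    return windows.transpose(0, 1, 4, 5, 2, 3).reshape(N, C * kh * kw, OH * OW)


def conv2d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Valid correlation of (N,C,H,W) with (F,C,kh,kw) kernels."""
    N, C, H, Wd = x.shape
    F, _, kh, kw = W.shape
    cols = _im2col(x, kh, kw)
    out = (W.reshape(F, -1) @ cols).reshape(N, F, H - kh + 1, Wd - kw + 1)
    out += b[None, :, None, None]
    return out, cols


def conv2d_backward(dout, cols, x_shape, W):
    N, C, H, Wd = x_shape
    F, _, kh, kw = W.shape
    OH, OW = H - kh + 1, Wd - kw + 1
    dflat = dout.reshape(N, F, OH * OW)
    dW = np.einsum("nfl,ncl->fc", dflat, cols).reshape(W.shape)
    db = dout.sum(axis=(0, 2, 3))
    dcols = np.einsum("fc,nfl->ncl", W.reshape(F, -1), dflat)
    # col2im: scatter-add patch columns back onto the image
    dx = np.zeros(x_shape)
    dcols = dcols.reshape(N, C, kh, kw, OH, OW)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i:i + OH, j:j + OW] += dcols[:, :, i, j]
    return dx, dW, db


def maxpool2_forward(x: np.ndarray):
    """2x2 max pooling with stride 2 (even spatial dims required)."""
    N, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2 needs even spatial dimensions")
    r = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    win = r.reshape(N, C, H // 2, W // 2, 4)
    out = win.max(axis=-1)
    mask = win == out[..., None]
    # break ties toward the first max so the backward pass is well-defined
    first = mask & (np.cumsum(mask, axis=-1) == 1)
    return out, first


def maxpool2_backward(dout, mask, x_shape):
    N, C, H, W = x_shape
    d = mask * dout[..., None]  # (N, C, H/2, W/2, 4)
    d = d.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return d.reshape(N, C, H, W)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def sgd_update(params, grads, velocity, lr: float, momentum: float) -> None:
    for key in params:
        velocity[key] = momentum * velocity[key] - lr * grads[key]
        params[key] += velocity[key]


class SmallCNN:
    """2 conv (each + ReLU + 2x2 max-pool) -> FC + ReLU -> FC -> softmax.

    Parameters are He-initialized from the given seed; training and
    inference are fully deterministic for a fixed seed and input order.
    Lateral surround modulation can be injected at the post-ReLU,
    pre-pool activations of either conv layer via ``modulators``.
    """

    def __init__(
        self,
        in_shape: tuple[int, int, int] = (1, 28, 28),
        conv_channels: tuple[int, int] = (32, 64),
        kernel_sizes: tuple[int, int] = (5, 5),
        fc_width: int = 128,
        n_classes: int = 10,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        C, H, W = in_shape
        c1, c2 = conv_channels
        k1, k2 = kernel_sizes
        h1, w1 = (H - k1 + 1) // 2, (W - k1 + 1) // 2
        h2, w2 = (h1 - k2 + 1) // 2, (w1 - k2 + 1) // 2
        if h2 < 1 or w2 < 1:
            raise ValueError("input too small for the architecture")
        flat = c2 * h2 * w2

        def he(shape, fan_in):
            return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)

        self.params = {
            "W1": he((c1, C, k1, k1), C * k1 * k1),
            "b1": np.zeros(c1),
            "W2": he((c2, c1, k2, k2), c1 * k2 * k2),
            "b2": np.zeros(c2),
            "W3": he((flat, fc_width), flat),
            "b3": np.zeros(fc_width),
            "W4": he((fc_width, n_classes), fc_width),
            "b4": np.zeros(n_classes),
        }
        self.velocity = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.in_shape = in_shape
        self.seed = seed
        self.n_classes = n_classes

    # ---------------------------------------------------------------- forward
    def forward(self, x: np.ndarray, modulators=None, return_cache: bool = False):
        """Class probabilities for a batch (N, C, H, W).

        ``modulators`` is an optional pair of callables applied to the
        post-ReLU activations of conv layer 1 and 2 (either may be None).
        """
        p = self.params
        mods = modulators or (None, None)

        z1, cols1 = conv2d_forward(x, p["W1"], p["b1"])
        a1 = np.maximum(z1, 0.0)
        m1 = mods[0](a1) if mods[0] is not None else a1
        p1, mask1 = maxpool2_forward(m1)

        z2, cols2 = conv2d_forward(p1, p["W2"], p["b2"])
        a2 = np.maximum(z2, 0.0)
        m2 = mods[1](a2) if mods[1] is not None else a2
        p2, mask2 = maxpool2_forward(m2)

        flat = p2.reshape(x.shape[0], -1)
        z3 = flat @ p["W3"] + p["b3"]
        a3 = np.maximum(z3, 0.0)
        logits = a3 @ p["W4"] + p["b4"]
        probs = softmax(logits)
        if not return_cache:
            return probs
        cache = dict(x=x, z1=z1, cols1=cols1, a1=a1, p1=p1, mask1=mask1,
                     z2=z2, cols2=cols2, a2=a2, p2=p2, mask2=mask2,
                     flat=flat, z3=z3, a3=a3, logits=logits, probs=probs)
        return probs, cache

    def conv_activations(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Post-ReLU, pre-pool activations of the two conv layers."""
        p = self.params
        z1, _ = conv2d_forward(x, p["W1"], p["b1"])
        a1 = np.maximum(z1, 0.0)
        p1, _ = maxpool2_forward(a1)
        z2, _ = conv2d_forward(p1, p["W2"], p["b2"])
        a2 = np.maximum(z2, 0.0)
        return a1, a2

    # --------------------------------------------------------------- backward
    def loss_and_gradients(self, x: np.ndarray, y: np.ndarray):
        """Mean cross-entropy and parameter gradients (no modulation)."""
        p = self.params
        probs, c = self.forward(x, return_cache=True)
        N = x.shape[0]
        eps = 1e-12
        loss = -np.log(probs[np.arange(N), y] + eps).mean()

        dlogits = probs.copy()
        dlogits[np.arange(N), y] -= 1.0
        dlogits /= N

        grads = {}
        grads["W4"] = c["a3"].T @ dlogits
        grads["b4"] = dlogits.sum(axis=0)
        da3 = dlogits @ p["W4"].T
        dz3 = da3 * (c["z3"] > 0)
        grads["W3"] = c["flat"].T @ dz3
        grads["b3"] = dz3.sum(axis=0)
        dflat = dz3 @ p["W3"].T
        dp2 = dflat.reshape(c["p2"].shape)

        da2 = maxpool2_backward(dp2, c["mask2"], c["a2"].shape)
        dz2 = da2 * (c["z2"] > 0)
        dp1, grads["W2"], grads["b2"] = conv2d_backward(
            dz2, c["cols2"], c["p1"].shape, p["W2"]
        )
        da1 = maxpool2_backward(dp1, c["mask1"], c["a1"].shape)
        dz1 = da1 * (c["z1"] > 0)
        _, grads["W1"], grads["b1"] = conv2d_backward(
            dz1, c["cols1"], c["x"].shape, p["W1"]
        )
        return loss, grads

    def train_epoch(self, x, y, rng, batch_size=64, lr=0.1, momentum=0.9):
        """One shuffled pass of minibatch SGD; returns the mean loss."""
        order = rng.permutation(len(x))
        losses = []
        for start in range(0, len(x), batch_size):
            idx = order[start:start + batch_size]
            loss, grads = self.loss_and_gradients(x[idx], y[idx])
            sgd_update(self.params, grads, self.velocity, lr, momentum)
            losses.append(loss)
        return float(np.mean(losses))

    def predict(self, x, modulators=None, batch_size=256) -> np.ndarray:
        out = []
        for start in range(0, len(x), batch_size):
            probs = self.forward(x[start:start + batch_size], modulators=modulators)
            out.append(probs.argmax(axis=1))
        return np.concatenate(out) if out else np.empty(0, dtype=int)

    def state_dict(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k, v in state.items():
            self.params[k] = np.array(v)
        self.velocity = {k: np.zeros_like(v) for k, v in self.params.items()}
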