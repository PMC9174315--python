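"""Minimal neural-network primitives used by the MIL and segmentation models.

Everything here is plain NumPy with hand-written backprop. The networks are
deliberately small (two conv blocks, global average pooling) so that training a
full multi-magnification ensemble stays in the minutes range on one CPU core.

Conventions
-----------
* images are ``(N, H, W, C)`` float32 arrays in [0, 1]
* convolutions use 3x3 kernels, stride 1, reflect padding (so a constant input
  stays constant everywhere — no zero-pad edge artifacts)
* pooling is 2x2 average pooling
* parameters live in plain dicts ``{name: ndarray}``
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "TinyCNN",
    "GatedAttentionHead",
    "LogisticHead",
    "Adam",
    "bce_with_logits",
    "sigmoid",
]


def sigmoid(x):
    out = np.empty_like(x, dtype=x.dtype)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logit: float, target: float) -> tuple[float, float]:
    """Binary cross-entropy for a single bag. Returns (loss, dloss/dlogit)."""
    z = float(logit)
    t = float(target)
    loss = max(z, 0.0) - z * t + np.log1p(np.exp(-abs(z)))
    grad = float(sigmoid(np.asarray([z]))[0] - t)
    return loss, grad


# ---------------------------------------------------------------------------
# layer primitives
# ---------------------------------------------------------------------------


def _pad_reflect(x):
    return np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)), mode="reflect")


def conv3x3_forward(x, W, b):
    """x (N,H,W,Cin), W (3,3,Cin,Cout), b (Cout,) -> y (N,H,W,Cout).

    Implemented as nine shifted matmuls (no im2col tensor) for speed.
    """
    n, h, w, _ = x.shape
    xp = _pad_reflect(x)
    y = np.empty((n, h, w, W.shape[3]), dtype=x.dtype)
    y[:] = b
    for di in range(3):
        for dj in range(3):
            y += xp[:, di:di + h, dj:dj + w, :] @ W[di, dj]
    return y, xp


def conv3x3_backward(dy, W, cache, compute_dx=True):
    xp = cache
    n, h, w, _ = dy.shape
    db = dy.sum(axis=(0, 1, 2))
    dW = np.empty_like(W)
    dyf = np.ascontiguousarray(dy).reshape(-1, dy.shape[3])
    for di in range(3):
        for dj in range(3):
            xs = xp[:, di:di + h, dj:dj + w, :]
            dW[di, dj] = xs.reshape(-1, xs.shape[3]).T @ dyf if xs.flags.c_contiguous \
                else np.ascontiguousarray(xs).reshape(-1, xs.shape[3]).T @ dyf
    if not compute_dx:
        return None, dW, db
    dxpad = np.zeros_like(xp)
    for di in range(3):
        for dj in range(3):
            dxpad[:, di:di + h, dj:dj + w, :] += dy @ W[di, dj].T
    # fold the reflect padding's gradient back onto its mirror pixels
    dx = dxpad[:, 1:-1, 1:-1].copy()
    dx[:, 1, :] += dxpad[:, 0, 1:-1]
    dx[:, -2, :] += dxpad[:, -1, 1:-1]
    dx[:, :, 1] += dxpad[:, 1:-1, 0]
    dx[:, :, -2] += dxpad[:, 1:-1, -1]
    dx[:, 1, 1] += dxpad[:, 0, 0]
    dx[:, 1, -2] += dxpad[:, 0, -1]
    dx[:, -2, 1] += dxpad[:, -1, 0]
    dx[:, -2, -2] += dxpad[:, -1, -1]
    return dx, dW, db


# leaky slope: keeps units trainable if a channel's pre-activations go
# all-negative (all-positive image inputs make plain ReLU prone to dying)
LEAKY_SLOPE = 0.1

# constant input centering applied by TinyCNN (inputs are [0,1] RGB)
INPUT_OFFSET = 0.65


def relu_forward(x):
    pos = x > 0
    return np.where(pos, x, LEAKY_SLOPE * x), pos


def relu_backward(dy, pos):
    return np.where(pos, dy, LEAKY_SLOPE * dy)


def avgpool2_forward(x):
    n, h, w, c = x.shape
    y = x.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))
    return y, (h, w)


def avgpool2_backward(dy, shape):
    h, w = shape
    n, hh, ww, c = dy.shape
    dx = np.broadcast_to(
        dy[:, :, None, :, None, :] * 0.25, (n, hh, 2, ww, 2, c)
    ).reshape(n, h, w, c)
    return dx


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


class TinyCNN:
    """Two conv blocks + global average pooling feature extractor.

    ``(N, S, S, 3) -> (N, feature_dim)`` with ``feature_dim == channels[1]``.
    """

    def __init__(self, channels=(8, 16), dtype=np.float32):
        self.channels = tuple(channels)
        self.dtype = np.dtype(dtype)

    @property
    def feature_dim(self) -> int:
        return self.channels[1]

    def init_params(self, rng: np.random.Generator) -> dict:
        c1, c2 = self.channels
        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(self.dtype)

        return {
            "W1": he((3, 3, 3, c1), 27),
            "b1": np.zeros(c1, dtype=self.dtype),
            "W2": he((3, 3, c1, c2), 9 * c1),
            "b2": np.zeros(c2, dtype=self.dtype),
        }

    def forward(self, params, x):
        """Returns (features, cache). cache["A2"] is the last conv feature map."""
        x = x - np.asarray(INPUT_OFFSET, dtype=x.dtype)
        z1, c1 = conv3x3_forward(x, params["W1"], params["b1"])
        a1, m1 = relu_forward(z1)
        p1, s1 = avgpool2_forward(a1)
        z2, c2 = conv3x3_forward(p1, params["W2"], params["b2"])
        a2, m2 = relu_forward(z2)
        p2, s2 = avgpool2_forward(a2)
        feat = p2.mean(axis=(1, 2))
        cache = {"c1": c1, "m1": m1, "s1": s1, "c2": c2, "m2": m2, "s2": s2,
                 "p2shape": p2.shape, "A2": a2}
        return feat, cache

    def backward(self, params, dfeat, cache, need_dx=False):
        n, hh, ww, c = cache["p2shape"]
        dp2 = np.broadcast_to(
            dfeat[:, None, None, :] / (hh * ww), (n, hh, ww, c)
        ).astype(dfeat.dtype)
        da2 = avgpool2_backward(dp2, cache["s2"])
        dz2 = relu_backward(da2, cache["m2"])
        dp1, dW2, db2 = conv3x3_backward(dz2, params["W2"], cache["c2"])
        da1 = avgpool2_backward(dp1, cache["s1"])
        dz1 = relu_backward(da1, cache["m1"])
        dx, dW1, db1 = conv3x3_backward(dz1, params["W1"], cache["c1"],
                                        compute_dx=need_dx)
        grads = {"W1": dW1, "b1": db1, "W2": dW2, "b2": db2}
        return (grads, dx) if need_dx else (grads, None)

    def grad_wrt_last_conv(self, params, dfeat, cache):
        """Gradient of the scalar objective wrt the last conv activation A2."""
        n, hh, ww, c = cache["p2shape"]
        dp2 = np.broadcast_to(
            dfeat[:, None, None, :] / (hh * ww), (n, hh, ww, c)
        ).astype(dfeat.dtype)
        da2 = avgpool2_backward(dp2, cache["s2"])
        return da2


class GatedAttentionHead:
    """Gated attention pooling + linear bag classifier.

    attention: a = softmax_k( w^T (tanh(H V) * sigmoid(H U)) )
    bag embedding z = sum_k a_k h_k ; bag logit = z . c + b
    """

    def __init__(self, feature_dim: int, hidden_dim: int, dtype=np.float32):
        self.feature_dim = int(feature_dim)
        self.hidden_dim = int(hidden_dim)
        self.dtype = np.dtype(dtype)

    def init_params(self, rng: np.random.Generator) -> dict:
        f, d = self.feature_dim, self.hidden_dim
        sc = 1.0 / np.sqrt(f)
        return {
            "V": (rng.standard_normal((f, d)) * sc).astype(self.dtype),
            "U": (rng.standard_normal((f, d)) * sc).astype(self.dtype),
            "w": (rng.standard_normal(d) / np.sqrt(d)).astype(self.dtype),
            "c": (rng.standard_normal(f) * sc).astype(self.dtype),
            "b": np.zeros((), dtype=self.dtype),
        }

    def forward(self, params, H):
        """H (K, F) -> (attention (K,), embedding (F,), logit, cache)."""
        T = np.tanh(H @ params["V"])
        S = sigmoid(H @ params["U"])
        G = T * S
        e = G @ params["w"]
        e = e - e.max()
        ex = np.exp(e)
        a = ex / ex.sum()
        z = a @ H
        logit = float(z @ params["c"] + params["b"])
        cache = (H, T, S, G, a, z)
        return a, z, logit, cache

    def backward(self, params, dlogit, cache):
        H, T, S, G, a, z = cache
        dz = dlogit * params["c"]
        dc = dlogit * z
        db = np.asarray(dlogit, dtype=z.dtype)
        # z = a @ H
        da = H @ dz
        dH = np.outer(a, dz)
        # softmax backward
        de = a * (da - float(a @ da))
        dG = np.outer(de, params["w"])
        dw = G.T @ de
        dT = dG * S
        dS = dG * T
        dpreT = dT * (1 - T * T)
        dpreS = dS * S * (1 - S)
        dV = H.T @ dpreT
        dU = H.T @ dpreS
        dH += dpreT @ params["V"].T + dpreS @ params["U"].T
        grads = {"V": dV, "U": dU, "w": dw, "c": dc, "b": db}
        return grads, dH


class LogisticHead:
    """Plain linear + sigmoid head for patch-level classification."""

    def __init__(self, feature_dim: int, dtype=np.float32):
        self.feature_dim = int(feature_dim)
        self.dtype = np.dtype(dtype)

    def init_params(self, rng: np.random.Generator) -> dict:
        f = self.feature_dim
        return {
            "c": (rng.standard_normal(f) / np.sqrt(f)).astype(self.dtype),
            "b": np.zeros((), dtype=self.dtype),
        }

    def forward(self, params, H):
        logits = H @ params["c"] + params["b"]
        return logits, H

    def backward(self, params, dlogits, cache):
        H = cache
        grads = {"c": H.T @ dlogits, "b": np.asarray(dlogits.sum(), dtype=H.dtype)}
        dH = np.outer(dlogits, params["c"])
        return grads, dH


class Adam:
    def __init__(self, lr=3e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            g = np.asarray(g, dtype=params[k].dtype)
            if k not in self.m:
                self.m[k] = np.zeros_like(params[k])
                self.v[k] = np.zeros_like(params[k])
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                params[k].dtype
            )
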