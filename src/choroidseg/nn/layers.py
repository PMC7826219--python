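"""Minimal numpy neural-network layers with hand-derived backprop.

Only what the patch classifier needs: 3x3 same-padding convolution
(implemented as nine shifted GEMMs, channels-last), ReLU, cross-channel
local response normalization, and dense layers.  Every layer exposes
``forward`` / ``backward`` and dictionaries of parameters and gradients so
an optimizer can walk the whole network.  Correctness of each backward pass
is pinned by finite-difference tests.
"""

from __future__ import annotations

import numpy as np

try:  # optional: fused channel-window kernel; numpy fallback below
    from numba import njit

    @njit
    def _window_sum_running(a, r):
        # inclusive window [c-r, c+r] along axis 1 of a 2-D array, via a
        # running sum per row; O(N*C) with no temporaries
        N, C = a.shape
        out = np.empty_like(a)
        for i in range(N):
            s = 0.0
            for c in range(min(r + 1, C)):
                s += a[i, c]
            for c in range(C):
                out[i, c] = s
                hi = c + r + 1
                lo = c - r
                if hi < C:
                    s += a[i, hi]
                if lo >= 0:
                    s -= a[i, lo]
        return out

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero padding 1 (spatial size preserved).

    Input/output are channels-last ``(B, H, W, C)``.  The kernel is applied
    as nine shifted matrix products, which keeps memory flat and lets BLAS
    do the work.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float32,
                 first: bool = False):
        super().__init__()
        fan_in = 9 * c_in
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(3, 3, c_in, c_out))
        self.params = {"W": w.astype(dtype), "b": np.zeros(c_out, dtype=dtype)}
        self.first = first  # first layer: no input gradient needed

    def forward(self, x, train=False):
        B, H, Wd, C = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        W = self.params["W"]
        if C <= 4:
            # im2col pays off when 9*C is tiny (the grayscale input layer)
            win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
            col = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
                B * H * Wd, 9 * C
            )
            out = (col @ W.reshape(9 * C, -1) + self.params["b"]).reshape(B, H, Wd, -1)
        else:
            # nine shifted GEMMs on the contiguous padded tensor; no im2col
            # buffer, at the price of ~13% extra FLOPs on the padded border
            flat = xp.reshape(-1, C)
            out = np.empty((B, H, Wd, W.shape[3]), dtype=x.dtype)
            out[:] = self.params["b"]
            for dy in range(3):
                for dx in range(3):
                    full = (flat @ W[dy, dx]).reshape(B, H + 2, Wd + 2, -1)
                    out += full[:, dy : dy + H, dx : dx + Wd, :]
        if train:
            self._cache = xp
        return out

    def backward(self, dout):
        xp = self._cache
        B, Hp, Wp, C = xp.shape
        H, Wd = Hp - 2, Wp - 2
        W = self.params["W"]
        c_out = W.shape[3]
        dout_r = np.ascontiguousarray(dout).reshape(-1, c_out)
        dW = np.empty_like(W)
        dxp = None if self.first else np.zeros_like(xp)
        for dy in range(3):
            for dx in range(3):
                sl = np.ascontiguousarray(xp[:, dy : dy + H, dx : dx + Wd, :]).reshape(-1, C)
                dW[dy, dx] = sl.T @ dout_r
                if dxp is not None:
                    dxp[:, dy : dy + H, dx : dx + Wd, :] += (dout_r @ W[dy, dx].T).reshape(
                        B, H, Wd, C
                    )
        self.grads = {"W": dW, "b": dout_r.sum(axis=0)}
        self._cache = None
        if dxp is None:
            return np.zeros((B, H, Wd, C), dtype=dout.dtype)
        return dxp[:, 1:-1, 1:-1, :]


class ReLU(Layer):
    def forward(self, x, train=False):
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout):
        dx = dout * self._mask
        self._mask = None
        return dx


class LRN(Layer):
    """Cross-channel local response normalization.

    ``y_c = x_c / (k + alpha * sum_{|c'-c| <= r} x_{c'}^2)^beta`` with the
    canonical published constants r=5, alpha=1e-4, beta=0.75, k=2.
    Works on the last axis (channels-last layout).
    """

    def __init__(self, radius: int = 5, alpha: float = 1e-4, beta: float = 0.75, k: float = 2.0):
        super().__init__()
        self.radius, self.alpha, self.beta, self.k = radius, alpha, beta, k

    def _window_sum(self, a):
        if _HAVE_NUMBA:
            a2 = np.ascontiguousarray(a).reshape(-1, a.shape[-1])
            return _window_sum_running(a2, self.radius).reshape(a.shape)
        return self._window_sum_numpy(a)

    def _window_sum_numpy(self, a):
        # inclusive window [c-r, c+r] along the last axis via cumulative sums;
        # boundary clamping is folded into padding so both ends are plain
        # slices rather than fancy-index gathers
        C = a.shape[-1]
        r = self.radius
        cs = np.empty(a.shape[:-1] + (C + 1,), dtype=a.dtype)
        cs[..., 0] = 0
        np.cumsum(a, axis=-1, out=cs[..., 1:])
        shape = a.shape[:-1]
        hi = np.concatenate(  # cs[min(c+r+1, C)] for c = 0..C-1
            [cs[..., r + 1 :], np.broadcast_to(cs[..., -1:], shape + (min(r, C),))], axis=-1
        )
        lo = np.concatenate(  # cs[max(c-r, 0)] for c = 0..C-1
            [np.zeros(shape + (min(r, C),), dtype=a.dtype), cs[..., : max(C - r, 0)]], axis=-1
        )
        return hi - lo

    def _inv_pow_beta(self, denom):
        # denom**(-beta); beta=3/4 via two sqrts, much cheaper than np.power
        if self.beta == 0.75:
            s = np.sqrt(denom)
            return 1.0 / (s * np.sqrt(s))
        return denom ** (-self.beta)

    def forward(self, x, train=False):
        denom = self.k + self.alpha * self._window_sum(x * x)
        scale = self._inv_pow_beta(denom)
        out = x * scale
        if train:
            self._cache = (x, denom, scale)
        return out

    def backward(self, dout):
        x, denom, scale = self._cache
        # dx_j = g_j * scale_j - 2 alpha beta x_j * sum_{c: j in win(c)} g_c x_c denom_c^{-beta-1}
        t = dout * x * (scale / denom)
        dx = dout * scale - 2.0 * self.alpha * self.beta * x * self._window_sum(t)
        self._cache = None
        return dx


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.params = {"W": w.astype(dtype), "b": np.zeros(n_out, dtype=dtype)}

    def forward(self, x, train=False):
        if train:
            self._cache = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        x = self._cache
        self.grads = {"W": x.T @ dout, "b": dout.sum(axis=0)}
        self._cache = None
        return dout @ self.params["W"].T


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
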