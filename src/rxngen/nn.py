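"""Minimal NumPy neural-network layers with exact backpropagation.

Only what the sequence VAE needs: an embedding lookup, dense projections, an
LSTM with variational recurrent dropout, and Adam with global-norm gradient
clipping.  Parameters are float64 by default (float32 supported for speed);
everything is seeded, and gradients are verified against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

try:  # numba accelerates the LSTM time loops ~20x; pure NumPy works without it
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=True)
def _lstm_forward_core(xW, U, b, mask, one):
    """Time-major LSTM forward.

    xW: (T, B, 4H) precomputed input contributions; mask: (B, H) recurrent
    dropout mask (all ones when disabled).  Returns hidden sequence plus the
    caches the backward pass needs.
    """
    T, B, H4 = xW.shape
    H = H4 // 4
    dt = xW.dtype
    hs = np.zeros((T, B, H), dt)
    h_in_c = np.zeros((T, B, H), dt)
    c_prev_c = np.zeros((T, B, H), dt)
    gates_c = np.zeros((T, B, H4), dt)  # post-activation i, f, g, o
    tc_c = np.zeros((T, B, H), dt)
    h_t = np.zeros((B, H), dt)
    c_t = np.zeros((B, H), dt)
    for t in range(T):
        h_in = h_t * mask
        pre = xW[t] + np.dot(h_in, U) + b
        i = one / (one + np.exp(-pre[:, :H]))
        f = one / (one + np.exp(-pre[:, H : 2 * H]))
        g = np.tanh(pre[:, 2 * H : 3 * H])
        o = one / (one + np.exp(-pre[:, 3 * H :]))
        c_prev_c[t] = c_t
        c_t = f * c_t + i * g
        tc = np.tanh(c_t)
        h_t = o * tc
        h_in_c[t] = h_in
        gates_c[t, :, :H] = i
        gates_c[t, :, H : 2 * H] = f
        gates_c[t, :, 2 * H : 3 * H] = g
        gates_c[t, :, 3 * H :] = o
        tc_c[t] = tc
        hs[t] = h_t
    return hs, h_in_c, c_prev_c, gates_c, tc_c


@njit(cache=True)
def _lstm_backward_core(dhs, dh_last, W, U, mask, h_in_c, c_prev_c, gates_c, tc_c, x, one):
    """Time-major LSTM backward; returns (dx, dW, dU, db).

    Per-timestep work is one matmul (the recurrent gradient); the weight and
    input gradients are computed with batched matmuls after the loop.
    """
    T, B, H = dhs.shape
    dt = dhs.dtype
    dgates_all = np.zeros((T, B, 4 * H), dt)
    dh_next = dh_last.copy()
    dc_next = np.zeros((B, H), dt)
    Ut = U.T.copy()
    for t in range(T - 1, -1, -1):
        dh = dhs[t] + dh_next
        i = gates_c[t, :, :H]
        f = gates_c[t, :, H : 2 * H]
        g = gates_c[t, :, 2 * H : 3 * H]
        o = gates_c[t, :, 3 * H :]
        tc = tc_c[t]
        dc = dc_next + dh * o * (one - tc * tc)
        dgates = dgates_all[t]
        dgates[:, :H] = dc * g * i * (one - i)
        dgates[:, H : 2 * H] = dc * c_prev_c[t] * f * (one - f)
        dgates[:, 2 * H : 3 * H] = dc * i * (one - g * g)
        dgates[:, 3 * H :] = dh * tc * o * (one - o)
        dc_next = dc * f
        dh_next = np.dot(dgates, Ut) * mask
    n_in = x.shape[2]
    Gf = dgates_all.reshape(T * B, 4 * H)
    dW = np.dot(x.reshape(T * B, n_in).T, Gf)
    dU = np.dot(h_in_c.reshape(T * B, H).T, Gf)
    db = Gf.sum(axis=0).astype(dt)
    dx = np.dot(Gf, W.T).reshape(T, B, n_in)
    return dx, dW, dU, db


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[-1]))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Parameter container: ``params`` and matching ``grads`` dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for name, p in self.params.items():
            self.grads[name] = np.zeros_like(p)


class Embedding(Layer):
    def __init__(self, n_symbols: int, dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = rng.normal(0.0, 0.05, size=(n_symbols, dim))
        self.zero_grad()

    def forward(self, codes: np.ndarray) -> np.ndarray:
        self._codes = codes
        return self.params["W"][codes]

    def backward(self, dout: np.ndarray) -> None:
        dim = self.params["W"].shape[1]
        np.add.at(self.grads["W"], self._codes.ravel(), dout.reshape(-1, dim))


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = _glorot(rng, (n_in, n_out))
        self.params["b"] = np.zeros(n_out)
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        d2 = dout.reshape(-1, dout.shape[-1])
        self.grads["W"] += x2.T @ d2
        self.grads["b"] += d2.sum(axis=0)
        return dout @ self.params["W"].T


class LSTM(Layer):
    """Single-direction LSTM over (batch, time, features) sequences.

    Gate order i, f, g, o.  Recurrent dropout is variational: one mask per
    sequence applied to the previous hidden state at every timestep.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator) -> None:
        super().__init__()
        h = n_hidden
        self.n_hidden = h
        self.params["W"] = _glorot(rng, (n_in, 4 * h))
        self.params["U"] = _glorot(rng, (h, 4 * h))
        self.params["b"] = np.zeros(4 * h)
        self.params["b"][h : 2 * h] = 1.0  # forget-gate bias
        self.zero_grad()

    def forward(self, x: np.ndarray, rec_mask: np.ndarray | None = None) -> np.ndarray:
        """Returns the full hidden sequence (B, T, H)."""
        B, T, _ = x.shape
        h = self.n_hidden
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        mask = (
            np.ones((B, h), dtype=x.dtype)
            if rec_mask is None
            else np.ascontiguousarray(rec_mask, dtype=x.dtype)
        )
        x_tm = np.ascontiguousarray(x.transpose(1, 0, 2))  # time-major
        xW = x_tm @ W
        hs, h_in_c, c_prev_c, gates_c, tc_c = _lstm_forward_core(xW, U, b, mask, x.dtype.type(1.0))
        self._cache = (x_tm, mask, h_in_c, c_prev_c, gates_c, tc_c)
        return hs.transpose(1, 0, 2)

    def backward(self, dhs: np.ndarray | None, dh_last: np.ndarray | None = None) -> np.ndarray:
        """Backprop given upstream gradients on the hidden sequence and/or on
        the final hidden state; returns gradient w.r.t. the input sequence."""
        x_tm, mask, h_in_c, c_prev_c, gates_c, tc_c = self._cache
        T, B, _ = x_tm.shape
        h = self.n_hidden
        dhs_tm = (
            np.zeros((T, B, h), dtype=x_tm.dtype)
            if dhs is None
            else np.ascontiguousarray(dhs.transpose(1, 0, 2), dtype=x_tm.dtype)
        )
        dh_l = (
            np.zeros((B, h), dtype=x_tm.dtype)
            if dh_last is None
            else np.ascontiguousarray(dh_last, dtype=x_tm.dtype)
        )
        dx, dW, dU, db = _lstm_backward_core(
            dhs_tm, dh_l, self.params["W"], self.params["U"], mask,
            h_in_c, c_prev_c, gates_c, tc_c, x_tm, x_tm.dtype.type(1.0),
        )
        self.grads["W"] += dW
        self.grads["U"] += dU
        self.grads["b"] += db
        return dx.transpose(1, 0, 2)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adam over the parameters of a list of layers."""

    def __init__(
        self,
        layers: list[Layer],
        learning_rate: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        clip_norm: float | None = None,
    ) -> None:
        self.layers = layers
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in layers]

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def step(self) -> None:
        if self.clip_norm is not None:  # global-norm gradient clipping
            sq = 0.0
            for layer in self.layers:
                for g in layer.grads.values():
                    sq += float(np.sum(g * g))
            norm = np.sqrt(sq)
            if norm > self.clip_norm:
                scale = self.clip_norm / norm
                for layer in self.layers:
                    for g in layer.grads.values():
                        g *= scale
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        correction = np.sqrt(1.0 - b2**self.t) / (1.0 - b1**self.t)
        for layer, m, v in zip(self.layers, self.m, self.v):
            for name, p in layer.params.items():
                g = layer.grads[name]
                m[name] = b1 * m[name] + (1 - b1) * g
                v[name] = b2 * v[name] + (1 - b2) * g * g
                p -= self.lr * correction * m[name] / (np.sqrt(v[name]) + self.eps)
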