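"""Minimal LSTM engine: forward pass, backpropagation through time, Adam.

Implements the standard LSTM cell (no peephole connections, one bias vector
per gate block) — the convention under which the parameter count of a layer
is ``4 * ((n_in + n_hidden) * n_hidden + n_hidden)``. Gates are packed in
the order input, forget, output, cell-candidate; the forget-gate bias is
initialized to 1.

The engine supports stacked layers and stateful processing: hidden/cell
states are carried across consecutive chunks of a continuous stream, with
gradients truncated at chunk boundaries. Whole-chunk input projections,
weight-gradient accumulation and input gradients are single BLAS calls; the
sequential per-frame recurrence (gate nonlinearities and cell update, and
their adjoints) is JIT-compiled with numba. Everything is float64 and fully
deterministic given a seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.special import expit as sigmoid


@njit(cache=True)
def _lstm_forward_kernel(zx, Wh, h0, c0):
    B, T, H4 = zx.shape
    H = H4 // 4
    hs = np.empty((B, T, H))
    gates = np.empty((B, T, H4))
    cs = np.empty((B, T, H))
    tcs = np.empty((B, T, H))
    h = h0.copy()
    c = c0.copy()
    for t in range(T):
        zr = np.dot(h, Wh)
        for b in range(B):
            for j in range(H):
                zi = zx[b, t, j] + zr[b, j]
                zf = zx[b, t, H + j] + zr[b, H + j]
                zo = zx[b, t, 2 * H + j] + zr[b, 2 * H + j]
                zg = zx[b, t, 3 * H + j] + zr[b, 3 * H + j]
                ig = 1.0 / (1.0 + np.exp(-zi))
                fg = 1.0 / (1.0 + np.exp(-zf))
                og = 1.0 / (1.0 + np.exp(-zo))
                gg = np.tanh(zg)
                cc = fg * c[b, j] + ig * gg
                tc = np.tanh(cc)
                gates[b, t, j] = ig
                gates[b, t, H + j] = fg
                gates[b, t, 2 * H + j] = og
                gates[b, t, 3 * H + j] = gg
                cs[b, t, j] = cc
                tcs[b, t, j] = tc
                hs[b, t, j] = og * tc
                h[b, j] = og * tc
                c[b, j] = cc
    return hs, gates, cs, tcs, h, c


@njit(cache=True)
def _lstm_backward_kernel(dh_out, gates, cs, tcs, c0, WhT):
    B, T, H = dh_out.shape
    dz = np.empty((B, T, 4 * H))
    dzt = np.empty((B, 4 * H))
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        for b in range(B):
            for j in range(H):
                ig = gates[b, t, j]
                fg = gates[b, t, H + j]
                og = gates[b, t, 2 * H + j]
                gg = gates[b, t, 3 * H + j]
                tc = tcs[b, t, j]
                dh = dh_out[b, t, j] + dh_next[b, j]
                do = dh * tc
                dc = dh * og * (1.0 - tc * tc) + dc_next[b, j]
                cp = cs[b, t - 1, j] if t > 0 else c0[b, j]
                dzt[b, j] = (dc * gg) * ig * (1.0 - ig)
                dzt[b, H + j] = (dc * cp) * fg * (1.0 - fg)
                dzt[b, 2 * H + j] = do * og * (1.0 - og)
                dzt[b, 3 * H + j] = (dc * ig) * (1.0 - gg * gg)
                dc_next[b, j] = dc * fg
        dh_next = np.dot(dzt, WhT)
        dz[:, t] = dzt
    return dz


class LSTMLayer:
    """One LSTM layer with packed weights W: (n_in + n_hidden, 4 * n_hidden).

    Rows ``[:n_in]`` project the input, rows ``[n_in:]`` the recurrent
    state; columns hold the i, f, o, g gate blocks.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_in = n_in
        self.n_hidden = n_hidden
        limit = np.sqrt(6.0 / (n_in + n_hidden + 4 * n_hidden))
        self.W = rng.uniform(-limit, limit, (n_in + n_hidden, 4 * n_hidden))
        self.b = np.zeros(4 * n_hidden)
        self.b[n_hidden : 2 * n_hidden] = 1.0  # forget-gate bias

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def zero_state(self, batch: int) -> tuple[np.ndarray, np.ndarray]:
        return (np.zeros((batch, self.n_hidden)), np.zeros((batch, self.n_hidden)))

    def forward(
        self,
        x: np.ndarray,
        state: tuple[np.ndarray, np.ndarray],
        want_cache: bool = False,
    ):
        """Process x (B, T, n_in); returns h (B, T, H), final state, cache."""
        h0, c0 = state
        zx = np.ascontiguousarray(x) @ self.W[: self.n_in] + self.b
        Wh = np.ascontiguousarray(self.W[self.n_in :])
        hs, gates, cs, tcs, h, c = _lstm_forward_kernel(zx, Wh, h0, c0)
        cache = None
        if want_cache:
            cache = {"x": x, "h0": h0, "c0": c0, "gates": gates,
                     "cs": cs, "tcs": tcs, "hs": hs}
        return hs, (h, c), cache

    def backward(self, dh_out: np.ndarray, cache: dict):
        """Backprop dh_out (B, T, H) through the cached forward pass.

        Gradients are truncated at t = 0 (stateful training: no flow into
        the previous chunk). Returns (dx, dW, db).
        """
        B, T, H = dh_out.shape
        WhT = np.ascontiguousarray(self.W[self.n_in :].T)
        dz = _lstm_backward_kernel(
            np.ascontiguousarray(dh_out), cache["gates"], cache["cs"],
            cache["tcs"], cache["c0"], WhT,
        )
        h_prev = np.concatenate([cache["h0"][:, None, :], cache["hs"][:, :-1]], axis=1)
        flat_dz = dz.reshape(-1, 4 * H)
        dW = np.empty_like(self.W)
        dW[: self.n_in] = cache["x"].reshape(-1, self.n_in).T @ flat_dz
        dW[self.n_in :] = h_prev.reshape(-1, H).T @ flat_dz
        db = flat_dz.sum(axis=0)
        dx = dz @ self.W[: self.n_in].T
        return dx, dW, db


class Dense:
    """Output head: h @ W + b with sigmoid or linear activation."""

    def __init__(self, n_in: int, n_out: int, activation: str, rng: np.random.Generator):
        if activation not in ("sigmoid", "linear"):
            raise ValueError(f"unknown activation {activation!r}")
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, (n_in, n_out))
        self.b = np.zeros(n_out)
        self.activation = activation

    def forward(self, h: np.ndarray) -> np.ndarray:
        z = h @ self.W + self.b
        return sigmoid(z) if self.activation == "sigmoid" else z

    def backward(self, h: np.ndarray, dz: np.ndarray):
        """dz is the gradient w.r.t. the pre-activation; returns (dh, dW, db)."""
        dW = h.reshape(-1, h.shape[-1]).T @ dz.reshape(-1, dz.shape[-1])
        db = dz.reshape(-1, dz.shape[-1]).sum(axis=0)
        dh = dz @ self.W.T
        return dh, dW, db


class Adam:
    """Adam optimizer over a flat list of parameter arrays (in-place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g**2
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
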