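"""Minimal numpy neural-network kernels for the attention Bi-LSTM.

Everything is float64 with hand-derived backprop: an LSTM layer (run
forwards or backwards over time, with masked state carry so padded
positions leave the recurrence untouched), single-context additive
attention with masked softmax, a dense softmax output, and Adam.

Padded positions are handled by carrying hidden/cell state through them
(``h_t = m_t * h_new + (1 - m_t) * h_prev``), which together with the
attention mask makes predictions exactly invariant to appended padding.

A finite-difference gradient check in the test suite validates the
backward passes end to end.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

__all__ = ["LSTMLayer", "AdditiveAttention", "Dense", "Adam", "softmax", "cross_entropy"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(probs: np.ndarray, targets: np.ndarray) -> float:
    """Mean negative log-likelihood; targets are class indices."""
    p = probs[np.arange(len(targets)), targets]
    return float(-np.log(np.clip(p, 1e-12, None)).mean())


class LSTMLayer:
    """Single-direction LSTM over (B, T, D) inputs with a (B, T) mask.

    Gate order in the stacked weight matrices: input, forget, cell, output.
    ``reverse=True`` runs the recurrence from the last position to the
    first (the backward half of a Bi-LSTM).
    """

    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator, reverse: bool = False):
        self.D, self.H, self.reverse = input_dim, hidden_dim, reverse
        scale = 1.0 / np.sqrt(hidden_dim)
        self.Wx = rng.uniform(-scale, scale, (input_dim, 4 * hidden_dim))
        self.Wh = rng.uniform(-scale, scale, (hidden_dim, 4 * hidden_dim))
        self.b = np.zeros(4 * hidden_dim)
        self.b[hidden_dim : 2 * hidden_dim] = 1.0  # forget-gate bias
        self._cache = None

    @property
    def params(self):
        return {"Wx": self.Wx, "Wh": self.Wh, "b": self.b}

    def forward(
        self,
        x: np.ndarray,
        mask: np.ndarray,
        recurrent_drop: Optional[np.ndarray] = None,
    ) -> np.ndarray:
        """``recurrent_drop`` is an optional (B, H) variational dropout mask
        applied to the hidden state fed back into the recurrence (training
        only); per-position outputs are left untouched."""
        B, T, _ = x.shape
        H = self.H
        order = range(T - 1, -1, -1) if self.reverse else range(T)
        rdrop = np.ones((B, H)) if recurrent_drop is None else recurrent_drop
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.zeros((B, T, H))
        cache = []
        for t in order:
            m = mask[:, t : t + 1]
            h_in = rdrop * h
            z = x[:, t] @ self.Wx + h_in @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            cache.append((t, m, i, f, g, o, c, h_in, c_new, tanh_c))
            h = m * h_new + (1 - m) * h
            c = m * c_new + (1 - m) * c
            hs[:, t] = h
        self._cache = (x, mask, rdrop, cache)
        return hs

    def backward(self, dhs: np.ndarray):
        """dhs: gradient wrt the per-position hidden outputs. Returns
        (dx, grads) with grads keyed like ``params``."""
        x, mask, rdrop, cache = self._cache
        B, T, _ = x.shape
        H = self.H
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dx = np.zeros_like(x)
        dh_carry = np.zeros((B, H))
        dc_carry = np.zeros((B, H))
        for t, m, i, f, g, o, c_prev, h_in, c_new, tanh_c in reversed(cache):
            dh_total = dhs[:, t] + dh_carry
            # through the mask carry: gradient splits between new and previous state
            dh_new = m * dh_total
            dh_prev_skip = (1 - m) * dh_total
            dc_new = m * dc_carry
            dc_prev_skip = (1 - m) * dc_carry

            do = dh_new * tanh_c
            dc = dc_new + dh_new * o * (1 - tanh_c**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_prev = dc * f

            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)], axis=1
            )
            dWx += x[:, t].T @ dz
            dWh += h_in.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] += dz @ self.Wx.T
            dh_carry = (dz @ self.Wh.T) * rdrop + dh_prev_skip
            dc_carry = dc_prev + dc_prev_skip
        return dx, {"Wx": dWx, "Wh": dWh, "b": db}


class AdditiveAttention:
    """score_t = u . tanh(Wa h_t + ba); masked softmax -> weights; weighted
    sum of hidden states -> context vector."""

    def __init__(self, hidden_dim: int, att_dim: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(att_dim)
        self.Wa = rng.uniform(-scale, scale, (hidden_dim, att_dim))
        self.ba = np.zeros(att_dim)
        self.u = rng.uniform(-scale, scale, att_dim)
        self._cache = None

    @property
    def params(self):
        return {"Wa": self.Wa, "ba": self.ba, "u": self.u}

    def forward(self, h: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        e = np.tanh(h @ self.Wa + self.ba)  # (B, T, A)
        s = e @ self.u  # (B, T)
        s = np.where(mask > 0, s, -np.inf)
        alpha = softmax(s, axis=1)
        ctx = np.einsum("bt,bth->bh", alpha, h)
        self._cache = (h, mask, e, alpha)
        return ctx, alpha

    def backward(self, dctx: np.ndarray, dalpha_extra: Optional[np.ndarray] = None):
        h, mask, e, alpha = self._cache
        dalpha = np.einsum("bh,bth->bt", dctx, h)
        if dalpha_extra is not None:
            dalpha = dalpha + dalpha_extra
        dh = alpha[:, :, None] * dctx[:, None, :]
        # masked-softmax backward
        ds = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
        ds = ds * (mask > 0)
        de = ds[:, :, None] * self.u[None, None, :]
        dpre = de * (1 - e**2)
        dWa = np.einsum("bth,bta->ha", h, dpre)
        dba = dpre.sum(axis=(0, 1))
        du = (e * ds[:, :, None]).sum(axis=(0, 1))
        dh += dpre @ self.Wa.T
        return dh, {"Wa": dWa, "ba": dba, "u": du}


class Dense:
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(in_dim)
        self.W = rng.uniform(-scale, scale, (in_dim, out_dim))
        self.b = np.zeros(out_dim)
        self._cache = None

    @property
    def params(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray):
        x = self._cache
        return dout @ self.W.T, {"W": x.T @ dout, "b": dout.sum(axis=0)}


class Adam:
    """Adam over a flat dict of named parameter arrays (updated in place)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
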