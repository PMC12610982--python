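"""Minimal numpy sequence-model engine: LSTM, linear, dropout, Adam.

Implements exactly the pieces the score estimator needs, with hand-written
reverse-mode gradients (gradient-checked against numerical differentiation in
the test suite). Weights use the conventional uniform fan-in initialization
U(-k, k) with k = 1/sqrt(hidden) for recurrent layers and k = 1/sqrt(fan_in)
for linear layers; all randomness flows through an explicit Generator so runs
are bit-reproducible on one machine.

float32 is the default compute dtype for speed; float64 is used by the
gradient-check tests.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Linear", "LSTM", "Dropout", "Adam", "sigmoid"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Module:
    """Base: exposes params/grads as dicts of arrays."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        k = 1.0 / np.sqrt(d_in)
        self.params["W"] = rng.uniform(-k, k, (d_in, d_out)).astype(dtype)
        self.params["b"] = rng.uniform(-k, k, d_out).astype(dtype)
        self.grads = {n: np.zeros_like(p) for n, p in self.params.items()}
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] += self._x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"].T


class LSTM(Module):
    """Single-layer LSTM over (batch, time, features); returns all hidden states."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        self.d_in, self.d_hidden = d_in, d_hidden
        k = 1.0 / np.sqrt(d_hidden)
        self.params["W_ih"] = rng.uniform(-k, k, (d_in, 4 * d_hidden)).astype(dtype)
        self.params["W_hh"] = rng.uniform(-k, k, (d_hidden, 4 * d_hidden)).astype(dtype)
        self.params["b"] = rng.uniform(-k, k, 4 * d_hidden).astype(dtype)
        self.grads = {n: np.zeros_like(p) for n, p in self.params.items()}
        self._cache: dict | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, t, _ = x.shape
        h = self.d_hidden
        dtype = self.params["b"].dtype
        hs = np.zeros((b, t, h), dtype=dtype)
        h_t = np.zeros((b, h), dtype=dtype)
        c_t = np.zeros((b, h), dtype=dtype)
        gates, cells, tanhc, h_prevs, c_prevs = [], [], [], [], []
        w_ih, w_hh, bias = (self.params["W_ih"], self.params["W_hh"],
                            self.params["b"])
        for step in range(t):
            h_prevs.append(h_t)
            c_prevs.append(c_t)
            z = x[:, step] @ w_ih + h_t @ w_hh + bias
            zi, zf, zg, zo = np.split(z, 4, axis=1)
            i = sigmoid(zi)
            f = sigmoid(zf)
            g = np.tanh(zg)
            o = sigmoid(zo)
            c_t = f * c_t + i * g
            tc = np.tanh(c_t)
            h_t = o * tc
            hs[:, step] = h_t
            gates.append((i, f, g, o))
            cells.append(c_t)
            tanhc.append(tc)
        self._cache = dict(x=x, gates=gates, cells=cells, tanhc=tanhc,
                           h_prevs=h_prevs, c_prevs=c_prevs)
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        cache = self._cache
        x = cache["x"]
        b, t, _ = x.shape
        dtype = self.params["b"].dtype
        w_ih, w_hh = self.params["W_ih"], self.params["W_hh"]
        dx = np.zeros_like(x)
        dh_next = np.zeros((b, self.d_hidden), dtype=dtype)
        dc_next = np.zeros((b, self.d_hidden), dtype=dtype)
        for step in range(t - 1, -1, -1):
            i, f, g, o = cache["gates"][step]
            tc = cache["tanhc"][step]
            c_prev = cache["c_prevs"][step]
            h_prev = cache["h_prevs"][step]
            dh = dhs[:, step] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1.0 - i), df * f * (1.0 - f),
                 dg * (1.0 - g * g), do * o * (1.0 - o)], axis=1)
            self.grads["W_ih"] += x[:, step].T @ dz
            self.grads["W_hh"] += h_prev.T @ dz
            self.grads["b"] += dz.sum(axis=0)
            dx[:, step] = dz @ w_ih.T
            dh_next = dz @ w_hh.T
        return dx


class Dropout:
    """Inverted dropout; identity when not training."""

    def __init__(self, p: float) -> None:
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout p must be in [0, 1)")
        self.p = p
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if not training or self.p == 0.0:
            self._mask = None
            return x
        keep = (rng.random(x.shape) >= self.p).astype(x.dtype)
        self._mask = keep / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class Adam:
    """Adam optimizer over a list of Modules."""

    def __init__(self, modules: list[Module], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8) -> None:
        self.modules = modules
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [{n: np.zeros_like(p) for n, p in mod.params.items()}
                   for mod in modules]
        self._v = [{n: np.zeros_like(p) for n, p in mod.params.items()}
                   for mod in modules]

    def zero_grad(self) -> None:
        for mod in self.modules:
            mod.zero_grad()

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for mod, m, v in zip(self.modules, self._m, self._v):
            for name, p in mod.params.items():
                g = mod.grads[name]
                m[name] = self.b1 * m[name] + (1.0 - self.b1) * g
                v[name] = self.b2 * v[name] + (1.0 - self.b2) * g * g
                mhat = m[name] / bc1
                vhat = v[name] / bc2
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
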