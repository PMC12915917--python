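"""Small convolutional-recurrent networks for daily sequence forecasting.

A deliberately desk-scale architecture: one 1-D convolution over the time
axis (ReLU), one recurrent layer (LSTM or GRU) whose final hidden state
feeds a dense head — linear output for regression, softmax for
classification.  Written directly in numpy with explicit
backpropagation-through-time and Adam updates; training is deterministic
given the seed (fixed initialization, fixed epoch count, full-batch
shuffling from a seeded generator).

These nets trade capacity for reproducibility and CPU friendliness:
channel widths and unit counts default well under the sizes a GPU study
would use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConvRecurrentNet"]


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[-2], shape[-1]
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=shape)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1**self.t)
            vh = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + self.eps)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -40, 40)))


@dataclass
class ConvRecurrentNet:
    """conv1d -> LSTM/GRU -> dense, trained with Adam on MSE or cross-entropy.

    Parameters
    ----------
    cell : "lstm" or "gru"
    task : "regression" or "classification"
    conv_channels, kernel_size, hidden_units : layer sizes
    epochs, batch_size, lr : optimization schedule
    seed : controls init and batch shuffling; identical seeds and data give
        identical fits.
    """

    cell: str = "lstm"
    task: str = "regression"
    conv_channels: int = 16
    kernel_size: int = 3
    hidden_units: int = 32
    epochs: int = 30
    batch_size: int = 64
    lr: float = 3e-3
    seed: int = 0
    clip_norm: float = 5.0
    params: dict = field(default_factory=dict, repr=False)
    _norm: dict = field(default_factory=dict, repr=False)
    classes_: np.ndarray | None = None

    # ---------------- initialization ----------------

    def _init_params(self, n_channels: int, n_out: int):
        rng = np.random.default_rng(self.seed)
        F, H, K = self.conv_channels, self.hidden_units, self.kernel_size
        p = {
            "Wc": _glorot(rng, (K * n_channels, F)).reshape(K, n_channels, F),
            "bc": np.zeros(F),
            "Wo": _glorot(rng, (H, n_out)),
            "bo": np.zeros(n_out),
        }
        gates = 4 if self.cell == "lstm" else 3
        p["Wx"] = _glorot(rng, (F, gates * H))
        p["Wh"] = _glorot(rng, (H, gates * H))
        p["bh"] = np.zeros(gates * H)
        if self.cell == "lstm":
            p["bh"][H : 2 * H] = 1.0  # forget-gate bias
        self.params = p

    # ---------------- forward ----------------

    def _conv_forward(self, x):
        # x: (N, T, C) -> valid conv -> (N, T-K+1, F)
        K = self.kernel_size
        N, T, C = x.shape
        windows = np.lib.stride_tricks.sliding_window_view(x, K, axis=1)  # (N,T-K+1,C,K)
        pre = np.einsum("ntck,kcf->ntf", windows, self.params["Wc"]) + self.params["bc"]
        return windows, pre, np.maximum(pre, 0.0)

    def _recurrent_forward(self, z):
        # z: (N, T, F); returns final hidden state and per-step caches
        N, T, F = z.shape
        H = self.hidden_units
        Wx, Wh, bh = self.params["Wx"], self.params["Wh"], self.params["bh"]
        h = np.zeros((N, H))
        caches = []
        if self.cell == "lstm":
            c = np.zeros((N, H))
            for t in range(T):
                a = z[:, t] @ Wx + h @ Wh + bh
                i, f, g, o = (
                    _sigmoid(a[:, :H]),
                    _sigmoid(a[:, H : 2 * H]),
                    np.tanh(a[:, 2 * H : 3 * H]),
                    _sigmoid(a[:, 3 * H :]),
                )
                c_new = f * c + i * g
                tanh_c = np.tanh(c_new)
                h_new = o * tanh_c
                caches.append((z[:, t], h, c, i, f, g, o, c_new, tanh_c))
                h, c = h_new, c_new
        else:  # gru
            for t in range(T):
                a = z[:, t] @ Wx + h @ Wh + bh
                r, u = _sigmoid(a[:, :H]), _sigmoid(a[:, H : 2 * H])
                n_pre = z[:, t] @ Wx[:, 2 * H :] + (r * h) @ Wh[:, 2 * H :] + bh[2 * H :]
                n = np.tanh(n_pre)
                h_new = (1 - u) * n + u * h
                caches.append((z[:, t], h, r, u, n))
                h = h_new
        return h, caches

    def _head_forward(self, h):
        return h @ self.params["Wo"] + self.params["bo"]

    # ---------------- backward ----------------

    def _recurrent_backward(self, dh, caches, grads, T, F):
        H = self.hidden_units
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        dbh = np.zeros_like(self.params["bh"])
        dz = np.zeros((dh.shape[0], T, F))
        if self.cell == "lstm":
            dc = np.zeros_like(dh)
            for t in reversed(range(T)):
                zt, h_prev, c_prev, i, f, g, o, c_new, tanh_c = caches[t]
                do = dh * tanh_c
                dct = dc + dh * o * (1 - tanh_c**2)
                di, df, dg = dct * g, dct * c_prev, dct * i
                da = np.concatenate(
                    [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                    axis=1,
                )
                dWx += zt.T @ da
                dWh += h_prev.T @ da
                dbh += da.sum(axis=0)
                dz[:, t] = da @ Wx.T
                dh = da @ Wh.T
                dc = dct * f
        else:
            for t in reversed(range(T)):
                zt, h_prev, r, u, n = caches[t]
                dn = dh * (1 - u)
                du = dh * (h_prev - n)
                dn_pre = dn * (1 - n**2)
                # n gate uses Wx[:,2H:], Wh[:,2H:] with r*h_prev
                dWx[:, 2 * H :] += zt.T @ dn_pre
                dWh[:, 2 * H :] += (r * h_prev).T @ dn_pre
                dbh[2 * H :] += dn_pre.sum(axis=0)
                drh = dn_pre @ Wh[:, 2 * H :].T
                dr = drh * h_prev
                dh_prev = dh * u + drh * r
                da = np.concatenate([dr * r * (1 - r), du * u * (1 - u)], axis=1)
                dWx[:, : 2 * H] += zt.T @ da
                dWh[:, : 2 * H] += h_prev.T @ da
                dbh[: 2 * H] += da.sum(axis=0)
                dz[:, t] = dn_pre @ Wx[:, 2 * H :].T + da @ Wx[:, : 2 * H].T
                dh = dh_prev + da @ Wh[:, : 2 * H].T
        grads["Wx"], grads["Wh"], grads["bh"] = dWx, dWh, dbh
        return dz

    def _backward(self, windows, pre, z, h, caches, dout):
        grads: dict[str, np.ndarray] = {}
        grads["Wo"] = h.T @ dout
        grads["bo"] = dout.sum(axis=0)
        dh = dout @ self.params["Wo"].T
        T, F = z.shape[1], z.shape[2]
        dz = self._recurrent_backward(dh, caches, grads, T, F)
        dpre = dz * (pre > 0)
        grads["Wc"] = np.einsum("ntck,ntf->kcf", windows, dpre)
        grads["bc"] = dpre.sum(axis=(0, 1))
        return grads

    # ---------------- API ----------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ConvRecurrentNet":
        """Train on sequences X (N, T, C) and targets y.

        Regression targets are z-scored internally; classification targets
        may be any label array (classes stored in ``classes_``).
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must have shape (N, T, C)")
        mu = X.mean(axis=(0, 1))
        sd = X.std(axis=(0, 1))
        sd[sd == 0] = 1.0
        self._norm = {"mu": mu, "sd": sd}
        Xn = (X - mu) / sd

        if self.task == "classification":
            self.classes_, codes = np.unique(np.asarray(y, dtype=object), return_inverse=True)
            n_out = len(self.classes_)
            Y = np.eye(n_out)[codes]
        else:
            y = np.asarray(y, dtype=float)
            ymu, ysd = y.mean(), y.std() or 1.0
            self._norm["ymu"], self._norm["ysd"] = ymu, ysd
            Y = ((y - ymu) / ysd)[:, None]
            n_out = 1

        self._init_params(X.shape[2], n_out)
        opt = _Adam(self.params, self.lr)
        rng = np.random.default_rng(self.seed + 1)
        n = len(Xn)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = Xn[idx], Y[idx]
                windows, pre, z = self._conv_forward(xb)
                h, caches = self._recurrent_forward(z)
                out = self._head_forward(h)
                if self.task == "classification":
                    out -= out.max(axis=1, keepdims=True)
                    p = np.exp(out)
                    p /= p.sum(axis=1, keepdims=True)
                    dout = (p - yb) / len(idx)
                else:
                    dout = 2.0 * (out - yb) / len(idx)
                grads = self._backward(windows, pre, z, h, caches, dout)
                norm = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
                if norm > self.clip_norm:
                    grads = {k: g * (self.clip_norm / norm) for k, g in grads.items()}
                opt.step(self.params, grads)
        return self

    def _forward_all(self, X):
        Xn = (np.asarray(X, dtype=float) - self._norm["mu"]) / self._norm["sd"]
        _, _, z = self._conv_forward(Xn)
        h, _ = self._recurrent_forward(z)
        return self._head_forward(h)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted concentrations (regression) or class labels."""
        out = self._forward_all(X)
        if self.task == "classification":
            return self.classes_[np.argmax(out, axis=1)]
        return out[:, 0] * self._norm["ysd"] + self._norm["ymu"]
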