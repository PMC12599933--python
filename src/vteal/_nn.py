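"""Minimal NumPy neural-network primitives for the small text classifiers.

Implements an embedding layer feeding either an LSTM (last-true-state
readout) or 1D convolutions with max-over-time pooling, trained with Adam
on softmax cross-entropy.  Written against NumPy only so the package runs
on a bare scientific-Python stack; gradients are verified against finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "LSTMNet", "CNNNet", "softmax", "cross_entropy_grad"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(
    logits: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(p[np.arange(n), y] + 1e-12).mean())
    d = p.copy()
    d[np.arange(n), y] -= 1.0
    return loss, d / n


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            self.params[k] -= self.lr * (self.m[k] / b1c) / (
                np.sqrt(self.v[k] / b2c) + self.eps
            )


def _init(rng: np.random.Generator, *shape: int) -> np.ndarray:
    fan_in = shape[0]
    return rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shape)


class LSTMNet:
    """Embedding -> single-layer LSTM -> dense softmax on the last true
    hidden state.  Padded timesteps carry state through unchanged."""

    def __init__(self, vocab_size: int, embed_dim: int, hidden_dim: int,
                 n_classes: int, rng: np.random.Generator):
        d, h = embed_dim, hidden_dim
        self.hidden_dim = h
        self.params = {
            "E": rng.normal(0.0, 0.1, size=(vocab_size, d)),
            "Wx": _init(rng, d, 4 * h),
            "Wh": _init(rng, h, 4 * h),
            "b": np.zeros(4 * h),
            "Wy": _init(rng, h, n_classes),
            "by": np.zeros(n_classes),
        }
        # forget-gate bias 1: standard stabilization
        self.params["b"][h:2 * h] = 1.0

    def forward(self, ids: np.ndarray, lengths: np.ndarray):
        p = self.params
        h_dim = self.hidden_dim
        tb = int(lengths.max())
        ids = ids[:, :tb]
        b = ids.shape[0]
        x = p["E"][ids]  # (B, T, D)
        h = np.zeros((b, h_dim))
        c = np.zeros((b, h_dim))
        steps = []
        for t in range(tb):
            m = (t < lengths).astype(np.float64)[:, None]
            z = x[:, t] @ p["Wx"] + h @ p["Wh"] + p["b"]
            i = _sigmoid(z[:, :h_dim])
            f = _sigmoid(z[:, h_dim:2 * h_dim])
            g = np.tanh(z[:, 2 * h_dim:3 * h_dim])
            o = _sigmoid(z[:, 3 * h_dim:])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            steps.append((m, i, f, g, o, c, h, c_new, tanh_c))
            h = m * h_new + (1 - m) * h
            c = m * c_new + (1 - m) * c
        logits = h @ p["Wy"] + p["by"]
        cache = (ids, x, steps, h)
        return logits, cache

    def backward(self, cache, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        h_dim = self.hidden_dim
        ids, x, steps, h_final = cache
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        grads["Wy"] = h_final.T @ dlogits
        grads["by"] = dlogits.sum(axis=0)
        dh = dlogits @ p["Wy"].T
        dc = np.zeros_like(dh)
        for t in range(len(steps) - 1, -1, -1):
            m, i, f, g, o, c_prev, h_prev, c_new, tanh_c = steps[t]
            dh_new = dh * m
            do = dh_new * tanh_c
            dc_new = dc * m + dh_new * o * (1.0 - tanh_c**2)
            di = dc_new * g
            df = dc_new * c_prev
            dg = dc_new * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            grads["Wx"] += x[:, t].T @ dz
            grads["Wh"] += h_prev.T @ dz
            grads["b"] += dz.sum(axis=0)
            dx_t = dz @ p["Wx"].T
            np.add.at(grads["E"], ids[:, t], dx_t)
            dh = dh * (1 - m) + dz @ p["Wh"].T
            dc = dc_new * f + dc * (1 - m)
        return grads


class CNNNet:
    """Embedding -> parallel 1D convolutions (ReLU, max-over-time) ->
    dense softmax.  ``kernel_sizes=(3,)`` gives the plain 1D-CNN;
    ``(3, 4, 5)`` the multi-kernel variant."""

    def __init__(self, vocab_size: int, embed_dim: int, n_filters: int,
                 kernel_sizes: tuple[int, ...], n_classes: int,
                 rng: np.random.Generator):
        self.kernel_sizes = tuple(kernel_sizes)
        self.n_filters = n_filters
        d = embed_dim
        self.params = {"E": rng.normal(0.0, 0.1, size=(vocab_size, d))}
        for k in self.kernel_sizes:
            self.params[f"W{k}"] = _init(rng, k * d, n_filters)
            self.params[f"c{k}"] = np.zeros(n_filters)
        total = n_filters * len(self.kernel_sizes)
        self.params["Wy"] = _init(rng, total, n_classes)
        self.params["by"] = np.zeros(n_classes)

    def forward(self, ids: np.ndarray, lengths: np.ndarray):
        p = self.params
        kmax = max(self.kernel_sizes)
        tb = max(int(lengths.max()), kmax)
        ids = ids[:, :tb] if ids.shape[1] >= tb else np.pad(
            ids, ((0, 0), (0, tb - ids.shape[1]))
        )
        b = ids.shape[0]
        x = p["E"][ids]  # (B, T, D)
        feats = []
        caches = []
        for k in self.kernel_sizes:
            n_pos = tb - k + 1
            win = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
            # (B, P, D, K) -> (B, P, K*D) with token-major ordering
            win = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
                b, n_pos, -1
            )
            conv = win @ p[f"W{k}"] + p[f"c{k}"]
            relu = np.maximum(conv, 0.0)
            valid = np.maximum(lengths - k + 1, 1)
            pos_ok = np.arange(n_pos)[None, :] < valid[:, None]
            masked = np.where(pos_ok[:, :, None], relu, -np.inf)
            arg = masked.argmax(axis=1)  # (B, F)
            pooled = np.take_along_axis(masked, arg[:, None, :], axis=1)[:, 0, :]
            pooled = np.maximum(pooled, 0.0)  # all-masked guard
            feats.append(pooled)
            caches.append((win, conv, arg, n_pos, pos_ok))
        feat = np.concatenate(feats, axis=1)
        logits = feat @ p["Wy"] + p["by"]
        return logits, (ids, x, caches, feat)

    def backward(self, cache, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        ids, x, caches, feat = cache
        b, tb, d = x.shape
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        grads["Wy"] = feat.T @ dlogits
        grads["by"] = dlogits.sum(axis=0)
        dfeat = dlogits @ p["Wy"].T
        dx = np.zeros_like(x)
        offset = 0
        for k, (win, conv, arg, n_pos, pos_ok) in zip(self.kernel_sizes, caches):
            dpool = dfeat[:, offset:offset + self.n_filters]
            offset += self.n_filters
            dconv = np.zeros_like(conv)
            np.put_along_axis(dconv, arg[:, None, :], dpool[:, None, :], axis=1)
            dconv *= (conv > 0) & pos_ok[:, :, None]
            grads[f"W{k}"] = win.reshape(-1, k * d).T @ dconv.reshape(-1, self.n_filters)
            grads[f"c{k}"] = dconv.sum(axis=(0, 1))
            dwin = (dconv @ p[f"W{k}"].T).reshape(b, n_pos, k, d)
            for off in range(k):
                dx[:, off:off + n_pos] += dwin[:, :, off]
        np.add.at(grads["E"], ids, dx)
        return grads
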