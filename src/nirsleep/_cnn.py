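"""Minimal deterministic 1-D CNN for 8x60 feature epochs, NumPy only.

Architecture: two conv blocks (32 and 64 filters, kernel 5, ReLU, max-pool
2), global average pooling, dense 32 + ReLU, dropout, sigmoid output.
Trained with Adam on class-weighted binary cross-entropy. Everything is
seeded through one Generator, so training is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CNNConfig:
    input_channels: int = 8
    input_length: int = 60
    conv_filters: tuple[int, ...] = (32, 64)
    kernel_size: int = 5
    dense_width: int = 32
    dropout: float = 0.3
    learning_rate: float = 0.001
    batch_size: int = 2
    epochs: int = 100
    patience: int = 15
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be at least 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / (1 - self.b1**self.t)
            v_hat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _conv1d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """'Same'-padded 1-D convolution, channels first: x (B,C,L), W (O,C,K)."""
    k = W.shape[2]
    p = k // 2
    x_pad = np.pad(x, ((0, 0), (0, 0), (p, p)))
    patches = np.lib.stride_tricks.sliding_window_view(x_pad, k, axis=2)  # (B,C,L,K)
    out = np.einsum("ock,bclk->bol", W, patches, optimize=True) + b[None, :, None]
    return out, (x_pad, patches)


def _conv1d_backward(dout: np.ndarray, W: np.ndarray, cache):
    x_pad, patches = cache
    k = W.shape[2]
    p = k // 2
    dW = np.einsum("bol,bclk->ock", dout, patches, optimize=True)
    db = dout.sum(axis=(0, 2))
    dx_pad = np.zeros_like(x_pad)
    L = dout.shape[2]
    for j in range(k):
        dx_pad[:, :, j:j + L] += np.einsum("bol,oc->bcl", dout, W[:, :, j], optimize=True)
    dx = dx_pad[:, :, p:x_pad.shape[2] - p]
    return dx, dW, db


def _maxpool2_forward(x: np.ndarray):
    B, C, L = x.shape
    L2 = L // 2
    xv = x[:, :, :2 * L2].reshape(B, C, L2, 2)
    idx = xv.argmax(axis=3)
    return xv.max(axis=3), (idx, x.shape)


def _maxpool2_backward(dout: np.ndarray, cache):
    idx, shape = cache
    B, C, L = shape
    L2 = L // 2
    dx = np.zeros((B, C, L2, 2))
    np.put_along_axis(dx, idx[..., None], dout[..., None], axis=3)
    out = np.zeros((B, C, L))
    out[:, :, :2 * L2] = dx.reshape(B, C, 2 * L2)
    return out


class CNNClassifier:
    """Binary QS-vs-AS classifier on (N, 8, 60) feature tensors."""

    def __init__(self, config: CNNConfig | None = None):
        self.config = config or CNNConfig()
        self.params: dict[str, np.ndarray] | None = None
        self.loss_trace: list[float] = []
        self._norm: tuple[np.ndarray, np.ndarray] | None = None

    # -- parameter setup ---------------------------------------------------
    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        cfg = self.config
        p: dict[str, np.ndarray] = {}
        c_in = cfg.input_channels
        for i, c_out in enumerate(cfg.conv_filters):
            p[f"Wc{i}"] = _he_init(rng, (c_out, c_in, cfg.kernel_size),
                                   c_in * cfg.kernel_size)
            p[f"bc{i}"] = np.zeros(c_out)
            c_in = c_out
        p["Wd1"] = _he_init(rng, (c_in, cfg.dense_width), c_in)
        p["bd1"] = np.zeros(cfg.dense_width)
        p["Wd2"] = _he_init(rng, (cfg.dense_width, 1), cfg.dense_width)
        p["bd2"] = np.zeros(1)
        return p

    # -- forward / backward ------------------------------------------------
    def _forward(self, x: np.ndarray, rng: np.random.Generator | None = None):
        """Returns (probabilities, caches); rng enables dropout (training mode)."""
        p = self.params
        caches = []
        h = x
        for i in range(len(self.config.conv_filters)):
            z, cc = _conv1d_forward(h, p[f"Wc{i}"], p[f"bc{i}"])
            a = np.maximum(z, 0.0)
            pool, pc = _maxpool2_forward(a)
            caches.append((cc, z, pc))
            h = pool
        gap = h.mean(axis=2)  # (B, C)
        z1 = gap @ p["Wd1"] + p["bd1"]
        a1 = np.maximum(z1, 0.0)
        if rng is not None and self.config.dropout > 0:
            mask = (rng.random(a1.shape) >= self.config.dropout) / (1 - self.config.dropout)
            a1d = a1 * mask
        else:
            mask = None
            a1d = a1
        z2 = a1d @ p["Wd2"] + p["bd2"]
        prob = 1.0 / (1.0 + np.exp(-z2[:, 0]))
        return prob, (caches, h.shape, gap, z1, mask, a1d)

    def _backward(self, x, prob, y, w, cache):
        p = self.params
        caches, h_shape, gap, z1, mask, a1d = cache
        B = len(y)
        grads: dict[str, np.ndarray] = {}
        # weighted BCE with sigmoid: dL/dz2 = w * (prob - y) / sum(w)
        dz2 = (w * (prob - y) / w.sum())[:, None]  # (B, 1)
        grads["Wd2"] = a1d.T @ dz2
        grads["bd2"] = dz2.sum(axis=0)
        da1 = dz2 @ p["Wd2"].T
        if mask is not None:
            da1 = da1 * mask
        dz1 = da1 * (z1 > 0)
        grads["Wd1"] = gap.T @ dz1
        grads["bd1"] = dz1.sum(axis=0)
        dgap = dz1 @ p["Wd1"].T
        dh = np.repeat(dgap[:, :, None] / h_shape[2], h_shape[2], axis=2)
        for i in reversed(range(len(self.config.conv_filters))):
            cc, z, pc = caches[i]
            da = _maxpool2_backward(dh, pc)
            dz = da * (z > 0)
            dh, dW, db = _conv1d_backward(dz, p[f"Wc{i}"], cc)
            grads[f"Wc{i}"] = dW
            grads[f"bc{i}"] = db
        return grads

    # -- training ----------------------------------------------------------
    @staticmethod
    def _loss(prob, y, w):
        eps = 1e-12
        return float(-np.sum(w * (y * np.log(prob + eps)
                                  + (1 - y) * np.log(1 - prob + eps))) / w.sum())

    def fit(self, X: np.ndarray, y: np.ndarray,
            class_weights: dict[int, float] | None = None) -> "CNNClassifier":
        """X: (N, 8, 60); y: 1 for QS (positive class), 0 for AS."""
        cfg = self.config
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) != {0.0, 1.0}:
            raise ValueError("training data must contain both classes")
        rng = np.random.default_rng(cfg.seed)
        # per-channel standardization, stored for inference
        mu = X.mean(axis=(0, 2), keepdims=True)
        sd = X.std(axis=(0, 2), keepdims=True)
        sd[sd == 0] = 1.0
        self._norm = (mu, sd)
        Xn = (X - mu) / sd

        w_all = np.ones_like(y)
        if class_weights:
            w_all = np.where(y == 1, class_weights.get(1, 1.0), class_weights.get(0, 1.0))

        n_val = max(0, int(round(cfg.validation_fraction * len(y))))
        order = rng.permutation(len(y))
        val_idx, tr_idx = order[:n_val], order[n_val:]
        if n_val and (len(set(y[val_idx])) < 2 or len(set(y[tr_idx])) < 2):
            n_val, val_idx, tr_idx = 0, order[:0], order  # fall back: no split
        Xtr, ytr, wtr = Xn[tr_idx], y[tr_idx], w_all[tr_idx]

        self.params = self._init_params(rng)
        opt = _Adam(self.params, cfg.learning_rate)
        best_loss, best_params, since_best = np.inf, None, 0
        self.loss_trace = []
        for _epoch in range(cfg.epochs):
            perm = rng.permutation(len(ytr))
            ep_loss = 0.0
            for s in range(0, len(perm), cfg.batch_size):
                b = perm[s:s + cfg.batch_size]
                prob, cache = self._forward(Xtr[b], rng)
                if not np.all(np.isfinite(prob)):
                    raise FloatingPointError(
                        f"NaN/Inf in CNN forward pass at epoch {_epoch}; "
                        "inspect feature scaling and learning rate"
                    )
                grads = self._backward(Xtr[b], prob, ytr[b], wtr[b], cache)
                opt.step(self.params, grads)
                ep_loss += self._loss(prob, ytr[b], wtr[b]) * len(b)
            ep_loss /= len(ytr)
            self.loss_trace.append(ep_loss)
            if not np.isfinite(ep_loss):
                raise FloatingPointError(f"non-finite training loss at epoch {_epoch}")
            monitor = ep_loss
            if n_val:
                pv, _ = self._forward(Xn[val_idx])
                monitor = self._loss(pv, y[val_idx], w_all[val_idx])
            if monitor < best_loss - 1e-6:
                best_loss = monitor
                best_params = {k: v.copy() for k, v in self.params.items()}
                since_best = 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
        if best_params is not None:
            self.params = best_params
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of the positive (QS) class, shape (N,)."""
        if self.params is None:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1:] != (self.config.input_channels, self.config.input_length):
            raise ValueError(
                f"expected epochs of shape (*, {self.config.input_channels}, "
                f"{self.config.input_length}), got {X.shape}"
            )
        mu, sd = self._norm
        prob, _ = self._forward((X - mu) / sd)
        return prob
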