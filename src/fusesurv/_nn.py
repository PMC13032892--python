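"""Minimal NumPy feed-forward net, AdamW, and gradient clipping.

Shared plumbing for the risk head and, when layers are unfrozen, the mock
encoder. Reverse-mode gradients are written by hand and verified against
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "AdamW", "clip_global_norm"]


class MLP:
    """Fully connected blocks (linear, dropout, ReLU) + linear scalar head.

    Dropout is active only when ``training=True`` and is driven by the rng
    passed to :meth:`forward`, so evaluation-mode predictions are
    deterministic.
    """

    def __init__(self, in_dim: int, hidden=(1024, 512, 256, 128), dropout: float = 0.2,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        dims = [in_dim, *hidden, 1]
        self.dropout = dropout
        self.W = []
        self.b = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            # He initialization for the ReLU blocks
            self.W.append(rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)))
            self.b.append(np.zeros(d_out))

    def parameters(self) -> list[np.ndarray]:
        out = []
        for W, b in zip(self.W, self.b):
            out.extend([W, b])
        return out

    def set_parameters(self, params: list[np.ndarray]) -> None:
        flat = self.parameters()
        for dst, src in zip(flat, params):
            dst[...] = src

    def copy_parameters(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def forward(self, X: np.ndarray, training: bool = False, rng=None):
        """Risk scores (n,) and, when training, a backprop cache."""
        h = np.asarray(X, float)
        cache = []
        n_blocks = len(self.W) - 1
        for i in range(n_blocks):
            z = h @ self.W[i] + self.b[i]
            if training and self.dropout > 0:
                keep = (rng.random(z.shape) >= self.dropout) / (1.0 - self.dropout)
            else:
                keep = None
            zd = z * keep if keep is not None else z
            a = np.maximum(zd, 0.0)
            cache.append((h, zd, keep))
            h = a
        out = (h @ self.W[-1] + self.b[-1]).ravel()
        cache.append((h, None, None))
        return out, cache

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic evaluation-mode risk scores."""
        return self.forward(X, training=False)[0]

    def backward(self, d_out: np.ndarray, cache, need_input_grad: bool = False):
        """Parameter gradients (aligned with :meth:`parameters`) given the
        loss gradient w.r.t. the scalar outputs; optionally also the
        gradient w.r.t. the input matrix."""
        grads_W = [None] * len(self.W)
        grads_b = [None] * len(self.b)
        h_last = cache[-1][0]
        d = d_out[:, None]
        grads_W[-1] = h_last.T @ d
        grads_b[-1] = d.sum(axis=0)
        dh = d @ self.W[-1].T
        for i in range(len(self.W) - 2, -1, -1):
            h_in, zd, keep = cache[i]
            dz = dh * (zd > 0)
            if keep is not None:
                dz = dz * keep
            grads_W[i] = h_in.T @ dz
            grads_b[i] = dz.sum(axis=0)
            if i > 0 or need_input_grad:
                dh = dz @ self.W[i].T
        grads = []
        for gW, gb in zip(grads_W, grads_b):
            grads.extend([gW, gb])
        if need_input_grad:
            return grads, dh
        return grads

    def input_gradient(self, X: np.ndarray) -> np.ndarray:
        """d(risk)/d(input) per sample, evaluation mode (for attribution)."""
        _, cache = self.forward(X, training=False)
        _, dX = self.backward(np.ones(X.shape[0]), cache, need_input_grad=True)
        return dX


class AdamW(object):
    """Decoupled weight-decay Adam over a flat parameter list."""

    def __init__(self, params: list[np.ndarray], lr: float, weight_decay: float = 0.0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p)


def clip_global_norm(grads: list[np.ndarray], max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is <= max_norm."""
    total = float(np.sqrt(sum(float(np.sum(g * g)) for g in grads)))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for g in grads:
            g *= scale
    return total
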