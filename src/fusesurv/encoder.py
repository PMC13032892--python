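"""Pluggable embedding-provider contract and a deterministic mock encoder.

The adapter contract any embedding provider must satisfy:

* input is a full-vocabulary expression profile (width ``V``) with
  non-selected genes already masked to zero;
* two total-count tokens (target and source) are appended, both equal to
  the sum of the input values — the convention used for bulk profiles
  where sequencing-depth variation is absent;
* ``pool_type="max"`` yields embeddings of width ``H`` (default 768),
  ``pool_type="all"`` of width ``4*H`` (3072 at the default width);
* the last ``Nu`` of ``L`` layers may be unfrozen for supervised
  fine-tuning; ``Nu=0`` reproduces the frozen pretrained behavior
  bitwise.

The mock realization uses token-wise affine+tanh layers (no attention):
cheap, smooth, deterministic from its seed, and with hand-written
backprop so gradient flow through unfrozen layers is real. The "all"
pooling composition (mean / max / std over tokens plus the final
count-token feature) is this package's own stand-in honoring the
``4*H`` width relation; it is isolated behind the adapter contract.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

__all__ = ["EncoderConfig", "EmbeddingMatrix", "MockEncoder", "init_mock_encoder"]

POOL_TYPES = ("max", "all")


@dataclass(frozen=True)
class EncoderConfig:
    """Mock encoder hyperparameters; embedding width follows the pooling
    mode: ``Ne = H`` for "max", ``Ne = 4*H`` for "all"."""

    vocab_size: int = 19_264
    hidden_width: int = 768
    n_layers: int = 12
    pool_type: str = "max"
    seed: int = 0

    def __post_init__(self):
        if self.hidden_width < 1 or self.n_layers < 1:
            raise ValueError("hidden_width and n_layers must be >= 1")
        if self.pool_type not in POOL_TYPES:
            raise ValueError(f"pool_type must be one of {POOL_TYPES}")

    @property
    def embedding_dim(self) -> int:
        return self.hidden_width if self.pool_type == "max" else 4 * self.hidden_width

    def fingerprint(self) -> str:
        payload = (
            f"{self.vocab_size}|{self.hidden_width}|{self.n_layers}"
            f"|{self.pool_type}|{self.seed}"
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:16]


@dataclass
class EmbeddingMatrix:
    """Per-sample encoder output of width ``Ne`` plus provenance."""

    values: np.ndarray
    pool_type: str
    fingerprint: str

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embeddings must be finite")

    @property
    def width(self) -> int:
        return self.values.shape[1]


class MockEncoder:
    """Deterministic token-wise encoder with partially unfreezable layers.

    Tokens are the ``V`` gene values plus two count tokens; each token
    scalar is embedded as ``value * u + g_t`` (``u`` a shared direction,
    ``g_t`` a per-token offset), then passed through ``L`` layers
    ``f -> tanh(f @ W_l + b_l)`` applied token-wise.
    """

    def __init__(self, config: EncoderConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        V, H, L = config.vocab_size, config.hidden_width, config.n_layers
        self.u = rng.normal(0.0, 1.0, size=H) / np.sqrt(H)
        self.token_offsets = rng.normal(0.0, 0.5, size=(V + 2, H))
        self.W = [rng.normal(0.0, 1.0, size=(H, H)) / np.sqrt(H) for _ in range(L)]
        self.b = [rng.normal(0.0, 0.1, size=H) for _ in range(L)]
        self.n_unfrozen = 0

    # -- trainability ---------------------------------------------------
    def set_unfrozen_layers(self, Nu: int) -> "MockEncoder":
        if not 0 <= Nu <= self.config.n_layers:
            raise ValueError(
                f"Nu must lie in [0, {self.config.n_layers}], got {Nu}"
            )
        self.n_unfrozen = Nu
        return self

    @property
    def trainable_layer_indices(self) -> list[int]:
        L = self.config.n_layers
        return list(range(L - self.n_unfrozen, L))

    def trainable_parameters(self) -> list[np.ndarray]:
        out = []
        for li in self.trainable_layer_indices:
            out.extend([self.W[li], self.b[li]])
        return out

    # -- forward --------------------------------------------------------
    def _tokens(self, masked_expr: np.ndarray) -> np.ndarray:
        V = self.config.vocab_size
        if masked_expr.ndim != 2 or masked_expr.shape[1] != V:
            raise ValueError(
                f"input width {masked_expr.shape[-1]} does not match vocabulary {V}"
            )
        totals = masked_expr.sum(axis=1, keepdims=True)
        scalars = np.concatenate([masked_expr, totals, totals], axis=1)  # n x (V+2)
        return scalars[:, :, None] * self.u[None, None, :] + self.token_offsets[None]

    def forward(self, masked_expr: np.ndarray, cache: bool = False):
        """Token features through all layers, then pooling.

        With ``cache=True`` also returns the activation stack needed by
        :meth:`backward`.
        """
        f = self._tokens(np.asarray(masked_expr, float))
        acts = [f]
        for W, b in zip(self.W, self.b):
            f = np.tanh(f @ W + b)
            acts.append(f)
        pooled, pool_cache = self._pool(f)
        if cache:
            return pooled, (acts, pool_cache)
        return pooled

    def _pool(self, f: np.ndarray):
        if self.config.pool_type == "max":
            arg = np.argmax(f, axis=1)
            return f.max(axis=1), ("max", arg, f.shape)
        mean = f.mean(axis=1)
        mx = f.max(axis=1)
        arg = np.argmax(f, axis=1)
        std = f.std(axis=1)
        count_tok = f[:, -1, :]
        pooled = np.concatenate([mean, mx, std, count_tok], axis=1)
        return pooled, ("all", arg, f.shape, mean, std)

    def encode(self, masked_expr, pool_type: str | None = None) -> EmbeddingMatrix:
        """Embed masked full-vocabulary profiles; deterministic given the
        current weights."""
        if pool_type is not None and pool_type != self.config.pool_type:
            raise ValueError(
                "pool_type is fixed at construction; rebuild the encoder to change it"
            )
        values = self.forward(np.asarray(masked_expr, float))
        return EmbeddingMatrix(
            values=values,
            pool_type=self.config.pool_type,
            fingerprint=self.config.fingerprint(),
        )

    # -- backward -------------------------------------------------------
    def backward(self, d_pooled: np.ndarray, cache) -> list[np.ndarray]:
        """Gradients of a scalar loss w.r.t. trainable layer parameters.

        ``d_pooled`` is the loss gradient at the pooled embeddings;
        returns gradients aligned with :meth:`trainable_parameters`.
        """
        acts, pool_cache = cache
        f_last = acts[-1]
        df = self._pool_backward(d_pooled, pool_cache, f_last)
        trainable = self.trainable_layer_indices  # contiguous tail of layers
        if not trainable:
            return []
        grads: dict[int, list[np.ndarray]] = {}
        for li in range(self.config.n_layers - 1, trainable[0] - 1, -1):
            pre_act = acts[li]
            post = acts[li + 1]
            dz = df * (1.0 - post**2)  # tanh'
            n, T, H = pre_act.shape
            gW = pre_act.reshape(n * T, H).T @ dz.reshape(n * T, H)
            gb = dz.sum(axis=(0, 1))
            grads[li] = [gW, gb]
            df = dz @ self.W[li].T
        out = []
        for li in trainable:
            out.extend(grads[li])
        return out

    def _pool_backward(self, d_pooled, pool_cache, f_last):
        n, T, H = f_last.shape
        df = np.zeros_like(f_last)
        if pool_cache[0] == "max":
            arg = pool_cache[1]
            np.put_along_axis(
                df, arg[:, None, :], d_pooled[:, None, :], axis=1
            )
            return df
        _, arg, _, mean, std = pool_cache
        d_mean = d_pooled[:, :H]
        d_max = d_pooled[:, H : 2 * H]
        d_std = d_pooled[:, 2 * H : 3 * H]
        d_ct = d_pooled[:, 3 * H :]
        df += d_mean[:, None, :] / T
        df_max = np.zeros_like(df)
        np.put_along_axis(df_max, arg[:, None, :], d_max[:, None, :], axis=1)
        df += df_max
        safe_std = np.where(std > 0, std, 1.0)
        centered = f_last - mean[:, None, :]
        df += d_std[:, None, :] * centered / (T * safe_std[:, None, :])
        df[:, -1, :] += d_ct
        return df


def init_mock_encoder(config: EncoderConfig) -> MockEncoder:
    """Build a mock encoder with weights drawn deterministically from the
    config seed; weights are immutable unless layers are unfrozen."""
    return MockEncoder(config)
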