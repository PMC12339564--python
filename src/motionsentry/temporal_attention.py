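"""Transformer-style temporal modeling over per-frame embeddings.

Scaled dot-product self-attention A = softmax(Q K^T / sqrt(d')) mixes
information across time steps; fixed sinusoidal positional encodings keep
the notion of temporal order. Two representation losses regularize the
attended features: a smoothness penalty on frame-to-frame jumps and a
lag-k cosine contrastive term that rewards locally consistent embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _ops as am
from .graph_encoder import glorot_uniform

DEFAULT_LATENT_DIM = 64
DEFAULT_PE_BASE = 10000.0


@dataclass
class TemporalAttentionParams:
    """Projections W_Q, W_K, W_V from model dim d to latent dim d'."""

    w_q: "np.ndarray"  # (d, d')
    w_k: "np.ndarray"
    w_v: "np.ndarray"
    stride: int = 5  # contrastive lag k, frames

    def __post_init__(self):
        shapes = {am.asdata(w).shape for w in (self.w_q, self.w_k, self.w_v)}
        if len(shapes) != 1:
            raise ValueError("W_Q, W_K, W_V must share one shape")
        if self.stride < 1:
            raise ValueError("contrastive stride k must be >= 1")

    @property
    def latent_dim(self) -> int:
        return am.asdata(self.w_q).shape[1]

    @classmethod
    def init(
        cls, d: int, d_latent: int = DEFAULT_LATENT_DIM, rng=None, stride: int = 5
    ) -> "TemporalAttentionParams":
        rng = rng or np.random.default_rng(0)
        return cls(
            w_q=glorot_uniform(rng, d, d_latent),
            w_k=glorot_uniform(rng, d, d_latent),
            w_v=glorot_uniform(rng, d, d_latent),
            stride=stride,
        )


def positional_encoding(
    n_frames: int, d: int, base: float = DEFAULT_PE_BASE
) -> np.ndarray:
    """Sinusoidal table PE[t, 2i] = sin(t / base^(2i/d)), PE[t, 2i+1] = cos(...).

    Odd ``d`` is padded internally and truncated, so the returned table always
    has exactly ``d`` columns. Every entry lies in [-1, 1].
    """
    d_pad = d + (d % 2)
    t = np.arange(n_frames)[:, None]
    i = np.arange(d_pad // 2)[None, :]
    angle = t / base ** (2.0 * i / d_pad)
    pe = np.zeros((n_frames, d_pad))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe[:, :d]


def add_positional_encoding(X, base: float = DEFAULT_PE_BASE):
    """X' = X + PE, broadcasting the fixed table onto a (T, d) sequence."""
    T, d = am.asdata(X).shape
    return X + positional_encoding(T, d, base)


def temporal_attention(X, params: TemporalAttentionParams):
    """Scaled dot-product self-attention over time.

    Returns ``(A, Z)`` with A = softmax(Q K^T / sqrt(d')) row-stochastic of
    shape (T, T) and Z = A V of shape (T, d').
    """
    Xd = am.asdata(X)
    if Xd.ndim != 2:
        raise ValueError("temporal attention expects a T x d sequence")
    if not np.isfinite(Xd).all():
        raise ValueError("temporal attention input contains non-finite values")
    q = X @ params.w_q
    k = X @ params.w_k
    v = X @ params.w_v
    logits = (q @ am.swapaxes(k, -1, -2)) * (1.0 / np.sqrt(params.latent_dim))
    A = am.softmax(logits, axis=-1)
    return A, A @ v


def temporal_smoothness_loss(Z):
    """sum_t ||Z_t - Z_{t+1}||^2; zero for constant (or single-frame) Z."""
    Zd = am.asdata(Z)
    if Zd.shape[0] < 2:
        return Z[0:0].sum() if am.is_tensor(Z) else 0.0
    d = Z[1:] - Z[:-1]
    return am.summation(d * d)


def temporal_contrastive_loss(Z, k: int, eps: float = 0.0):
    """sum_{t=1}^{T-k} (1 - cos(Z_t, Z_{t+k})).

    Zero when Z is periodic with period k; each orthogonal pair contributes 1,
    each anti-aligned pair 2. Rejects zero-norm rows (cosine undefined) unless
    a positive ``eps`` is supplied to regularize the norms (training path).
    """
    Zd = am.asdata(Z)
    T = Zd.shape[0]
    if T <= k:
        raise ValueError(f"need T > k (got T={T}, k={k})")
    if eps == 0.0:
        norms = np.linalg.norm(Zd, axis=1)
        zero = np.nonzero(norms == 0)[0]
        if zero.size:
            raise ValueError(
                f"zero-norm embedding at frame {int(zero[0])}: cosine undefined"
            )
    a, b = Z[:-k], Z[k:]
    dot = am.summation(a * b, axis=1)
    na = am.sqrt(am.summation(a * a, axis=1) + eps)
    nb = am.sqrt(am.summation(b * b, axis=1) + eps)
    cos = dot / (na * nb)
    return am.summation(1.0 - cos)
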