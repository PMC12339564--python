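"""Graph-convolutional spatial encoding and joint-level attention.

Both blocks act frame-wise on node-feature matrices (J joints x F channels);
given a stacked T x J x F input they apply to each frame independently with
shared parameters. All functions accept either numpy arrays (inference,
oracles) or autodiff tensors (training).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _ops as am
from .motion import SkeletonGraph

_ACTIVATIONS = {
    "relu": am.relu,
    "tanh": am.tanh,
    "identity": lambda x: x,
}


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    """Uniform(-a, a) with a = sqrt(6 / (fan_in + fan_out))."""
    a = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-a, a, size=(fan_in, fan_out))


@dataclass
class GCNStack:
    """Weights of a multi-layer graph convolution H' = act(A_hat H W)."""

    weights: list  # per-layer (F_in, F_out) matrices; numpy or Tensor
    activation: str = "relu"

    def __post_init__(self):
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        for l in range(len(self.weights) - 1):
            if am.asdata(self.weights[l]).shape[1] != am.asdata(
                self.weights[l + 1]
            ).shape[0]:
                raise ValueError(f"layer {l} output dim != layer {l + 1} input dim")

    @classmethod
    def init(
        cls, dims: list[int], rng: np.random.Generator, activation: str = "relu"
    ) -> "GCNStack":
        ws = [glorot_uniform(rng, a, b) for a, b in zip(dims[:-1], dims[1:])]
        return cls(weights=ws, activation=activation)


@dataclass
class SpatialAttentionParams:
    """Bilinear attention maps phi, psi: node-feature dim -> attention dim."""

    phi: "np.ndarray"  # (F, d_a)
    psi: "np.ndarray"  # (F, d_a)
    temperature: float = 1.0

    def __post_init__(self):
        if am.asdata(self.phi).shape[1] != am.asdata(self.psi).shape[1]:
            raise ValueError("phi and psi must share their output dimension")

    @classmethod
    def init(
        cls, n_features: int, attn_dim: int, rng: np.random.Generator
    ) -> "SpatialAttentionParams":
        return cls(
            phi=glorot_uniform(rng, n_features, attn_dim),
            psi=glorot_uniform(rng, n_features, attn_dim),
        )


def gcn_forward(H, A_hat, stack: GCNStack):
    """Layer-wise H^(l+1) = act(A_hat H^(l) W^(l)).

    ``H`` may be (J, F) for a single frame or (T, J, F); the frame axis is a
    pure batch dimension.
    """
    J = am.asdata(H).shape[-2]
    if am.asdata(A_hat).shape != (J, J):
        raise ValueError("A_hat shape does not match the joint axis of H")
    act = _ACTIVATIONS[stack.activation]
    out = H
    for l, W in enumerate(stack.weights):
        if am.asdata(out).shape[-1] != am.asdata(W).shape[0]:
            raise ValueError(
                f"layer {l}: feature dim {am.asdata(out).shape[-1]} != "
                f"weight input dim {am.asdata(W).shape[0]}"
            )
        out = act(A_hat @ out @ W)
    return out


def spatial_attention(F, graph: SkeletonGraph, params: SpatialAttentionParams):
    """Neighborhood-restricted joint attention.

    alpha_ij = softmax over j in N_i of phi(F_i)^T psi(F_j), with N_i the
    graph neighbors of i plus i itself; the output aggregates
    H_i = sum_j alpha_ij F_j. Returns ``(alpha, H_attn)``; alpha rows sum
    to 1 over each neighborhood. Works on (J, F) or (T, J, F).
    """
    mask = graph.neighborhoods()
    Fd = am.asdata(F)
    if Fd.shape[-2] != graph.n_joints:
        raise ValueError("feature joint axis does not match the skeleton")
    q = F @ params.phi  # (..., J, d_a)
    k = F @ params.psi
    logits = (q @ am.swapaxes(k, -1, -2)) * (1.0 / params.temperature)
    # exclude non-neighbors from the softmax support
    neg = np.where(mask, 0.0, -1e30)
    alpha = am.softmax(logits + neg, axis=-1)
    H_attn = alpha @ F
    return alpha, H_attn
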